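"""GO biological-process association rules and path significance.

Rules are unordered pairs of GO *leaf* terms observed on protein pairs
that are both (i) members of the same known pathway and (ii) adjacent in
the interaction network.  A candidate path is scored by the number of
rules realized along its edges; its p-value compares that count with
rule counts of random simple paths of the same edge count.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class AssociationRule:
    """An unordered GO leaf-term pair with its pathway support count."""

    terms: frozenset[str]
    support: int

    def matches(self, terms_u: set[str], terms_v: set[str]) -> bool:
        ts = sorted(self.terms)
        if len(ts) == 1:
            return ts[0] in terms_u and ts[0] in terms_v
        a, b = ts
        return (a in terms_u and b in terms_v) or (b in terms_u and a in terms_v)


@dataclass
class PathScore:
    """Scores attached to one candidate path."""

    path: tuple[str, ...]
    rule_count: int
    mean_abs_coexpr: float
    p_value: float


def leaf_annotations(
    annotations: Mapping[str, Iterable[str]], go_graph: nx.DiGraph
) -> dict[str, set[str]]:
    """Restrict each protein's annotation set to its leaf-most terms.

    A term is kept iff none of its descendants (GO graph edges point
    child -> parent) also annotates the same protein.  Idempotent.
    Unknown terms raise ``KeyError`` naming the term.
    """

    @lru_cache(maxsize=None)
    def descendants(term: str) -> frozenset[str]:
        # nodes that can reach `term`, i.e. GO descendants
        return frozenset(nx.ancestors(go_graph, term))

    out: dict[str, set[str]] = {}
    for protein, terms in annotations.items():
        terms = set(terms)
        for term in terms:
            if term not in go_graph:
                raise KeyError(f"annotation term {term!r} not in GO graph")
        out[protein] = {
            t for t in terms if not (descendants(t) & (terms - {t}))
        }
    return out


def mine_rules(
    pathways: Mapping[str, Iterable[str]],
    leaf_annots: Mapping[str, set[str]],
    network: nx.Graph,
    min_support: int = 1,
) -> set[AssociationRule]:
    """Mine leaf-term pair rules from pathway co-membership + adjacency.

    Support counts the distinct protein pairs (pooled across pathways)
    exhibiting the term pair.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    adjacent_pairs: set[tuple[str, str]] = set()
    for members in pathways.values():
        members = sorted(set(members))
        for u, v in combinations(members, 2):
            if network.has_edge(u, v):
                adjacent_pairs.add((u, v))

    support: dict[frozenset[str], set[tuple[str, str]]] = {}
    for u, v in adjacent_pairs:
        for ta in leaf_annots.get(u, ()):  # unordered term pairs
            for tb in leaf_annots.get(v, ()):
                support.setdefault(frozenset((ta, tb)), set()).add((u, v))

    return {
        AssociationRule(terms=rule, support=len(pairs))
        for rule, pairs in support.items()
        if len(pairs) >= min_support
    }


def path_rule_count(
    path: Sequence[str],
    rules: Iterable[AssociationRule],
    leaf_annots: Mapping[str, set[str]],
) -> int:
    """Number of (rule, edge) matches along the path.

    Each rule counts at most once per edge; a rule {ta, tb} matches edge
    (u, v) when ta annotates u and tb annotates v, or vice versa.
    """
    count = 0
    for u, v in zip(path, path[1:]):
        terms_u = leaf_annots.get(u, set())
        terms_v = leaf_annots.get(v, set())
        if not terms_u or not terms_v:
            continue
        for rule in rules:
            if rule.matches(terms_u, terms_v):
                count += 1
    return count


def sample_simple_path(
    network: nx.Graph,
    n_edges: int,
    rng: np.random.Generator,
    node_list: Sequence[str] | None = None,
    max_tries: int = 10_000,
) -> tuple[str, ...]:
    """Draw one random simple path with exactly ``n_edges`` edges.

    Random walk from a uniform start node, stepping to uniform unvisited
    neighbors; restarts on a dead end.  Raises ``ValueError`` when no
    path of the requested length is found within ``max_tries`` restarts.
    """
    if n_edges < 1:
        raise ValueError("n_edges must be >= 1")
    nodes = list(node_list) if node_list is not None else sorted(network.nodes)
    if not nodes:
        raise ValueError("empty network")
    for _ in range(max_tries):
        current = nodes[rng.integers(len(nodes))]
        path = [current]
        visited = {current}
        ok = True
        for _ in range(n_edges):
            neighbors = [n for n in network.neighbors(current) if n not in visited]
            if not neighbors:
                ok = False
                break
            current = neighbors[rng.integers(len(neighbors))]
            path.append(current)
            visited.add(current)
        if ok:
            return tuple(path)
    raise ValueError(f"no simple path of {n_edges} edges found in {max_tries} tries")


def path_significance(
    path: Sequence[str],
    rules: Iterable[AssociationRule],
    leaf_annots: Mapping[str, set[str]],
    network: nx.Graph,
    n_null: int = 1000,
    seed: int = 0,
) -> float:
    """Add-one-smoothed upper-tail p-value of the path's rule count.

    Null: rule counts of ``n_null`` random simple paths with the same
    edge count.  p = (1 + #{null >= observed}) / (1 + n_null).
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rules = list(rules)
    observed = path_rule_count(path, rules, leaf_annots)
    n_edges = len(path) - 1
    rng = np.random.default_rng(seed)
    node_list = sorted(network.nodes)
    ge = 0
    for _ in range(n_null):
        null_path = sample_simple_path(network, n_edges, rng, node_list=node_list)
        if path_rule_count(null_path, rules, leaf_annots) >= observed:
            ge += 1
    return (1 + ge) / (1 + n_null)
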