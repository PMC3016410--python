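"""Bounded simple-path enumeration and petal construction.

For a driver gene and each candidate gene, the search bound is the
shortest-path distance in the *raw* network (falling back to the imputed
network only when the pair is disconnected), which guarantees at least
one path whenever the pair is connected.  All simple paths within the
bound are enumerated in the imputed network, filtered by mean absolute
coexpression and association-rule significance, and merged.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from petals.coexpression import CoexpressionMap
from petals.go_rules import AssociationRule, PathScore, path_rule_count, path_significance

logger = logging.getLogger(__name__)


@dataclass
class Petal:
    """Union of the significant simple paths between driver and one candidate."""

    candidate: str | None
    graph: nx.Graph
    paths: list[PathScore] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return self.graph.number_of_edges() == 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class Blossom:
    """All non-empty petals radiating from one driver gene."""

    driver: str
    petals: dict[str, Petal] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.petals)


def shortest_path_distance(network: nx.Graph, a: str, b: str) -> float:
    """Minimum edge count between two nodes; ``inf`` when disconnected."""
    for node in (a, b):
        if node not in network:
            raise KeyError(f"node {node!r} not in network")
    try:
        return float(nx.shortest_path_length(network, a, b))
    except nx.NetworkXNoPath:
        return math.inf


def diameter_bound(raw: nx.Graph, imputed: nx.Graph, a: str, b: str) -> float:
    """Search bound d_i: raw-network distance, imputed fallback on disconnection."""
    d = shortest_path_distance(raw, a, b)
    if math.isinf(d):
        d = shortest_path_distance(imputed, a, b)
    return d


def all_paths_dfs(
    network: nx.Graph, a: str, b: str, max_len: int | float
) -> set[tuple[str, ...]]:
    """All simple paths from ``a`` to ``b`` with edge count <= ``max_len``.

    The bound is inclusive so the shortest path itself is always among
    the results when the endpoints are connected within the bound.
    """
    if math.isinf(max_len):
        raise ValueError("max_len must be finite; skip disconnected candidates")
    max_len = int(max_len)
    if max_len < 1:
        if a == b and max_len >= 0:
            return {(a,)}
        return set()
    for node in (a, b):
        if node not in network:
            raise KeyError(f"node {node!r} not in network")
    if a == b:
        return {(a,)}

    paths: set[tuple[str, ...]] = set()
    stack: list[str] = [a]
    visited: set[str] = {a}

    def _dfs(current: str) -> None:
        if len(stack) - 1 >= max_len:
            return
        for nxt in network.neighbors(current):
            if nxt == b:
                paths.add(tuple(stack) + (b,))
                continue
            if nxt in visited:
                continue
            stack.append(nxt)
            visited.add(nxt)
            _dfs(nxt)
            stack.pop()
            visited.remove(nxt)

    _dfs(a)
    return paths


def mean_abs_coexpression(path: Sequence[str], coexpr_map: CoexpressionMap) -> float:
    """r(phi): mean over consecutive pairs of |r|; missing genes count 0."""
    values = []
    for u, v in zip(path, path[1:]):
        if u in coexpr_map and v in coexpr_map:
            values.append(abs(coexpr_map.r(u, v)))
        else:
            values.append(0.0)
    return float(np.mean(values)) if values else 0.0


def _path_seed(seed: int, candidate: str, path: Sequence[str]) -> int:
    """Stable per-path substream so p-values do not depend on enumeration order."""
    key = candidate + "|" + "/".join(path)
    return int(np.random.SeedSequence([seed, zlib.crc32(key.encode())]).generate_state(1)[0])


def build_petal(
    candidate: str,
    paths: Iterable[Sequence[str]],
    coexpr_map: CoexpressionMap,
    rules: Iterable[AssociationRule],
    leaf_annots: Mapping[str, set[str]],
    network: nx.Graph,
    gamma: float = 0.6,
    p_threshold: float = 0.05,
    seed: int = 0,
    n_null: int = 1000,
) -> Petal:
    """Score candidate paths and merge the survivors into a petal.

    A path is kept when its mean absolute coexpression r(phi) >= gamma
    AND its rule-count p-value < p_threshold.  An empty petal is
    returned when no path survives.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must lie in (0, 1), got {gamma}")
    if not 0.0 < p_threshold < 1.0:
        raise ValueError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    rules = list(rules)
    retained: list[PathScore] = []
    for path in sorted(tuple(p) for p in paths):
        r_phi = mean_abs_coexpression(path, coexpr_map)
        if r_phi < gamma:
            continue  # cheap filter first; p is seeded per path either way
        p_phi = path_significance(
            path, rules, leaf_annots, network,
            n_null=n_null, seed=_path_seed(seed, candidate, path),
        )
        if p_phi < p_threshold:
            retained.append(
                PathScore(
                    path=path,
                    rule_count=path_rule_count(path, rules, leaf_annots),
                    mean_abs_coexpr=r_phi,
                    p_value=p_phi,
                )
            )

    graph = nx.Graph()
    for score in retained:
        for u, v in zip(score.path, score.path[1:]):
            graph.add_edge(u, v, **network.edges[u, v])
    return Petal(candidate=candidate, graph=graph, paths=retained)


def build_blossom(
    driver: str,
    candidates: Iterable[str],
    raw_network: nx.Graph,
    imputed_network: nx.Graph,
    coexpr_map: CoexpressionMap,
    rules: Iterable[AssociationRule],
    leaf_annots: Mapping[str, set[str]],
    gamma: float = 0.6,
    p_threshold: float = 0.05,
    seed: int = 0,
    n_null: int = 1000,
    max_bound: int | None = None,
) -> Blossom:
    """Run diameter bound -> path enumeration -> petal merge per candidate.

    Candidates disconnected in both networks, or whose petal is empty,
    are omitted.  Per-candidate results are independent, so the output
    does not depend on candidate order.  ``max_bound`` optionally caps
    the search depth (a safety valve for very dense networks).
    """
    if driver not in imputed_network:
        raise KeyError(f"driver {driver!r} not in network")
    rules = list(rules)
    blossom = Blossom(driver=driver)
    for candidate in sorted(set(candidates)):
        if candidate == driver or candidate not in imputed_network:
            continue
        d = diameter_bound(raw_network, imputed_network, driver, candidate)
        if math.isinf(d):
            logger.info("candidate %s disconnected in raw and imputed networks", candidate)
            continue
        if max_bound is not None:
            d = min(d, max_bound)
        paths = all_paths_dfs(imputed_network, driver, candidate, d)
        petal = build_petal(
            candidate, paths, coexpr_map, rules, leaf_annots, imputed_network,
            gamma=gamma, p_threshold=p_threshold, seed=seed, n_null=n_null,
        )
        logger.info(
            "candidate %s: bound %d, %d paths enumerated, %d retained",
            candidate, int(d), len(paths), len(petal.paths),
        )
        if not petal.is_empty:
            blossom.petals[candidate] = petal
    return blossom
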