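"""Edge-reliability filtering and family-based interaction imputation.

False positives are removed with a logistic regression over four edge
features (observation count, coexpression, mean endpoint clustering
coefficient, subcellular-localization overlap), thresholded at a cutoff
optimized on held-out splits.  False negatives are then imputed: a
missing edge is added whenever at least one observed edge joins the two
proteins' families.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

from petals.formats_io import IMPUTED, OBSERVED, ExpressionBundle, as_edge_key

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("obs_count", "coexpr", "clustering", "localization")

Edge = tuple[str, str]


def clustering_coefficient(network: nx.Graph, node: str) -> float:
    """Small-world clustering coefficient of one node (0 for degree < 2)."""
    if node not in network:
        raise KeyError(f"node {node!r} not in network")
    return float(nx.clustering(network, node))


def compute_edge_features(
    network: nx.Graph,
    expression: ExpressionBundle | None = None,
    localization_map: Mapping[str, set[str]] | None = None,
    edges: Iterable[Edge] | None = None,
) -> pd.DataFrame:
    """One four-feature row per edge, indexed by the sorted node pair.

    ``edges`` defaults to the network's edges; pairs outside the network
    (candidate negative examples) get observation count 0.  Missing data
    degrades to defaults: coexpression 0 when either gene is absent or
    constant, localization 0 when either compartment set is empty,
    otherwise the Jaccard overlap of the two sets.
    """
    if edges is None:
        edge_list = [as_edge_key(u, v) for u, v in network.edges]
    else:
        edge_list = [as_edge_key(u, v) for u, v in edges]
    edge_list = sorted(set(edge_list))
    localization_map = localization_map or {}

    clustering = nx.clustering(network)

    # z-scored rows make pairwise Pearson a single dot product
    zscores: dict[str, np.ndarray] = {}
    if expression is not None:
        mu = expression.values.mean(axis=1, keepdims=True)
        sd = expression.values.std(axis=1, keepdims=True)
        ok = sd[:, 0] > 0
        z = np.zeros_like(expression.values)
        z[ok] = (expression.values[ok] - mu[ok]) / sd[ok]
        zscores = {g: z[i] for i, g in enumerate(expression.genes) if ok[i]}

    rows = []
    n_samples = len(expression.samples) if expression is not None else 0
    for u, v in edge_list:
        obs = network[u][v].get("observation_count", 1) if network.has_edge(u, v) else 0
        coexpr = 0.0
        if u in zscores and v in zscores:
            coexpr = float(np.dot(zscores[u], zscores[v]) / n_samples)
            coexpr = float(np.clip(coexpr, -1.0, 1.0))
        clust = (clustering.get(u, 0.0) + clustering.get(v, 0.0)) / 2.0
        loc_u = localization_map.get(u, set())
        loc_v = localization_map.get(v, set())
        if loc_u and loc_v:
            loc = len(loc_u & loc_v) / len(loc_u | loc_v)
        else:
            loc = 0.0
        rows.append((obs, coexpr, clust, loc))

    index = pd.MultiIndex.from_tuples(edge_list, names=["geneA", "geneB"])
    return pd.DataFrame(rows, index=index, columns=list(FEATURE_NAMES), dtype=float)


@dataclass
class ReliabilityModel:
    """Fitted logistic edge-reliability model with a probability cutoff."""

    coef: np.ndarray  # aligned with FEATURE_NAMES
    intercept: float
    cutoff: float
    n_repeats: int
    seed: int
    holdout_accuracy: float = float("nan")
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError(f"cutoff must lie strictly in (0, 1), got {self.cutoff}")

    def predict_proba(self, features: pd.DataFrame) -> pd.Series:
        x = features[list(self.feature_names)].to_numpy(dtype=float)
        logit = x @ self.coef + self.intercept
        return pd.Series(1.0 / (1.0 + np.exp(-logit)), index=features.index)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "cutoff": self.cutoff,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "holdout_accuracy": self.holdout_accuracy,
            "feature_names": list(self.feature_names),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ReliabilityModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            coef=np.array(payload["coef"]),
            intercept=payload["intercept"],
            cutoff=payload["cutoff"],
            n_repeats=payload["n_repeats"],
            seed=payload["seed"],
            holdout_accuracy=payload.get("holdout_accuracy", float("nan")),
            feature_names=tuple(payload["feature_names"]),
        )


def train_reliability_model(
    features: pd.DataFrame,
    positives: Iterable[Edge],
    negatives: Iterable[Edge],
    n_repeats: int = 100,
    seed: int = 0,
) -> ReliabilityModel:
    """Fit the logistic model and choose a probability cutoff.

    Per repeat: a random 80/20 train/test split, a fit on the training
    80%, and the test-set probability threshold maximizing Youden's J.
    The final cutoff is the mean over repeats; the final coefficients
    come from a fit on all labeled edges.  Deterministic given ``seed``.
    """
    pos = sorted({as_edge_key(*e) for e in positives})
    neg = sorted({as_edge_key(*e) for e in negatives})
    overlap = set(pos) & set(neg)
    if overlap:
        raise ValueError(f"positives and negatives overlap: {sorted(overlap)[:5]}")
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 examples per class")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    missing = [e for e in pos + neg if e not in features.index]
    if missing:
        raise KeyError(f"labeled edges missing from feature table: {missing[:5]}")

    x = features.loc[pos + neg, list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = np.array([1] * len(pos) + [0] * len(neg))
    rng = np.random.default_rng(seed)

    cutoffs = []
    accuracies = []
    n = len(y)
    for _ in range(n_repeats):
        order = rng.permutation(n)
        n_test = max(1, int(round(0.2 * n)))
        test_idx, train_idx = order[:n_test], order[n_test:]
        if len(set(y[train_idx])) < 2 or len(set(y[test_idx])) < 2:
            continue  # degenerate split; Youden undefined
        clf = LogisticRegression(max_iter=1000)
        clf.fit(x[train_idx], y[train_idx])
        probs = clf.predict_proba(x[test_idx])[:, 1]
        fpr, tpr, thresholds = roc_curve(y[test_idx], probs)
        best = int(np.argmax(tpr - fpr))
        thr = float(np.clip(thresholds[best], 1e-6, 1 - 1e-6))
        cutoffs.append(thr)
        accuracies.append(float(np.mean((probs >= thr) == (y[test_idx] == 1))))
    if not cutoffs:
        raise ValueError("every split was degenerate; supply more labeled edges")

    final = LogisticRegression(max_iter=1000)
    final.fit(x, y)
    return ReliabilityModel(
        coef=final.coef_[0],
        intercept=float(final.intercept_[0]),
        cutoff=float(np.mean(cutoffs)),
        n_repeats=n_repeats,
        seed=seed,
        holdout_accuracy=float(np.mean(accuracies)),
    )


def filter_network(
    network: nx.Graph,
    model: ReliabilityModel,
    features: pd.DataFrame,
) -> tuple[nx.Graph, set[Edge]]:
    """Keep edges with predicted reliability >= cutoff; report removals.

    Returns (G', F): the filtered network over the unchanged node set,
    and the removed edge set F.
    """
    edges = [as_edge_key(u, v) for u, v in network.edges]
    missing = [e for e in edges if e not in features.index]
    if missing:
        raise KeyError(f"features missing for edges: {missing[:5]}")
    probs = model.predict_proba(features.loc[edges])
    refined = nx.Graph()
    refined.add_nodes_from(network.nodes)
    removed: set[Edge] = set()
    for edge in edges:
        if probs.loc[edge] >= model.cutoff:
            refined.add_edge(*edge, **network.edges[edge])
        else:
            removed.add(edge)
    logger.info("reliability filter: kept %d edges, removed %d", refined.number_of_edges(), len(removed))
    return refined, removed


def impute_edges(filtered_network: nx.Graph, family_map: Mapping[str, set[str]]) -> nx.Graph:
    """Add family-supported missing edges (provenance ``imputed``).

    A pair (a, b) with no existing edge is joined when some family of a
    and some family of b are linked by at least one *observed* edge of
    the filtered network.  Restricting the evidence to observed edges
    makes imputation idempotent.
    """
    fams = {g: set(f) for g, f in family_map.items() if g in filtered_network}
    members: dict[str, set[str]] = {}
    for gene, gene_fams in fams.items():
        for fam in gene_fams:
            members.setdefault(fam, set()).add(gene)

    interacting: set[frozenset[str]] = set()
    for u, v, data in filtered_network.edges(data=True):
        if data.get("provenance", OBSERVED) != OBSERVED:
            continue
        for fu in fams.get(u, ()):  # proteins may map to several families
            for fv in fams.get(v, ()):
                interacting.add(frozenset((fu, fv)))

    imputed = filtered_network.copy()
    n_added = 0
    for pair in interacting:
        if len(pair) == 1:
            (f,) = pair
            g = f
        else:
            f, g = sorted(pair)
        for a in members.get(f, ()):  # all cross-family pairs
            for b in members.get(g, ()):
                if a == b or imputed.has_edge(a, b):
                    continue
                imputed.add_edge(a, b, observation_count=0, provenance=IMPUTED)
                n_added += 1
    logger.info("imputation: added %d family-supported edges", n_added)
    return imputed


def sample_negative_edges(
    network: nx.Graph,
    n: int,
    exclude: Iterable[Edge],
    seed: int = 0,
) -> list[Edge]:
    """Sample node pairs uniformly at random that are neither network
    edges nor in ``exclude`` (stand-ins for unreliable interactions)."""
    rng = np.random.default_rng(seed)
    nodes = sorted(network.nodes)
    banned = {as_edge_key(u, v) for u, v in network.edges} | {as_edge_key(*e) for e in exclude}
    out: set[Edge] = set()
    max_tries = 100 * n + 1000
    tries = 0
    while len(out) < n and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, len(nodes), size=2)
        if i == j:
            continue
        pair = as_edge_key(nodes[i], nodes[j])
        if pair not in banned:
            out.add(pair)
    if len(out) < n:
        raise ValueError(f"could not sample {n} negative pairs from this network")
    return sorted(out)
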