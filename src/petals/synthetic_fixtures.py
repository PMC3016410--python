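"""Self-contained synthetic inputs with known ground truth.

Expression follows a latent-factor model: one shared factor carries the
driver gene, one factor per candidate carries that candidate's planted
path, and the planted ("true") proteomic targets load on the planted
candidate's factor with alternating signs, producing the two-tailed
coexpression signature the bimodality statistic is designed to detect.
Differential expression enters as a WT/MT mean shift on path genes,
sized to hit a requested t effect.  Annotations and pathways are built
so every planted path edge realizes at least one mined association rule.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from petals import formats_io
from petals.coexpression import activity, pearson_map
from petals.formats_io import ExpressionBundle, as_edge_key

logger = logging.getLogger(__name__)

ROOT_TERM = "GO:0000001"
SIGNAL_TERM = "GO:0000002"
COMPARTMENTS = ("nucleus", "cytoplasm", "membrane", "extracellular", "mitochondrion")


@dataclass
class FixtureSpec:
    """Knobs for one synthetic input bundle."""

    n_genes: int = 500
    n_samples_per_group: int = 8
    network_model: str = "er"  # "er" or "ba"
    n_edges: int = 1500
    n_families: int = 40
    n_pathways: int = 12
    n_candidates: int = 6
    path_len: int = 2  # edges per planted driver->candidate path
    n_targets: int = 31
    frac_true: float = 0.65  # fraction of targets loading on the planted factor
    target_corr: float = 0.6  # implied petal-gene <-> true-target correlation
    driver_loading: float = 1.5  # driver on the shared factor
    path_shared_loading: float = 1.0  # path genes on the shared factor
    path_loading: float = 2.2  # path genes on their candidate factor
    activity_t: float = 3.0  # requested Welch t of planted-path genes
    decoy_activity_t: float = 2.0  # requested Welch t of decoy-path genes
    noise_sigma: float = 1.0
    n_background_terms: int = 25
    seed: int = 0

    def validate(self) -> None:
        positive = {
            "n_genes": self.n_genes, "n_samples_per_group": self.n_samples_per_group,
            "n_edges": self.n_edges, "n_families": self.n_families,
            "n_pathways": self.n_pathways, "n_candidates": self.n_candidates,
            "path_len": self.path_len, "n_targets": self.n_targets,
            "noise_sigma": self.noise_sigma,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not 0.0 <= self.frac_true <= 1.0:
            raise ValueError("frac_true must lie in [0, 1]")
        if not -1.0 < self.target_corr < 1.0:
            raise ValueError("target_corr must lie in (-1, 1)")
        if self.network_model not in ("er", "ba"):
            raise ValueError("network_model must be 'er' or 'ba'")
        needed = 1 + self.n_candidates * self.path_len + self.n_targets
        if self.n_genes < needed + 10:
            raise ValueError(f"n_genes={self.n_genes} too small for planted structure ({needed})")


@dataclass
class SyntheticBundle:
    spec: FixtureSpec
    network: nx.Graph
    expression: ExpressionBundle
    annotations: dict[str, set[str]]
    go_graph: nx.DiGraph
    pathways: dict[str, list[str]]
    family_map: dict[str, set[str]]
    localization_map: dict[str, set[str]]
    targets: list[str]
    positives: list[tuple[str, str]]
    driver: str = ""
    candidates: list[str] = field(default_factory=list)
    ground_truth: dict = field(default_factory=dict)


def _delta_for_t(spec: FixtureSpec, group_var: float | None = None) -> float:
    """WT/MT mean shift giving a gene with the supplied within-group
    variance the requested Welch t (path-gene variance by default)."""
    if group_var is None:
        group_var = (
            spec.path_shared_loading**2 + spec.path_loading**2 + spec.noise_sigma**2
        )
    return spec.activity_t * math.sqrt(2.0 * group_var / spec.n_samples_per_group)


def _target_loading(spec: FixtureSpec) -> float:
    """Loading b of true targets on the planted factor so that the
    implied path-gene <-> target correlation equals ``target_corr``.

    r = a1*b / sqrt(v_path * (b^2 + sigma^2)) with v_path the pooled
    variance of a path gene (factors + group shift + noise).
    """
    a1 = spec.path_loading
    delta = _delta_for_t(spec)
    v_path = (
        spec.path_shared_loading**2 + a1**2 + spec.noise_sigma**2 + delta**2 / 4.0
    )
    r = spec.target_corr
    denom = a1**2 - r**2 * v_path
    if denom <= 0:
        raise ValueError(
            f"target_corr={r} unattainable with path_loading={a1}; raise path_loading"
        )
    return abs(r) * spec.noise_sigma * math.sqrt(v_path / denom)


def implied_correlation(loadings_i: dict, loadings_j: dict, noise_i: float, noise_j: float) -> float:
    """Model-implied Pearson r for two genes given factor loadings.

    Factor variances are 1 except the group pseudo-factor ``grp`` whose
    balanced-design variance is 1/4.
    """

    def factor_var(name: str) -> float:
        return 0.25 if name == "grp" else 1.0

    cov = sum(
        w * loadings_j.get(f, 0.0) * factor_var(f) for f, w in loadings_i.items()
    )
    var_i = sum(w**2 * factor_var(f) for f, w in loadings_i.items()) + noise_i**2
    var_j = sum(w**2 * factor_var(f) for f, w in loadings_j.items()) + noise_j**2
    return cov / math.sqrt(var_i * var_j)


def generate_fixture(spec: FixtureSpec) -> SyntheticBundle:
    """Build the full input bundle; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:04d}" for i in range(spec.n_genes)]

    driver = genes[0]
    candidates = genes[1 : 1 + spec.n_candidates]
    n_mid = spec.path_len - 1
    mid_pool = iter(genes[1 + spec.n_candidates :])
    planted_paths: dict[str, list[str]] = {}
    for cand in candidates:
        mids = [next(mid_pool) for _ in range(n_mid)]
        planted_paths[cand] = [driver, *mids, cand]
    path_genes = sorted({g for p in planted_paths.values() for g in p})

    used = set(path_genes)
    remaining = [g for g in genes if g not in used]
    n_true = int(round(spec.frac_true * spec.n_targets))
    true_targets = remaining[: n_true]
    decoy_targets = remaining[n_true : spec.n_targets]
    targets = sorted(true_targets + decoy_targets)

    network = _build_network(spec, genes, planted_paths, rng)
    expression, loadings, noise_scale, delta = _build_expression(
        spec, genes, planted_paths, true_targets, rng
    )
    go_graph, annotations = _build_annotations(spec, genes, path_genes, rng)
    pathways = _build_pathways(spec, genes, planted_paths, rng)
    family_map = _random_pair_map(genes, [f"F{i:03d}" for i in range(spec.n_families)],
                                  p_any=0.7, max_tokens=2, rng=rng)
    localization_map = _random_pair_map(genes, list(COMPARTMENTS), p_any=0.9,
                                        max_tokens=2, rng=rng)

    # labeled reliable edges for the refinement stage: the planted path
    # edges plus a sample of well-observed background edges
    planted_edges = sorted(
        {as_edge_key(u, v) for p in planted_paths.values() for u, v in zip(p, p[1:])}
    )
    background_edges = sorted(set(map(lambda e: as_edge_key(*e), network.edges)) - set(planted_edges))
    n_pos_bg = min(150, len(background_edges))
    pos_idx = rng.choice(len(background_edges), size=n_pos_bg, replace=False)
    positives = sorted(set(planted_edges) | {background_edges[i] for i in sorted(pos_idx)})

    planted_candidate = candidates[0]
    ground_truth = {
        "driver": driver,
        "candidates": candidates,
        "planted_candidate": planted_candidate,
        "planted_paths": {c: p for c, p in planted_paths.items()},
        "true_targets": sorted(true_targets),
        "decoy_targets": sorted(decoy_targets),
        "delta": delta,
        "loadings": {g: loadings[g] for g in sorted(loadings)},
        "noise_sigma": spec.noise_sigma,
        "signal_term": SIGNAL_TERM,
        "seed": spec.seed,
    }
    return SyntheticBundle(
        spec=spec,
        network=network,
        expression=expression,
        annotations=annotations,
        go_graph=go_graph,
        pathways=pathways,
        family_map=family_map,
        localization_map=localization_map,
        targets=targets,
        positives=positives,
        driver=driver,
        candidates=list(candidates),
        ground_truth=ground_truth,
    )


def _build_network(spec, genes, planted_paths, rng) -> nx.Graph:
    net_seed = int(rng.integers(2**31 - 1))
    if spec.network_model == "er":
        raw = nx.gnm_random_graph(spec.n_genes, spec.n_edges, seed=net_seed)
    else:
        m = max(1, round(spec.n_edges / spec.n_genes))
        raw = nx.barabasi_albert_graph(spec.n_genes, m, seed=net_seed)
    network = nx.relabel_nodes(raw, dict(enumerate(genes)))
    network.add_nodes_from(genes)

    driver = planted_paths[next(iter(planted_paths))][0]
    for cand, path in planted_paths.items():
        # keep the planted path tied for shortest: no driver-candidate shortcut
        if network.has_edge(driver, cand):
            network.remove_edge(driver, cand)
        while True:
            try:
                short = nx.shortest_path(network, driver, cand)
            except nx.NetworkXNoPath:
                break
            if len(short) - 1 >= spec.path_len:
                break
            planted = {as_edge_key(u, v) for p in planted_paths.values() for u, v in zip(p, p[1:])}
            removable = [
                as_edge_key(u, v)
                for u, v in zip(short, short[1:])
                if as_edge_key(u, v) not in planted and network.has_edge(u, v)
            ]
            if not removable:
                break
            network.remove_edge(*removable[rng.integers(len(removable))])

    for u, v in network.edges:
        count = 1 + (2 if rng.random() < 0.25 else 0) + int(rng.integers(0, 2))
        network[u][v]["observation_count"] = count
        network[u][v]["provenance"] = formats_io.OBSERVED
    for cand, path in planted_paths.items():
        for u, v in zip(path, path[1:]):
            network.add_edge(u, v, observation_count=int(rng.integers(4, 7)),
                             provenance=formats_io.OBSERVED)
    return network


def _build_expression(spec, genes, planted_paths, true_targets, rng):
    n_per = spec.n_samples_per_group
    n_samples = 2 * n_per
    samples = [f"wt{i + 1}" for i in range(n_per)] + [f"mt{i + 1}" for i in range(n_per)]
    groups = ["WT"] * n_per + ["MT"] * n_per
    grp = np.array([0.0] * n_per + [1.0] * n_per)

    candidates = list(planted_paths)
    factor_names = ["f0"] + [f"f_{c}" for c in candidates]
    # factors are made exactly orthogonal in-sample, group-centered, and
    # unit-variance: chance factor-factor correlation at 16 samples would
    # otherwise let decoy petals correlate coherently with the targets,
    # and chance group imbalance would corrupt the planted t effects
    raw = rng.standard_normal((n_samples, len(factor_names)))
    raw[:n_per] -= raw[:n_per].mean(axis=0)
    raw[n_per:] -= raw[n_per:].mean(axis=0)
    q, _ = np.linalg.qr(raw)
    factors = {
        name: q[:, k] * math.sqrt(n_samples) for k, name in enumerate(factor_names)
    }

    delta = _delta_for_t(spec)
    # the driver has less variance than path genes; shift it by less so
    # its t matches theirs instead of dominating the activity maximum
    delta_driver = _delta_for_t(
        spec, group_var=spec.driver_loading**2 + spec.noise_sigma**2
    )
    b = _target_loading(spec)
    driver = planted_paths[candidates[0]][0]
    planted_factor = f"f_{candidates[0]}"

    path_group_var = (
        spec.path_shared_loading**2 + spec.path_loading**2 + spec.noise_sigma**2
    )
    delta_decoy = spec.decoy_activity_t * math.sqrt(
        2.0 * path_group_var / spec.n_samples_per_group
    )

    loadings: dict[str, dict[str, float]] = {}
    loadings[driver] = {"f0": spec.driver_loading, "grp": delta_driver}
    for cand in candidates:
        shift = delta if cand == candidates[0] else delta_decoy
        for g in planted_paths[cand][1:]:
            loadings[g] = {
                "f0": spec.path_shared_loading,
                f"f_{cand}": spec.path_loading,
                "grp": shift,
            }
    for i, t in enumerate(sorted(true_targets)):
        sign = 1.0 if i % 2 == 0 else -1.0
        loadings[t] = {planted_factor: sign * b}

    values = rng.standard_normal((spec.n_genes, n_samples)) * spec.noise_sigma
    index = {g: i for i, g in enumerate(genes)}
    for g, load in loadings.items():
        row = values[index[g]]
        for f, w in load.items():
            row += w * (grp if f == "grp" else factors[f])

    expression = ExpressionBundle(genes=list(genes), samples=samples,
                                  values=values, groups=groups)
    return expression, loadings, spec.noise_sigma, delta


def _build_annotations(spec, genes, path_genes, rng):
    go_graph = nx.DiGraph()
    go_graph.add_node(ROOT_TERM, name="biological_process", namespace="biological_process")
    bg_terms = [f"GO:{100 + i:07d}" for i in range(spec.n_background_terms)]
    for term in [SIGNAL_TERM, *bg_terms]:
        go_graph.add_node(term, name=term, namespace="biological_process")
        go_graph.add_edge(term, ROOT_TERM, relation="is_a")

    annotations: dict[str, set[str]] = {}
    path_set = set(path_genes)
    for g in genes:
        if g in path_set:
            extra = rng.choice(len(bg_terms))
            annotations[g] = {ROOT_TERM, SIGNAL_TERM, bg_terms[int(extra)]}
        elif rng.random() < 0.8:
            k = int(rng.integers(1, 4))
            picks = rng.choice(len(bg_terms), size=k, replace=False)
            annotations[g] = {ROOT_TERM} | {bg_terms[int(i)] for i in picks}
    return go_graph, annotations


def _build_pathways(spec, genes, planted_paths, rng):
    pathways: dict[str, list[str]] = {}
    for i, (cand, path) in enumerate(planted_paths.items()):
        pathways[f"planted_{i:02d}"] = list(path)
    n_random = max(0, spec.n_pathways - len(pathways))
    for i in range(n_random):
        size = int(rng.integers(6, 11))
        picks = rng.choice(spec.n_genes, size=size, replace=False)
        pathways[f"random_{i:02d}"] = [genes[int(j)] for j in sorted(picks)]
    return pathways


def _random_pair_map(genes, tokens, p_any, max_tokens, rng):
    mapping: dict[str, set[str]] = {}
    for g in genes:
        if rng.random() < p_any:
            k = int(rng.integers(1, max_tokens + 1))
            picks = rng.choice(len(tokens), size=k, replace=False)
            mapping[g] = {tokens[int(i)] for i in picks}
    return mapping


def write_fixture(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the pipeline's standard text formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": outdir / "network.tsv",
        "expression": outdir / "expression.tsv",
        "groups": outdir / "groups.tsv",
        "gaf": outdir / "annotations.gaf",
        "obo": outdir / "go.obo",
        "gmt": outdir / "pathways.gmt",
        "families": outdir / "families.tsv",
        "localization": outdir / "localization.tsv",
        "targets": outdir / "targets.txt",
        "candidates": outdir / "candidates.txt",
        "positives": outdir / "positives.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "spec": outdir / "fixture_spec.json",
    }
    formats_io.write_edge_list(bundle.network, paths["network"])
    formats_io.write_expression(bundle.expression, paths["expression"], paths["groups"])
    formats_io.write_gaf(bundle.annotations, paths["gaf"])
    formats_io.write_obo(bundle.go_graph, paths["obo"])
    formats_io.write_gmt(bundle.pathways, paths["gmt"])
    formats_io.write_pair_map(bundle.family_map, paths["families"])
    formats_io.write_pair_map(bundle.localization_map, paths["localization"])
    formats_io.write_target_list(bundle.targets, paths["targets"])
    formats_io.write_target_list(bundle.candidates, paths["candidates"])
    with open(paths["positives"], "w") as fh:
        for u, v in bundle.positives:
            fh.write(f"{u}\t{v}\n")
    paths["ground_truth"].write_text(json.dumps(bundle.ground_truth, indent=1, sort_keys=True) + "\n")
    paths["spec"].write_text(json.dumps(dataclasses.asdict(bundle.spec), indent=1, sort_keys=True) + "\n")
    return paths


def fixture_truth_check(bundle: SyntheticBundle) -> dict[str, bool]:
    """Verify the planted structure actually holds in the generated data."""
    spec = bundle.spec
    gt = bundle.ground_truth
    checks: dict[str, bool] = {}

    ok = True
    for cand, path in gt["planted_paths"].items():
        for u, v in zip(path, path[1:]):
            ok &= bundle.network.has_edge(u, v)
        try:
            d = nx.shortest_path_length(bundle.network, gt["driver"], cand)
        except nx.NetworkXNoPath:
            ok = False
            continue
        ok &= d <= spec.path_len
    checks["planted_paths_within_bound"] = bool(ok)

    checks["targets_in_universe"] = set(bundle.targets) <= set(bundle.expression.genes)
    checks["true_targets_are_targets"] = set(gt["true_targets"]) <= set(bundle.targets)

    # empirical vs implied correlations, Fisher-z 3 SE tolerance
    coexpr = pearson_map(bundle.expression)
    n = len(bundle.expression.samples)
    se_z = 1.0 / math.sqrt(n - 3)
    loadings = gt["loadings"]
    noise = gt["noise_sigma"]

    def close(a: str, b: str) -> bool:
        implied = implied_correlation(loadings.get(a, {}), loadings.get(b, {}), noise, noise)
        implied = min(max(implied, -0.999), 0.999)
        observed = min(max(coexpr.r(a, b), -0.999), 0.999)
        return abs(np.arctanh(observed) - np.arctanh(implied)) <= 3 * se_z

    ok = True
    for path in gt["planted_paths"].values():
        for u, v in zip(path, path[1:]):
            ok &= close(u, v)
    checks["edge_correlations_match"] = bool(ok)

    planted_path = gt["planted_paths"][gt["planted_candidate"]]
    ok = True
    for g in planted_path[1:]:
        for t in gt["true_targets"]:
            ok &= close(g, t)
    checks["target_correlations_match"] = bool(ok)

    act = activity(bundle.expression)
    t_vals = [abs(act.t_of(g)) for path in gt["planted_paths"].values() for g in path[1:]]
    checks["path_genes_differentially_expressed"] = bool(
        np.median(t_vals) > spec.activity_t / 2
    )
    return checks
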