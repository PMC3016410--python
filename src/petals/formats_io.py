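"""Readers and writers for every external format the pipeline touches.

All identifiers live in one shared, case-sensitive namespace: the same
string token denotes the same gene/protein across the interaction
network, the expression matrix, annotations, and target lists.  No ID
mapping is performed here.

Interaction networks are :class:`networkx.Graph` instances whose edges
carry two attributes:

``observation_count``
    non-negative integer; number of independent observations supporting
    the interaction (0 for imputed edges).
``provenance``
    ``"observed"`` or ``"imputed"``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

OBSERVED = "observed"
IMPUTED = "imputed"

PETAL_FORMATS = ("graphml", "sif", "json")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# expression bundles
# ---------------------------------------------------------------------------


@dataclass
class ExpressionBundle:
    """Genes x samples expression matrix with WT/MT sample groups."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    groups: list[str]  # per-sample, "WT" or "MT", aligned with ``samples``

    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(self.groups) != len(self.samples):
            raise FormatError("group labels do not align with samples")
        bad = sorted(set(self.groups) - {"WT", "MT"})
        if bad:
            raise FormatError(f"unknown group labels: {bad}")
        seen: set[str] = set()
        for g in self.genes:
            if g in seen:
                raise FormatError(f"duplicate gene row {g!r}")
            seen.add(g)
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_wt(self) -> int:
        return sum(1 for g in self.groups if g == "WT")

    @property
    def n_mt(self) -> int:
        return sum(1 for g in self.groups if g == "MT")

    def group_values(self, group: str) -> np.ndarray:
        cols = [i for i, g in enumerate(self.groups) if g == group]
        return self.values[:, cols]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def row(self, gene: str) -> np.ndarray:
        return self.values[self._index[gene]]


def read_expression(matrix_path: str | Path, groups_path: str | Path) -> ExpressionBundle:
    """Read a genes x samples TSV plus its sample-group sidecar.

    The matrix header row lists sample IDs; the first column holds gene
    IDs.  The sidecar has two columns: sample ID and ``WT``/``MT``.
    """
    matrix_path, groups_path = Path(matrix_path), Path(groups_path)
    group_of: dict[str, str] = {}
    for lineno, line in enumerate(_data_lines(groups_path), start=1):
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{groups_path}:{lineno}: expected 2 columns, got {len(parts)}")
        sample, grp = parts
        group_of[sample] = grp

    with open(matrix_path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{matrix_path}: empty matrix file")
        samples = header.split("\t")[1:]
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(samples) + 1:
                raise FormatError(
                    f"{matrix_path}:{lineno}: expected {len(samples) + 1} columns, got {len(parts)}"
                )
            gene = parts[0]
            if gene in set(genes):
                raise FormatError(f"{matrix_path}:{lineno}: duplicate gene row {gene!r}")
            genes.append(gene)
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise FormatError(f"{matrix_path}:{lineno}: non-numeric value ({exc})") from exc

    missing = [s for s in samples if s not in group_of]
    if missing:
        raise FormatError(f"{groups_path}: samples missing group labels: {missing}")
    groups = [group_of[s] for s in samples]
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(samples)))
    return ExpressionBundle(genes=genes, samples=samples, values=values, groups=groups)


def write_expression(bundle: ExpressionBundle, matrix_path: str | Path, groups_path: str | Path) -> None:
    with open(matrix_path, "w") as fh:
        fh.write("gene\t" + "\t".join(bundle.samples) + "\n")
        for gene, row in zip(bundle.genes, bundle.values):
            fh.write(gene + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")
    with open(groups_path, "w") as fh:
        for sample, grp in zip(bundle.samples, bundle.groups):
            fh.write(f"{sample}\t{grp}\n")


# ---------------------------------------------------------------------------
# interaction networks
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path, dialect: str = "auto") -> nx.Graph:
    """Read an undirected edge list TSV into an interaction network.

    Columns: geneA, geneB[, observation_count[, provenance]].  Repeated
    lines for the same unordered pair sum their observation counts.
    Self-loop lines are skipped with a warning.  Whitespace-separated
    files are accepted when ``dialect="auto"``.
    """
    path = Path(path)
    graph = nx.Graph()
    for lineno, line in enumerate(_data_lines(path), start=1):
        parts = line.split("\t") if "\t" in line else line.split()
        if dialect == "tsv":
            parts = line.split("\t")
        if len(parts) < 2 or len(parts) > 4:
            raise FormatError(f"{path}:{lineno}: expected 2-4 columns, got {len(parts)}")
        a, b = parts[0], parts[1]
        if not a or not b:
            raise FormatError(f"{path}:{lineno}: empty gene identifier")
        if a == b:
            logger.warning("%s:%d: skipping self-loop %s-%s", path, lineno, a, b)
            continue
        count = 1
        if len(parts) >= 3:
            try:
                count = int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad observation count {parts[2]!r}") from exc
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative observation count")
        provenance = parts[3] if len(parts) == 4 else OBSERVED
        if provenance not in (OBSERVED, IMPUTED):
            raise FormatError(f"{path}:{lineno}: unknown provenance {provenance!r}")
        if graph.has_edge(a, b):
            graph[a][b]["observation_count"] += count
        else:
            graph.add_edge(a, b, observation_count=count, provenance=provenance)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write a network as a 4-column TSV (round-trips through read_edge_list)."""
    with open(path, "w") as fh:
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
            u, v = sorted((u, v))
            fh.write(
                f"{u}\t{v}\t{data.get('observation_count', 1)}\t{data.get('provenance', OBSERVED)}\n"
            )


def as_edge_key(u: str, v: str) -> tuple[str, str]:
    """Canonical (sorted) key for an undirected edge."""
    return (u, v) if u <= v else (v, u)


# ---------------------------------------------------------------------------
# GO annotations (GAF 2.x) and GO graph (OBO 1.2)
# ---------------------------------------------------------------------------


def read_gaf(path: str | Path, aspect: str = "P") -> dict[str, set[str]]:
    """Read (DB Object Symbol, GO ID) pairs for one aspect from a GAF file.

    Only the biological-process aspect (``P``) is kept by default.
    Rows with a NOT qualifier are dropped.
    """
    path = Path(path)
    annotations: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: expected >=9 GAF columns, got {len(parts)}")
            symbol, qualifier, go_id, row_aspect = parts[2], parts[3], parts[4], parts[8]
            if row_aspect != aspect:
                continue
            if "NOT" in qualifier.split("|"):
                continue
            annotations.setdefault(symbol, set()).add(go_id)
    return annotations


def write_gaf(annotations: Mapping[str, Iterable[str]], path: str | Path, aspect: str = "P") -> None:
    """Write a minimal GAF 2.1 file (symbol + GO ID + aspect columns filled)."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for symbol in sorted(annotations):
            for term in sorted(annotations[symbol]):
                cols = ["DB", symbol, symbol, "", term, "REF:0", "IEA", "", aspect,
                        "", "", "protein", "taxon:10090", "20100101", "DB", "", ""]
                fh.write("\t".join(cols) + "\n")


def read_obo(path: str | Path, namespace: str | None = None) -> nx.DiGraph:
    """Parse a (subset of the) OBO 1.2 term graph.

    Returns a DAG with edges pointing child -> parent for ``is_a`` and
    ``relationship: part_of`` lines.  Obsolete terms are skipped.  When
    ``namespace`` is given, only terms in that namespace are kept.
    """
    path = Path(path)
    graph = nx.DiGraph()
    term: dict[str, list[str]] = {}
    in_term = False

    def _flush() -> None:
        if not term or "id" not in term:
            return
        if term.get("is_obsolete") == ["true"]:
            return
        ns = term.get("namespace", [None])[0]
        if namespace is not None and ns is not None and ns != namespace:
            return
        tid = term["id"][0]
        graph.add_node(tid, name=term.get("name", [""])[0], namespace=ns)
        for parent in term.get("is_a", []):
            graph.add_edge(tid, parent, relation="is_a")
        for parent in term.get("part_of", []):
            graph.add_edge(tid, parent, relation="part_of")

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("["):
                _flush()
                term = {}
                in_term = line == "[Term]"
                continue
            if not in_term or not line:
                continue
            if ":" not in line:
                continue
            key, _, value = line.partition(":")
            value = value.split("!")[0].strip()
            if key == "relationship":
                rel, _, target = value.partition(" ")
                if rel == "part_of":
                    term.setdefault("part_of", []).append(target.strip())
            else:
                term.setdefault(key, []).append(value)
    _flush()
    if not nx.is_directed_acyclic_graph(graph):
        raise FormatError(f"{path}: GO graph contains a cycle")
    return graph


def write_obo(graph: nx.DiGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for tid in sorted(graph.nodes):
            data = graph.nodes[tid]
            fh.write("[Term]\n")
            fh.write(f"id: {tid}\n")
            if data.get("name"):
                fh.write(f"name: {data['name']}\n")
            if data.get("namespace"):
                fh.write(f"namespace: {data['namespace']}\n")
            for _, parent, edata in sorted(graph.out_edges(tid, data=True)):
                if edata.get("relation", "is_a") == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# gene sets, pair maps, target lists
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT pathway gene sets: name, description, members..."""
    path = Path(path)
    pathways: dict[str, list[str]] = {}
    for lineno, line in enumerate(_data_lines(path), start=1):
        parts = line.split("\t")
        if len(parts) < 4:  # name + description + >=2 members
            raise FormatError(f"{path}:{lineno}: pathway needs a description and >=2 members")
        name, members = parts[0], [m for m in parts[2:] if m]
        if name in pathways:
            raise FormatError(f"{path}:{lineno}: duplicate pathway {name!r}")
        pathways[name] = members
    return pathways


def write_gmt(pathways: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(pathways):
            fh.write("\t".join([name, "na", *pathways[name]]) + "\n")


def read_pair_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV mapping gene -> token (family or compartment)."""
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    for lineno, line in enumerate(_data_lines(path), start=1):
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise FormatError(f"{path}:{lineno}: expected 'gene<TAB>token'")
        mapping.setdefault(parts[0], set()).add(parts[1])
    return mapping


def write_pair_map(mapping: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(mapping):
            for token in sorted(mapping[gene]):
                fh.write(f"{gene}\t{token}\n")


def read_target_list(path: str | Path) -> list[str]:
    """Read a one-gene-per-line target list; deduplicates, keeps order."""
    path = Path(path)
    targets: list[str] = []
    seen: set[str] = set()
    for line in _data_lines(path):
        gene = line.strip()
        if gene and gene not in seen:
            targets.append(gene)
            seen.add(gene)
    if not targets:
        raise FormatError(f"{path}: empty target list")
    return targets


def write_target_list(targets: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in targets:
            fh.write(gene + "\n")


# ---------------------------------------------------------------------------
# petals
# ---------------------------------------------------------------------------


def write_petal(petal, path: str | Path, format: str = "json") -> None:
    """Serialize a petal subnetwork; round-trip safe for nodes/edges/provenance.

    ``format`` is one of ``graphml``, ``sif``, or ``json``.  The SIF
    dialect uses the edge provenance as the interaction type.  Only the
    JSON format preserves the contributing paths and their scores.
    """
    path = Path(path)
    if format == "json":
        payload = {
            "candidate": petal.candidate,
            "nodes": sorted(petal.graph.nodes),
            "edges": [
                {
                    "source": min(u, v),
                    "target": max(u, v),
                    "provenance": d.get("provenance", OBSERVED),
                    "observation_count": int(d.get("observation_count", 1)),
                }
                for u, v, d in sorted(
                    petal.graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))
                )
            ],
            "paths": [
                {
                    "path": list(s.path),
                    "rule_count": s.rule_count,
                    "mean_abs_coexpr": s.mean_abs_coexpr,
                    "p_value": s.p_value,
                }
                for s in petal.paths
            ],
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v, d in sorted(petal.graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
                u, v = sorted((u, v))
                fh.write(f"{u}\t{d.get('provenance', OBSERVED)}\t{v}\n")
            for node in sorted(nx.isolates(petal.graph)):
                fh.write(f"{node}\n")
    elif format == "graphml":
        graph = petal.graph.copy()
        graph.graph["candidate"] = petal.candidate
        nx.write_graphml(graph, path)
    else:
        raise FormatError(f"unknown petal format {format!r}; choose from {PETAL_FORMATS}")


def read_petal(path: str | Path, format: str = "json"):
    """Inverse of :func:`write_petal` (paths recovered from JSON only)."""
    from petals.blossom import Petal
    from petals.go_rules import PathScore

    path = Path(path)
    if format == "json":
        payload = json.loads(path.read_text())
        graph = nx.Graph()
        graph.add_nodes_from(payload["nodes"])
        for e in payload["edges"]:
            graph.add_edge(
                e["source"], e["target"],
                provenance=e["provenance"], observation_count=e["observation_count"],
            )
        paths = [
            PathScore(
                path=tuple(p["path"]),
                rule_count=p["rule_count"],
                mean_abs_coexpr=p["mean_abs_coexpr"],
                p_value=p["p_value"],
            )
            for p in payload["paths"]
        ]
        return Petal(candidate=payload["candidate"], graph=graph, paths=paths)
    if format == "sif":
        graph = nx.Graph()
        candidate = None
        for line in _data_lines(path):
            parts = line.split("\t")
            if len(parts) == 1:
                graph.add_node(parts[0])
            elif len(parts) == 3:
                graph.add_edge(parts[0], parts[2], provenance=parts[1],
                               observation_count=0 if parts[1] == IMPUTED else 1)
            else:
                raise FormatError(f"{path}: malformed SIF line {line!r}")
        return Petal(candidate=candidate, graph=graph, paths=[])
    if format == "graphml":
        raw = nx.read_graphml(path)
        graph = nx.Graph()
        graph.add_nodes_from(raw.nodes)
        for u, v, d in raw.edges(data=True):
            graph.add_edge(u, v, provenance=d.get("provenance", OBSERVED),
                           observation_count=int(d.get("observation_count", 1)))
        return Petal(candidate=raw.graph.get("candidate"), graph=graph, paths=[])
    raise FormatError(f"unknown petal format {format!r}; choose from {PETAL_FORMATS}")


def _data_lines(path: Path):
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line and not line.startswith("#"):
                yield line
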