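"""Pearson coexpression, differential-expression activity, and their product.

Activity of a gene is the absolute Welch-style t statistic of mutant vs
wild-type expression, scaled to [0, 1] by the cohort maximum.  Active
coexpression multiplies each gene's coexpression row by its activity, so
correlation only counts where the source gene is differentially
expressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from petals.formats_io import ExpressionBundle

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionMap:
    """Symmetric Pearson correlation lookup over a gene universe."""

    genes: list[str]
    matrix: np.ndarray  # genes x genes, diag == 1
    constant_genes: frozenset[str] = frozenset()

    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def r(self, a: str, b: str) -> float:
        return float(self.matrix[self._index[a], self._index[b]])

    def rows(self, row_genes: Sequence[str], col_genes: Sequence[str] | None = None) -> np.ndarray:
        ridx = [self._index[g] for g in row_genes]
        if col_genes is None:
            return self.matrix[ridx, :]
        cidx = [self._index[g] for g in col_genes]
        return self.matrix[np.ix_(ridx, cidx)]


@dataclass
class ActivityVector:
    """Per-gene t statistic and scaled absolute activity alpha."""

    genes: list[str]
    t: np.ndarray
    alpha: np.ndarray

    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.genes)}

    def t_of(self, gene: str) -> float:
        return float(self.t[self._index[gene]])

    def alpha_of(self, gene: str) -> float:
        return float(self.alpha[self._index[gene]])


@dataclass
class ActiveCoexpression:
    """Matrix of activity-weighted correlations r'[i, x] = alpha_i * r(i, x)."""

    row_genes: list[str]
    col_genes: list[str]
    matrix: np.ndarray

    def vec(self, exclude_self: bool = True) -> np.ndarray:
        """Vectorize the matrix, dropping row-gene == column-gene entries."""
        if not exclude_self:
            return self.matrix.ravel()
        keep = np.ones(self.matrix.shape, dtype=bool)
        col_index = {g: j for j, g in enumerate(self.col_genes)}
        for i, g in enumerate(self.row_genes):
            j = col_index.get(g)
            if j is not None:
                keep[i, j] = False
        return self.matrix[keep]


def pearson_map(expression: ExpressionBundle, gene_subset: Iterable[str] | None = None) -> CoexpressionMap:
    """Pairwise Pearson correlation across all samples (WT and MT pooled).

    Genes with zero variance get r = 0 against every partner (flagged in
    ``constant_genes``) so downstream vectorization never sees NaN; the
    diagonal stays 1.
    """
    if len(expression.samples) < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    if gene_subset is None:
        genes = list(expression.genes)
        values = expression.values
    else:
        genes = [g for g in gene_subset]
        missing = [g for g in genes if g not in expression]
        if missing:
            raise KeyError(f"genes absent from expression data: {missing}")
        values = np.vstack([expression.row(g) for g in genes])

    sd = values.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = np.corrcoef(values)
    matrix = np.atleast_2d(matrix)
    matrix[constant, :] = 0.0
    matrix[:, constant] = 0.0
    np.fill_diagonal(matrix, 1.0)
    matrix = np.clip(matrix, -1.0, 1.0)
    return CoexpressionMap(
        genes=genes,
        matrix=matrix,
        constant_genes=frozenset(g for g, c in zip(genes, constant) if c),
    )


def activity(expression: ExpressionBundle) -> ActivityVector:
    """Welch t of MT vs WT per gene, and alpha = |t| / max_j |t_j|.

    Uses unbiased (n-1) sample variances.  A gene whose pooled variance
    term is zero gets t = 0 (flat genes must not poison the maximum).
    If every t is zero, every alpha is zero.
    """
    if expression.n_wt < 2 or expression.n_mt < 2:
        raise ValueError(
            f"need >=2 samples per group, got WT={expression.n_wt} MT={expression.n_mt}"
        )
    wt = expression.group_values("WT")
    mt = expression.group_values("MT")
    n_wt, n_mt = wt.shape[1], mt.shape[1]
    num = mt.mean(axis=1) - wt.mean(axis=1)
    denom = np.sqrt(mt.var(axis=1, ddof=1) / n_mt + wt.var(axis=1, ddof=1) / n_wt)
    t = np.zeros_like(num)
    nonzero = denom > 0
    t[nonzero] = num[nonzero] / denom[nonzero]
    degenerate = (~nonzero) & (num != 0)
    if degenerate.any():
        logger.warning(
            "%d genes have zero within-group variance but unequal means; t set to 0",
            int(degenerate.sum()),
        )
    max_abs = np.abs(t).max() if len(t) else 0.0
    alpha = np.abs(t) / max_abs if max_abs > 0 else np.zeros_like(t)
    return ActivityVector(genes=list(expression.genes), t=t, alpha=alpha)


def active_coexpression(
    activity_vector: ActivityVector,
    coexpr_map: CoexpressionMap,
    petal_nodes: Iterable[str],
    target_set: Sequence[str],
) -> ActiveCoexpression:
    """Build R'(P, X) with rows = petal genes, columns = target gene set.

    Petal genes absent from the coexpression universe are dropped with a
    warning; an empty surviving row set is an error.
    """
    rows = sorted(set(petal_nodes))
    surviving = [g for g in rows if g in coexpr_map]
    dropped = [g for g in rows if g not in coexpr_map]
    if dropped:
        logger.warning("dropping petal genes absent from the array: %s", dropped)
    if not surviving:
        raise ValueError("no petal gene is present on the expression array")
    missing_targets = [g for g in target_set if g not in coexpr_map]
    if missing_targets:
        raise KeyError(f"target genes absent from coexpression universe: {missing_targets}")
    alpha = np.array([activity_vector.alpha_of(g) for g in surviving])
    r = coexpr_map.rows(surviving, list(target_set))
    return ActiveCoexpression(
        row_genes=surviving,
        col_genes=list(target_set),
        matrix=alpha[:, None] * r,
    )
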