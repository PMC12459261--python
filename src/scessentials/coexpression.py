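"""Permutation-null Spearman co-expression of gene pairs per cell type.

The correlation statistic is Spearman's rho computed as the Pearson
correlation of midranks.  Significance comes from a permutation null shared
by every pair with the same number of cells: the distribution of rho
between a fixed rank vector and random rank permutations.  When n! <= 5040
(n <= 7) the null is enumerated exhaustively and p-values are exact
(count / n!); otherwise ``iters`` random permutations are drawn and
p = (1 + #{|null| >= |rho|}) / (iters + 1), so the attainable p floor is
1/(iters+1).  BH correction is applied across all pairs of a cell type.

Genes poorly detected in a cell type distort rank correlations through
excess zeroes, so pairs are restricted to genes with nonzero expression in
at least ``min_nonzero_frac`` (default 90%) of the cell type's cells.
"""

from __future__ import annotations

import dataclasses
import math
from itertools import permutations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import ExpressionAtlas, ValidationError

__all__ = [
    "NullDistribution",
    "expression_fraction_filter",
    "spearman_rho",
    "permutation_null",
    "correlate_pairs",
    "top_pairs",
    "compare_pair_counts",
    "kruskal_wallis",
]

#: enumerate the exact null when n! is at most this
EXHAUSTIVE_LIMIT = 5040
#: tie guard so float roundoff at exactly-equal rho cannot flip a count;
#: null rho values at small n are spaced far wider than this
_TIE_EPS = 1e-12


def expression_fraction_filter(atlas: ExpressionAtlas, cell_type: str,
                               min_nonzero_frac: float = 0.9) -> set[str]:
    """Genes with nonzero expression in >= ``min_nonzero_frac`` of the
    cell type's cells (well-detected genes suitable for rank correlation)."""
    if not 0.0 <= min_nonzero_frac <= 1.0:
        raise ValidationError("min_nonzero_frac outside [0,1]")
    sub = atlas.cells_of_type(cell_type)
    counts = sub.counts
    if sp.issparse(counts):
        frac = np.asarray((counts != 0).sum(axis=1)).ravel() / sub.n_cells
    else:
        frac = (counts != 0).sum(axis=1) / sub.n_cells
    return {g for g, f in zip(sub.gene_ids, frac) if f >= min_nonzero_frac}


def spearman_rho(x, y) -> float:
    """Spearman correlation: Pearson on midranks.  NaN if either vector is
    constant (zero rank variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


@dataclasses.dataclass
class NullDistribution:
    """Shared permutation null of Spearman rho for a given cell count."""

    n_cells: int
    values: np.ndarray          # sorted
    seed: int | None
    exhaustive: bool

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))
        self._abs_sorted = np.sort(np.abs(self.values))

    @property
    def iters(self) -> int:
        return self.values.size

    def p_value(self, rho: float) -> float:
        """Two-sided permutation p for an observed rho."""
        if np.isnan(rho):
            return float("nan")
        count = self.values.size - np.searchsorted(
            self._abs_sorted, abs(rho) - _TIE_EPS, side="left")
        if self.exhaustive:
            return count / self.values.size
        return (1 + count) / (self.values.size + 1)


def _rho_of_ranks(fixed: np.ndarray, perm: np.ndarray) -> float:
    n = fixed.size
    # ranks 1..n: closed-form moments
    mean = (n + 1) / 2.0
    ss = n * (n * n - 1) / 12.0
    return float((fixed - mean) @ (perm - mean) / ss)


def permutation_null(n_cells: int, iters: int = 10_000,
                     seed: int | None = 123441,
                     exhaustive: bool | None = None) -> NullDistribution:
    """Null rho distribution between a fixed rank vector and permutations.

    ``exhaustive=None`` auto-enables exact enumeration when n! <= 5040.
    """
    if n_cells < 3:
        raise ValidationError("n_cells must be >= 3")
    if exhaustive is None:
        exhaustive = math.factorial(n_cells) <= EXHAUSTIVE_LIMIT
    fixed = np.arange(1, n_cells + 1, dtype=float)
    if exhaustive:
        vals = np.array([
            _rho_of_ranks(fixed, np.asarray(p, dtype=float))
            for p in permutations(range(1, n_cells + 1))
        ])
        return NullDistribution(n_cells, vals, seed=None, exhaustive=True)
    if iters < 100:
        raise ValidationError("iters must be >= 100 (p floor too unstable)")
    rng = np.random.default_rng(seed)
    vals = np.empty(iters)
    for i in range(iters):
        vals[i] = _rho_of_ranks(fixed, rng.permutation(fixed))
    return NullDistribution(n_cells, vals, seed=seed, exhaustive=False)


def _rank_matrix(dense: np.ndarray) -> np.ndarray:
    return stats.rankdata(dense, axis=1)


def correlate_pairs(atlas: ExpressionAtlas, cell_type: str,
                    genes: set[str] | None = None, iters: int = 10_000,
                    seed: int | None = 123441, alpha: float = 0.05,
                    min_nonzero_frac: float = 0.9,
                    null: NullDistribution | None = None) -> pd.DataFrame:
    """All-pairs Spearman correlations with permutation p and BH q.

    Returns a DataFrame with columns
    ``cell_type, gene_a, gene_b, n_cells, rho, p_value, fdr_q, significant``
    (pairs stored lexicographically, gene_a < gene_b).  Constant genes are
    skipped.  A precomputed ``null`` (matching ``n_cells``) can be supplied
    to share it across cell types.
    """
    keep = expression_fraction_filter(atlas, cell_type, min_nonzero_frac)
    if genes is not None:
        keep &= set(genes)
    keep_sorted = sorted(keep)
    if len(keep_sorted) < 2:
        raise ValidationError(
            f"fewer than 2 genes pass the expression filter in {cell_type!r}")
    sub = atlas.cells_of_type(cell_type).subset_genes(keep_sorted)
    order = np.argsort(np.asarray(sub.gene_ids, dtype=object))
    names = [sub.gene_ids[i] for i in order]
    dense = sub.dense()[order, :]
    ranks = _rank_matrix(dense)
    const = np.ptp(ranks, axis=1) == 0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks)
    if null is None:
        null = permutation_null(sub.n_cells, iters=iters, seed=seed)
    elif null.n_cells != sub.n_cells:
        raise ValidationError("supplied null has wrong n_cells")
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if const[i] or const[j]:
                continue
            rho = float(corr[i, j])
            rows.append((cell_type, names[i], names[j], sub.n_cells, rho,
                         null.p_value(rho)))
    out = pd.DataFrame(rows, columns=["cell_type", "gene_a", "gene_b",
                                      "n_cells", "rho", "p_value"])
    if out.empty:
        out["fdr_q"] = []
        out["significant"] = []
        return out
    _, q, _, _ = multipletests(out["p_value"].to_numpy(), method="fdr_bh")
    out["fdr_q"] = q
    out["significant"] = out["fdr_q"] < alpha
    return out


def top_pairs(pairs: pd.DataFrame, k: int = 100,
              min_n: int = 10) -> pd.DataFrame | None:
    """Top-|rho| significant pairs of one cell type.

    Keeps the ``k`` most correlated pairs (positive or inverse); if the
    significant count is in (min_n, k] all are kept; if it is <= min_n the
    cell type is dropped (returns None).
    """
    sig = pairs[pairs["significant"]] if "significant" in pairs.columns else pairs
    if len(sig) <= min_n:
        return None
    ordered = sig.assign(_abs=sig["rho"].abs()).sort_values(
        ["_abs", "gene_a", "gene_b"], ascending=[False, True, True],
        kind="stable").drop(columns="_abs")
    return ordered.head(k).reset_index(drop=True)


def compare_pair_counts(count_a: int, total_a: int, count_b: int,
                        total_b: int) -> tuple[float, float]:
    """Two-proportion z-test (pooled variance, no continuity correction)."""
    if total_a <= 0 or total_b <= 0:
        raise ValidationError("totals must be positive")
    if count_a > total_a or count_b > total_b:
        raise ValidationError("count exceeds total")
    p_pool = (count_a + count_b) / (total_a + total_b)
    var = p_pool * (1 - p_pool) * (1 / total_a + 1 / total_b)
    if var == 0:
        return 0.0, 1.0
    z = (count_a / total_a - count_b / total_b) / math.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H with midrank tie correction; chi^2 p on k-1 d.f.

    All-identical data is the degenerate no-signal case: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size == 0:
            raise ValidationError("empty group")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)
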