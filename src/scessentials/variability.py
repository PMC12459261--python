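"""Cell-to-cell variability decomposition.

Per cell type, each gene's total variance of log-normalised expression is
split into a mean-variance trend (the component expected from expression
level alone, mostly technical in scRNA-seq) and a biological residual
(total minus trend).  Negative residuals mean the gene is *more* stable
than expected at its expression level.  Donor/mouse identity acts as a
blocking covariate: statistics are computed within each donor block and
combined with weights proportional to the block's variance degrees of
freedom (n_b - 1).

The trend estimator is a sliding-window median over genes ordered by mean:
deterministic, robust, and exactly reproducible by a brute-force oracle.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model import ExpressionAtlas, ValidationError

__all__ = [
    "normalize_log",
    "fit_mean_variance_trend",
    "biological_component",
    "variability_table",
]


def normalize_log(atlas: ExpressionAtlas) -> ExpressionAtlas:
    """Median-library normalisation followed by log2(x+1).

    Each cell is scaled to the median library size (scale factor =
    median_library / cell_library), then log2(x+1) transformed.  Cells with
    zero total counts make scaling undefined and raise, listing the cells.
    """
    counts = atlas.counts
    if sp.issparse(counts):
        lib = np.asarray(counts.sum(axis=0)).ravel()
    else:
        lib = counts.sum(axis=0).astype(float)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        ids = atlas.cell_meta["cell_id"].iloc[zero].tolist()
        raise ValidationError(f"cells with zero total counts: {ids}")
    median_lib = float(np.median(lib))
    scale = median_lib / lib
    if sp.issparse(counts):
        mat = counts.tocsc(copy=True).astype(float)
        mat = mat.multiply(scale[None, :]).tocsr()
        mat.data = np.log2(mat.data + 1.0)
    else:
        mat = np.log2(counts * scale[None, :] + 1.0)
    return ExpressionAtlas(list(atlas.gene_ids), mat, atlas.cell_meta.copy(),
                           normalized=True)


def fit_mean_variance_trend(means: np.ndarray, variances: np.ndarray,
                            window: int = 51) -> np.ndarray:
    """Sliding-window median trend of variance against mean.

    Genes are sorted by mean; the trend at each position is the median of
    variances in a centred window of ``window`` genes (clamped at the edges
    so the window keeps its full width), then mapped back to input order.
    ``window`` is forced odd and shrunk to the number of genes when larger;
    with fewer genes than the window the trend is the global median.
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if means.shape != variances.shape or means.ndim != 1:
        raise ValidationError("means and variances must be equal-length 1-D vectors")
    if np.isnan(means).any() or np.isnan(variances).any():
        raise ValidationError("NaN in means or variances")
    n = means.size
    if n == 0:
        return np.empty(0)
    w = min(int(window), n)
    if w % 2 == 0:
        w -= 1
    w = max(w, 1)
    half = w // 2
    order = np.argsort(means, kind="stable")
    v_sorted = variances[order]
    trend_sorted = np.empty(n)
    for i in range(n):
        lo = min(max(0, i - half), n - w)
        trend_sorted[i] = np.median(v_sorted[lo:lo + w])
    trend = np.empty(n)
    trend[order] = trend_sorted
    return trend


def _block_moments(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = mat.mean(axis=1)
    var = mat.var(axis=1, ddof=1)
    return mean, var


def biological_component(atlas: ExpressionAtlas, cell_type: str,
                         block_key: str = "donor",
                         window: int = 51) -> pd.DataFrame:
    """Per-gene variability estimates within one cell type.

    Within each block (default: donor) of the cell type, the per-gene mean
    and variance of log-normalised expression are computed, a mean-variance
    trend is fitted, and the residual (total - trend) extracted.  Blocks
    with fewer than 2 cells are dropped with a warning; per-gene statistics
    are weighted averages over blocks with weights n_b - 1.

    Returns a DataFrame indexed by gene with columns
    ``mean, total, trend, bio_residual, n_blocks``.
    """
    if not atlas.normalized:
        warnings.warn("variability computed on non-normalised counts")
    sub = atlas.cells_of_type(cell_type)
    if sub.n_cells < 2:
        raise ValidationError(f"cell type {cell_type!r} has <2 cells")
    if block_key not in sub.cell_meta.columns:
        raise ValidationError(f"block column {block_key!r} absent from cell_meta")
    dense = sub.dense()
    weights, means, totals, trends = [], [], [], []
    for block, grp in sub.cell_meta.groupby(block_key, sort=True):
        idx = grp.index.to_numpy()
        if idx.size < 2:
            warnings.warn(f"block {block!r} in {cell_type!r} has <2 cells; dropped")
            continue
        mean, var = _block_moments(dense[:, idx])
        trend = fit_mean_variance_trend(mean, var, window=window)
        weights.append(idx.size - 1)
        means.append(mean)
        totals.append(var)
        trends.append(trend)
    if not weights:
        raise ValidationError(f"cell type {cell_type!r} has no usable blocks")
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    combine = lambda arrs: np.average(np.vstack(arrs), axis=0, weights=w)
    total = combine(totals)
    trend = combine(trends)
    # the weighted average of per-block (var - trend) equals total - trend;
    # computing it as the difference keeps the identity exact in floats
    out = pd.DataFrame(
        {
            "mean": combine(means),
            "total": total,
            "trend": trend,
            "bio_residual": total - trend,
            "n_blocks": len(weights),
        },
        index=pd.Index(atlas.gene_ids, name="gene"),
    )
    return out


def variability_table(atlas: ExpressionAtlas, block_key: str = "donor",
                      window: int = 51) -> pd.DataFrame:
    """Long-format variability estimates over every cell type in the atlas."""
    frames = []
    for ct in atlas.cell_types():
        try:
            est = biological_component(atlas, ct, block_key=block_key, window=window)
        except ValidationError:
            continue
        est = est.reset_index()
        est.insert(0, "cell_type", ct)
        frames.append(est)
    if not frames:
        raise ValidationError("no cell type had enough cells for variability")
    return pd.concat(frames, ignore_index=True)
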