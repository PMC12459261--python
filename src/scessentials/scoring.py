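"""Essentiality score and its multi-omic association tests.

The essentiality score combines the two characteristics of an essential
gene in single-cell data: non-cell-type-specificity and robustly high
detection.  For gene g,

    ES_g = mean_c d_{g,c} / (1 + m_g)

where d_{g,c} is the detection fraction in cell type c and m_g the number
of cell types listing g as a marker.  A gene detected everywhere with no
marker evidence scores 1; marker evidence divides the score down.  An
optional expression-magnitude factor (the gene's quantile of mean
expression) can be multiplied in for scores that also reward high level,
off by default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import kruskal_wallis, permutation_null, spearman_rho
from .data_model import (GDITable, MarkerTable, PeakTable, TSSAnnotation,
                         ValidationError)
from .filtering import DetectabilityReport

__all__ = [
    "essentiality_score",
    "gdi_variability_test",
    "gene_accessibility",
    "correlate_es_accessibility",
    "tf_enrichment",
]


def essentiality_score(report: DetectabilityReport, markers: MarkerTable,
                       expression_quantile: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene essentiality scores from a cell-type detectability report.

    Returns a DataFrame indexed by gene with columns ``mean_detection``,
    ``marker_evidence`` (m_g) and ``es``, sorted by descending es with ties
    broken by gene id.  ``expression_quantile`` (gene -> quantile of mean
    expression in (0,1]) optionally multiplies the score.
    """
    det = report.detection_matrix()
    if det.shape[1] < 1:
        raise ValidationError("detectability report covers no groups")
    mean_det = det.mean(axis=1)
    m = markers.marker_celltype_counts()
    m = m.reindex(mean_det.index).fillna(0).astype(int)
    es = mean_det / (1.0 + m)
    if expression_quantile is not None:
        missing = mean_det.index.difference(expression_quantile.index)
        if len(missing):
            warnings.warn(f"{len(missing)} genes lack an expression quantile; "
                          "factor treated as 1 for them")
        factor = expression_quantile.reindex(mean_det.index).fillna(1.0)
        es = es * factor
    out = pd.DataFrame({
        "mean_detection": mean_det,
        "marker_evidence": m,
        "es": es,
    })
    out.index.name = "gene"
    out = out.reset_index().sort_values(["es", "gene"], ascending=[False, True],
                                        kind="stable")
    return out.set_index("gene")


def gdi_variability_test(residuals: pd.Series, gdi: GDITable,
                         downsample_to: int | None = None, reps: int = 10,
                         seed: int = 123441) -> pd.DataFrame:
    """Kruskal-Wallis test of variability residuals across GDI categories,
    with the medium category repeatedly downsampled to balance group sizes.

    ``residuals`` maps gene -> biological residual.  ``downsample_to``
    defaults to the size of the high category.  Returns per-rep H and p plus
    a final row with the median p across reps.
    """
    groups = {}
    for cat in ("low", "medium", "high"):
        genes = [g for g in gdi.genes_in(cat) if g in residuals.index]
        if not genes:
            raise ValidationError(f"GDI category {cat!r} has no genes with residuals")
        groups[cat] = residuals.loc[genes]
    if downsample_to is None:
        downsample_to = len(groups["high"])
    if downsample_to > len(groups["medium"]):
        raise ValidationError("downsample_to exceeds the medium category size")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        idx = rng.choice(len(groups["medium"]), size=downsample_to, replace=False)
        med = groups["medium"].iloc[np.sort(idx)]
        h, p = kruskal_wallis([groups["low"].to_numpy(), med.to_numpy(),
                               groups["high"].to_numpy()])
        rows.append({"rep": rep, "H": h, "p_value": p})
    out = pd.DataFrame(rows)
    out.loc[len(out)] = {"rep": "median", "H": out["H"].median(),
                         "p_value": out["p_value"].median()}
    return out


def _window_overlaps(start, end, tss, window_bp) -> np.ndarray:
    """Peak [start,end) vs promoter window [tss-w, tss+w); window 0 means
    the peak must contain the TSS position itself."""
    if window_bp == 0:
        return (start <= tss) & (tss < end)
    return (start < tss + window_bp) & (end > tss - window_bp)


def gene_accessibility(peaks: PeakTable, tss: TSSAnnotation,
                       window_bp: int = 1000,
                       aggregate: str = "mean") -> pd.DataFrame:
    """Promoter accessibility per gene per cell type.

    A peak is assigned to a gene iff it intersects the +/- ``window_bp``
    window around the gene's TSS (same chromosome).  Per gene and cell type
    the assigned peak values are aggregated by ``mean`` (default) or
    ``sum``; genes with no assigned peak are omitted.  Output columns:
    gene, cell_type, accessibility, n_peaks.
    """
    if window_bp < 0:
        raise ValidationError("window_bp must be >= 0")
    if aggregate not in ("mean", "sum"):
        raise ValidationError("aggregate must be 'mean' or 'sum'")
    value_cols = peaks.value_columns()
    rows = []
    for trow in tss.table.itertuples(index=False):
        chrom_peaks = peaks.table[peaks.table["chrom"] == trow.chrom]
        if chrom_peaks.empty:
            continue
        hit = _window_overlaps(chrom_peaks["start"].to_numpy(),
                               chrom_peaks["end"].to_numpy(),
                               trow.tss, window_bp)
        assigned = chrom_peaks[hit]
        if assigned.empty:
            continue
        for ct in value_cols:
            vals = assigned[ct].to_numpy(dtype=float)
            agg = vals.mean() if aggregate == "mean" else vals.sum()
            rows.append({"gene": trow.gene, "cell_type": ct,
                         "accessibility": agg, "n_peaks": len(vals)})
    return pd.DataFrame(rows, columns=["gene", "cell_type",
                                       "accessibility", "n_peaks"])


def correlate_es_accessibility(es: pd.DataFrame, acc: pd.DataFrame,
                               cell_type: str, iters: int = 10_000,
                               seed: int = 123441) -> tuple[float, float]:
    """Spearman correlation between ES and promoter accessibility over the
    genes shared by both tables in one cell type, with a permutation p."""
    acc_ct = acc[acc["cell_type"] == cell_type].set_index("gene")["accessibility"]
    shared = es.index.intersection(acc_ct.index).sort_values()
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} genes shared between ES and accessibility")
    rho = spearman_rho(es.loc[shared, "es"].to_numpy(), acc_ct.loc[shared].to_numpy())
    null = permutation_null(len(shared), iters=iters, seed=seed)
    return rho, null.p_value(rho)


def tf_enrichment(gene_set: set[str], tf_list: set[str],
                  background_size: int) -> tuple[int, float]:
    """Upper-tail hypergeometric p for transcription-factor over-representation.

    Overlap k between ``gene_set`` and ``tf_list`` is tested against
    X ~ Hypergeometric(N=background_size, K=|tf_list|, n=|gene_set|);
    returns (k, P(X >= k)).
    """
    if len(gene_set) > background_size or len(tf_list) > background_size:
        raise ValidationError("set sizes exceed the background size")
    k = len(gene_set & tf_list)
    if k > min(len(gene_set), len(tf_list)):  # pragma: no cover - impossible
        raise ValidationError("overlap exceeds set sizes")
    p = float(stats.hypergeom.sf(k - 1, background_size, len(tf_list),
                                 len(gene_set)))
    return k, min(p, 1.0)
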