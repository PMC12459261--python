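"""Refining a candidate essential-gene list into scEssentials genes.

The funnel has three stages: (1) detectability across sequencing platforms
in a benchmarking atlas — a gene must have at least ``min_nonzero`` cells
with nonzero counts in *every* platform; (2) the same rule across cell
types in a tissue atlas; (3) a stability filter that removes genes whose
biological variability residual sits above a high quantile of all genes'
residuals in a majority of cell types.  The intersection of survivors is
the scEssentials set; a FilterTrace records every removal.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model import ExpressionAtlas, ValidationError
from .variability import normalize_log, variability_table

__all__ = [
    "DetectabilityReport",
    "FilterTrace",
    "detectability_filter",
    "stability_filter",
    "derive_scessentials",
]


@dataclasses.dataclass
class DetectabilityReport:
    """Per-gene, per-group nonzero-cell counts and detection fractions.

    ``table`` columns: gene, group, n_nonzero_cells, group_size,
    detection_fraction.  ``pass_all_groups`` maps gene -> bool.
    """

    group_key: str
    min_nonzero: int
    table: pd.DataFrame
    pass_all_groups: pd.Series

    def detection_matrix(self) -> pd.DataFrame:
        """Genes x groups matrix of detection fractions d_{g,c}."""
        return self.table.pivot(index="gene", columns="group",
                                values="detection_fraction")


@dataclasses.dataclass
class FilterTrace:
    """Ordered audit of the filtering funnel."""

    stages: list[dict] = dataclasses.field(default_factory=list)

    def record(self, name: str, genes_in: set[str], genes_out: set[str]) -> None:
        if not genes_out <= genes_in:
            raise ValidationError(f"stage {name!r}: output genes not a subset of input")
        self.stages.append({
            "stage": name,
            "n_in": len(genes_in),
            "n_out": len(genes_out),
            "removed": sorted(genes_in - genes_out),
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"stage": s["stage"], "n_in": s["n_in"], "n_out": s["n_out"],
              "removed": ",".join(s["removed"])} for s in self.stages]
        )


def _nonzero_by_group(atlas: ExpressionAtlas, gene_idx: np.ndarray,
                      group_key: str) -> pd.DataFrame:
    counts = atlas.counts[gene_idx, :]
    if sp.issparse(counts):
        nonzero = counts != 0
    else:
        nonzero = counts != 0
    groups = atlas.cell_meta[group_key]
    rows = []
    for group, grp in atlas.cell_meta.groupby(group_key, sort=True):
        idx = grp.index.to_numpy()
        if idx.size == 0:
            raise ValidationError(f"group {group!r} has zero cells")
        sub = nonzero[:, idx]
        n_nz = np.asarray(sub.sum(axis=1)).ravel()
        rows.append(pd.DataFrame({
            "gene": [atlas.gene_ids[i] for i in gene_idx],
            "group": group,
            "n_nonzero_cells": n_nz.astype(int),
            "group_size": idx.size,
        }))
    out = pd.concat(rows, ignore_index=True)
    out["detection_fraction"] = out["n_nonzero_cells"] / out["group_size"]
    return out


def detectability_filter(atlas: ExpressionAtlas, candidates: set[str],
                         group_key: str = "platform",
                         min_nonzero: int = 3) -> tuple[set[str], DetectabilityReport]:
    """Retain candidates detected (>= min_nonzero nonzero cells) in every group.

    Candidates absent from the atlas are treated as removed at this stage
    (recorded in ``pass_all_groups`` as False with no table rows).
    """
    if group_key not in atlas.cell_meta.columns:
        raise ValidationError(f"group column {group_key!r} absent from cell_meta")
    present = [g for g in atlas.gene_ids if g in candidates]
    if not present:
        raise ValidationError("no candidate gene present in the atlas")
    gene_idx = atlas.gene_index.get_indexer(present)
    table = _nonzero_by_group(atlas, gene_idx, group_key)
    passes = (
        table.assign(ok=table["n_nonzero_cells"] >= min_nonzero)
        .groupby("gene")["ok"].all()
    )
    absent = sorted(set(candidates) - set(present))
    pass_all = pd.concat([passes, pd.Series(False, index=absent, dtype=bool)])
    pass_all = pass_all.sort_index()
    retained = set(passes.index[passes])
    report = DetectabilityReport(group_key=group_key, min_nonzero=min_nonzero,
                                 table=table, pass_all_groups=pass_all)
    return retained, report


def stability_filter(residuals: pd.DataFrame, q: float = 0.90,
                     min_frac_celltypes: float = 0.5) -> set[str]:
    """Remove genes with high biological residual in most cell types.

    ``residuals`` is long format with columns gene, cell_type, bio_residual
    (one row per gene per cell type where the gene was measured).  A gene is
    removed iff its residual exceeds the ``q``-quantile of all genes'
    residuals within that cell type in more than ``min_frac_celltypes`` of
    the cell types where it is measured.
    """
    if not 0.0 < q < 1.0:
        raise ValidationError(f"q={q} outside (0,1)")
    needed = {"gene", "cell_type", "bio_residual"}
    if not needed <= set(residuals.columns):
        raise ValidationError(f"residual table needs columns {sorted(needed)}")
    if residuals.empty:
        raise ValidationError("residual table is empty")
    flagged = []
    for ct, grp in residuals.groupby("cell_type", sort=True):
        cutoff = grp["bio_residual"].quantile(q)
        flagged.append(pd.DataFrame({
            "gene": grp["gene"],
            "high": grp["bio_residual"].to_numpy() > cutoff,
        }))
    flags = pd.concat(flagged, ignore_index=True)
    frac_high = flags.groupby("gene")["high"].mean()
    removed = set(frac_high.index[frac_high > min_frac_celltypes])
    return set(frac_high.index) - removed


def derive_scessentials(atlas_bench: ExpressionAtlas, atlas_tissue: ExpressionAtlas,
                        candidates: set[str], min_nonzero: int = 3,
                        q: float = 0.90, min_frac_celltypes: float = 0.5,
                        block_key: str = "donor",
                        window: int = 51) -> tuple[set[str], FilterTrace]:
    """Full funnel: platform detectability -> cell-type detectability ->
    stability; returns the retained scEssentials set and its trace.

    An empty final set is a valid outcome (complete trace, no error).
    """
    trace = FilterTrace()
    stage1, _ = detectability_filter(atlas_bench, candidates,
                                     group_key="platform", min_nonzero=min_nonzero)
    trace.record("platform_detectability", set(candidates), stage1)
    if not stage1:
        return set(), trace

    present = stage1 & set(atlas_tissue.gene_ids)
    if not present:
        trace.record("celltype_detectability", stage1, set())
        return set(), trace
    stage2, _ = detectability_filter(atlas_tissue, present,
                                     group_key="cell_type", min_nonzero=min_nonzero)
    trace.record("celltype_detectability", stage1, stage2)
    if not stage2:
        return set(), trace

    # quantile cutoffs are computed over ALL atlas genes, then applied to the
    # surviving candidates
    normed = normalize_log(atlas_tissue)
    var_tab = variability_table(normed, block_key=block_key, window=window)
    stable = stability_filter(var_tab, q=q, min_frac_celltypes=min_frac_celltypes)
    stage3 = stage2 & stable
    trace.record("stability", stage2, stage3)
    return stage3, trace
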