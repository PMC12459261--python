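"""Random-list nulls, gene-set overlap statistics, and the marker/HVG
detectors used for overlap reporting.

The random-list ensemble is the study's null: gene lists matched in size to
the essential set, sampled without replacement from the atlas gene universe
and repeated (default 10 times, seed 123441).  Overlaps are tested with the
upper-tail hypergeometric; per-pathway overlap fractions are compared
between the essential set and the ensemble with a Kruskal-Wallis test.

Cell-type markers are detected with a 1-vs-rest Wilcoxon rank-sum plus a
log2 fold-change gate, and HVGs by the top biological residuals — both
rank-based, deterministic detectors suited to overlap reporting.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coexpression import kruskal_wallis
from .data_model import ExpressionAtlas, GeneSetCollection, ValidationError
from .variability import biological_component

__all__ = [
    "RandomListEnsemble",
    "random_gene_lists",
    "hypergeometric_overlap",
    "pathway_overlap_fractions",
    "de_markers",
    "hvg_select",
    "overlap_summary",
]


@dataclasses.dataclass
class RandomListEnsemble:
    """Size-matched random gene lists drawn from a universe."""

    universe: list[str]
    list_size: int
    seed: int
    lists: list[set[str]]

    @property
    def reps(self) -> int:
        return len(self.lists)


def random_gene_lists(universe, list_size: int, reps: int = 10,
                      seed: int = 123441) -> RandomListEnsemble:
    """Sample ``reps`` gene lists of ``list_size`` without replacement
    (within a list) from ``universe``; reproducible for a fixed seed."""
    universe = sorted(set(universe))
    if list_size > len(universe):
        raise ValidationError(
            f"list_size {list_size} exceeds universe size {len(universe)}")
    rng = np.random.default_rng(seed)
    arr = np.asarray(universe, dtype=object)
    lists = [set(rng.choice(arr, size=list_size, replace=False))
             for _ in range(reps)]
    return RandomListEnsemble(universe=universe, list_size=list_size,
                              seed=seed, lists=lists)


def hypergeometric_overlap(set_a, set_b, universe) -> tuple[int, float, float]:
    """Overlap size, its expectation, and the upper-tail hypergeometric p.

    X ~ Hypergeometric(N=|universe|, K=|set_a|, n=|set_b|); p = P(X >= k).
    """
    universe = set(universe)
    set_a, set_b = set(set_a), set(set_b)
    for name, s in (("set_a", set_a), ("set_b", set_b)):
        stray = s - universe
        if stray:
            raise ValidationError(
                f"{name} contains genes outside the universe: {sorted(stray)[:5]}")
    n_u = len(universe)
    k = len(set_a & set_b)
    expected = len(set_a) * len(set_b) / n_u if n_u else 0.0
    p = float(stats.hypergeom.sf(k - 1, n_u, len(set_a), len(set_b)))
    return k, expected, min(p, 1.0)


def pathway_overlap_fractions(gene_set: set[str], pathways: GeneSetCollection,
                              ensemble: RandomListEnsemble
                              ) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Per-pathway overlap of the gene set vs the random ensemble.

    Per pathway: count and percent (100 * |gene_set ∩ pathway| / |pathway|)
    for the gene set, plus each random list's count.  The Kruskal-Wallis
    test compares the per-pathway percent vectors of the gene set against
    each random list (1 + reps groups).  Empty pathways are skipped with a
    warning.
    """
    if len(pathways) == 0:
        raise ValidationError("pathway collection is empty")
    rows = []
    for name, members in sorted(pathways.items()):
        if not members:  # GeneSetCollection forbids this, belt and braces
            warnings.warn(f"pathway {name!r} empty; skipped")
            continue
        row = {
            "pathway": name,
            "size": len(members),
            "count": len(gene_set & members),
            "percent": 100.0 * len(gene_set & members) / len(members),
        }
        for r, lst in enumerate(ensemble.lists):
            row[f"random_count_{r}"] = len(lst & members)
            row[f"random_percent_{r}"] = 100.0 * len(lst & members) / len(members)
        rows.append(row)
    table = pd.DataFrame(rows)
    groups = [table["percent"].to_numpy()]
    groups += [table[f"random_percent_{r}"].to_numpy()
               for r in range(ensemble.reps)]
    h, p = kruskal_wallis(groups)
    return table, (h, p)


def de_markers(atlas: ExpressionAtlas, tissue: str, alpha: float = 0.05,
               min_abs_log2fc: float = 0.25,
               min_cells: int = 3) -> dict[str, set[str]]:
    """Cell-type marker (DEG) sets by 1-vs-rest Wilcoxon within a tissue.

    Per cell type, each gene is tested (two-sided rank-sum, cell type vs all
    other cells of the tissue), BH-corrected across genes; a DEG needs
    q < alpha and |difference of mean log2 expression| >= min_abs_log2fc.
    Cell types with fewer than ``min_cells`` cells are skipped.
    """
    if "tissue" not in atlas.cell_meta.columns:
        raise ValidationError("atlas lacks a tissue column")
    sub = atlas.subset_cells((atlas.cell_meta["tissue"] == tissue).to_numpy())
    if sub.n_cells == 0:
        raise ValidationError(f"tissue {tissue!r} not present")
    cts = sub.cell_types()
    if len(cts) < 2:
        raise ValidationError(f"tissue {tissue!r} has fewer than 2 cell types")
    dense = sub.dense()
    ct_arr = sub.cell_meta["cell_type"].to_numpy()
    out: dict[str, set[str]] = {}
    for ct in cts:
        mask = ct_arr == ct
        if mask.sum() < min_cells or (~mask).sum() < min_cells:
            warnings.warn(f"cell type {ct!r} has <{min_cells} cells; skipped")
            continue
        a, b = dense[:, mask], dense[:, ~mask]
        res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
        _, q, _, _ = multipletests(res.pvalue, method="fdr_bh")
        lfc = a.mean(axis=1) - b.mean(axis=1)  # data already on log2 scale
        hits = (q < alpha) & (np.abs(lfc) >= min_abs_log2fc)
        out[ct] = {g for g, h in zip(sub.gene_ids, hits) if h}
    return out


def hvg_select(atlas: ExpressionAtlas, cell_type: str, n_top: int = 2000,
               block_key: str = "donor") -> set[str]:
    """Top-``n_top`` highly variable genes by biological residual.

    Deterministic: ties in residual break by gene id.  Requesting more
    genes than exist returns all genes with a warning.
    """
    est = biological_component(atlas, cell_type, block_key=block_key)
    if n_top > len(est):
        warnings.warn(f"n_top={n_top} exceeds gene count {len(est)}; returning all")
        n_top = len(est)
    ranked = est.reset_index().sort_values(["bio_residual", "gene"],
                                           ascending=[False, True], kind="stable")
    return set(ranked["gene"].head(n_top))


def overlap_summary(scessentials: set[str],
                    per_celltype_sets: list[set[str]]) -> tuple[list[float], float]:
    """Percent of the scEssentials set found in each cell type's set, and
    the median percent across cell types."""
    if not scessentials or not per_celltype_sets:
        raise ValidationError("inputs must be non-empty")
    percents = [100.0 * len(scessentials & s) / len(scessentials)
                for s in per_celltype_sets]
    return percents, float(np.median(percents))
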