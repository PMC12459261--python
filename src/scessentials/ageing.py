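"""Gene-wise modelling of expression change with age across cell types.

For each gene the model is

    y ~ sex + age * celltype

on log-normalised expression, with sex a 2-level covariate, age an
unordered 3-level factor (3m, 18m, 24m) and cell type a factor.  Two
grouped F-tests are reported per gene: the age main effect (additive model
{sex + age + celltype} against {sex + celltype}) and the age x cell-type
interaction (full model against the additive one).  A third, overall
age-dependence test (full against {sex + celltype}, dropping age and
interaction together) is exported as ``p_age_overall`` for completeness.
BH correction is applied across genes separately per test family;
classification follows the two-step rule: age-significant first, otherwise
interaction-significant, otherwise stable.

All genes share the same design matrix, so the fits reduce to projections
onto three fixed column spaces and run vectorised across genes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .data_model import ExpressionAtlas, ValidationError
from .variability import normalize_log

__all__ = [
    "AgeingDesign",
    "prepare_ageing_atlas",
    "fit_gene_age_model",
    "classify_genes",
    "per_celltype_counts",
]

DEFAULT_AGE_LEVELS = ("3m", "18m", "24m")
_RANK_TOL = 1e-10


@dataclasses.dataclass
class AgeingDesign:
    """Per-cell factors and the (genes x cells) expression matrix."""

    genes: list[str]
    y: np.ndarray               # genes x cells, log-normalised
    sex: np.ndarray             # strings
    age: np.ndarray             # strings, ordered by age_levels
    celltype: np.ndarray        # strings
    age_levels: tuple[str, ...]
    celltype_levels: tuple[str, ...]
    dropped_celltypes: dict[str, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        observed = [lv for lv in self.age_levels if (self.age == lv).any()]
        if len(observed) < 2:
            raise ValidationError("design needs at least 2 observed age levels")

    @property
    def n_cells(self) -> int:
        return self.y.shape[1]


def prepare_ageing_atlas(atlas: ExpressionAtlas, platform_filter: str,
                         min_cells: int = 100,
                         age_levels=DEFAULT_AGE_LEVELS,
                         genes: set[str] | None = None) -> AgeingDesign:
    """Restrict an atlas to one platform and the stated age levels, drop
    cell types with fewer than ``min_cells`` cells, and log-normalise.

    The drop log (cell type -> cell count) is carried on the design.
    """
    for col in ("platform", "age_group", "sex"):
        if col not in atlas.cell_meta.columns:
            raise ValidationError(f"atlas lacks column {col!r}")
    meta = atlas.cell_meta
    mask = (meta["platform"] == platform_filter).to_numpy()
    mask &= meta["age_group"].isin(age_levels).to_numpy()
    if not mask.any():
        raise ValidationError(
            f"no cells on platform {platform_filter!r} within the age levels")
    sub = atlas.subset_cells(mask)
    sizes = sub.cell_meta["cell_type"].value_counts()
    keep_ct = sorted(sizes.index[sizes >= min_cells])
    dropped = {ct: int(n) for ct, n in sizes.items() if n < min_cells}
    if not keep_ct:
        raise ValidationError(f"no cell type has >= {min_cells} cells")
    sub = sub.subset_cells(sub.cell_meta["cell_type"].isin(keep_ct).to_numpy())
    if genes is not None:
        sub = sub.subset_genes(genes)
        if sub.n_genes == 0:
            raise ValidationError("no requested gene present in the atlas")
    if not sub.normalized:
        sub = normalize_log(sub)
    return AgeingDesign(
        genes=list(sub.gene_ids),
        y=sub.dense(),
        sex=sub.cell_meta["sex"].to_numpy(dtype=object),
        age=sub.cell_meta["age_group"].to_numpy(dtype=object),
        celltype=sub.cell_meta["cell_type"].to_numpy(dtype=object),
        age_levels=tuple(lv for lv in age_levels
                         if (sub.cell_meta["age_group"] == lv).any()),
        celltype_levels=tuple(keep_ct),
        dropped_celltypes=dropped,
    )


def _dummies(values: np.ndarray, levels) -> np.ndarray:
    """Treatment coding: one column per non-reference level."""
    return np.column_stack([(values == lv).astype(float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((values.size, 0))


def _design_matrices(design: AgeingDesign):
    n = design.n_cells
    intercept = np.ones((n, 1))
    sex_levels = sorted(set(design.sex))
    x_sex = _dummies(design.sex, sex_levels)
    x_age = _dummies(design.age, design.age_levels)
    x_ct = _dummies(design.celltype, design.celltype_levels)
    inter = []
    for i in range(x_age.shape[1]):
        for j in range(x_ct.shape[1]):
            col = x_age[:, i] * x_ct[:, j]
            if col.any():  # unobserved age x celltype combos are dropped
                inter.append(col)
    x_int = np.column_stack(inter) if inter else np.empty((n, 0))
    x_null = np.hstack([intercept, x_sex, x_ct])            # sex + celltype
    x_add = np.hstack([x_null, x_age])                      # + age
    x_full = np.hstack([x_add, x_int])                      # + age:celltype
    return x_null, x_add, x_full


def _projection_basis(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing pivoted QR)."""
    q, r, _ = linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > _RANK_TOL * max(diag[0], 1.0)))
    return q[:, :rank]


def _ssr(y: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Residual sum of squares per gene for the projection onto ``basis``.

    ``y`` is genes x cells; returns one SSR per gene.
    """
    total = np.einsum("gc,gc->g", y, y)
    proj = y @ basis
    return total - np.einsum("gk,gk->g", proj, proj)


def _f_test(ssr_red, ssr_full, df_diff, df_resid):
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((ssr_red - ssr_full) / df_diff) / (ssr_full / df_resid)
    f = np.where(ssr_full <= 0, np.nan, f)
    p = stats.f.sf(f, df_diff, df_resid)
    return f, p


def fit_gene_age_model(design: AgeingDesign) -> pd.DataFrame:
    """OLS fits and grouped F-tests for every gene of the design.

    Returns a DataFrame indexed by gene with columns ``f_age, p_age``
    (additive age main effect), ``f_int, p_int`` (age x cell-type
    interaction), ``p_age_overall`` (age and interaction dropped together)
    and ``ok`` (False where the residual variance is zero and the tests are
    undefined; such genes are excluded from BH downstream).
    """
    x_null, x_add, x_full = _design_matrices(design)
    q_null = _projection_basis(x_null)
    q_add = _projection_basis(x_add)
    q_full = _projection_basis(x_full)
    r_null, r_add, r_full = (q.shape[1] for q in (q_null, q_add, q_full))
    n = design.n_cells
    if r_full >= n:
        raise ValidationError("design has no residual degrees of freedom")
    if r_add == r_null:
        raise ValidationError("age term is aliased (single observed age level?)")
    y = design.y
    ssr_null = _ssr(y, q_null)
    ssr_add = _ssr(y, q_add)
    ssr_full = _ssr(y, q_full)
    df_resid = n - r_full
    f_age, p_age = _f_test(ssr_null, ssr_add, r_add - r_null, n - r_add)
    f_int, p_int = _f_test(ssr_add, ssr_full, r_full - r_add, df_resid)
    _, p_overall = _f_test(ssr_null, ssr_full, r_full - r_null, df_resid)
    resid_var = ssr_full / df_resid
    ok = resid_var > _RANK_TOL
    out = pd.DataFrame(
        {
            "f_age": f_age, "p_age": p_age,
            "f_int": f_int, "p_int": p_int,
            "p_age_overall": p_overall,
            "ok": ok,
        },
        index=pd.Index(design.genes, name="gene"),
    )
    return out


def classify_genes(fits: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH per test family, then the two-step classification.

    age q < alpha -> ``age_significant``; else interaction q < alpha ->
    ``interaction_significant``; else ``stable``.  Genes flagged not-ok are
    excluded from both BH families and labelled ``excluded``.
    """
    out = fits.copy()
    out["q_age"] = np.nan
    out["q_int"] = np.nan
    usable = out["ok"] & out["p_age"].notna() & out["p_int"].notna()
    idx = out.index[usable]
    if len(idx):
        _, q_age, _, _ = multipletests(out.loc[idx, "p_age"], method="fdr_bh")
        _, q_int, _, _ = multipletests(out.loc[idx, "p_int"], method="fdr_bh")
        out.loc[idx, "q_age"] = q_age
        out.loc[idx, "q_int"] = q_int
    label = np.full(len(out), "stable", dtype=object)
    label[(out["q_age"] < alpha).to_numpy()] = "age_significant"
    inter = (~(out["q_age"] < alpha) & (out["q_int"] < alpha)).to_numpy()
    label[inter] = "interaction_significant"
    label[~usable.to_numpy()] = "excluded"
    out["classification"] = label
    return out


def per_celltype_counts(fits: pd.DataFrame, design: AgeingDesign,
                        alpha: float = 0.05,
                        genes: list[str] | None = None) -> pd.Series:
    """Count, per cell type, the genes with a significant within-cell-type
    age effect.

    By default the tested genes are the interaction-significant ones (the
    cell-type-dependent responders); within each cell type the contrast is
    {sex + age} against {sex}, BH-corrected across the tested genes.
    """
    if genes is None:
        if "classification" not in fits.columns:
            raise ValidationError("fits must be classified first (classify_genes)")
        genes = fits.index[fits["classification"] == "interaction_significant"]
        genes = list(genes)
    counts = {}
    gene_pos = {g: i for i, g in enumerate(design.genes)}
    idx = [gene_pos[g] for g in genes if g in gene_pos]
    for ct in design.celltype_levels:
        if not idx:
            counts[ct] = 0
            continue
        mask = design.celltype == ct
        sex = design.sex[mask]
        age = design.age[mask]
        y = design.y[np.ix_(idx, np.flatnonzero(mask))]
        intercept = np.ones((int(mask.sum()), 1))
        x0 = np.hstack([intercept, _dummies(sex, sorted(set(sex)))])
        observed_ages = [lv for lv in design.age_levels if (age == lv).any()]
        x1 = np.hstack([x0, _dummies(age, observed_ages)])
        q0, q1 = _projection_basis(x0), _projection_basis(x1)
        if q1.shape[1] == q0.shape[1] or q1.shape[1] >= int(mask.sum()):
            counts[ct] = 0
            continue
        ssr0, ssr1 = _ssr(y, q0), _ssr(y, q1)
        _, p = _f_test(ssr0, ssr1, q1.shape[1] - q0.shape[1],
                       int(mask.sum()) - q1.shape[1])
        p = np.where(np.isnan(p), 1.0, p)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        counts[ct] = int((q < alpha).sum())
    return pd.Series(counts, name="n_significant").sort_index()
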