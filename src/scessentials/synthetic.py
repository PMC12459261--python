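"""Synthetic single-cell atlas generator with planted ground truth.

Counts are zero-inflated negative binomial: with probability
``dropout_prob_by_platform[p]`` a measurement is zeroed (platform-specific
capture failure), otherwise it is NB with mean ``mu_g * s_j * m_{g,ct}`` and
gene-class-specific dispersion, where ``s_j`` is a log-normal per-cell size
factor and ``m_{g,ct}`` an 8x marker multiplier in a marker gene's target
cell type.  Gene classes:

``essential_like``
    baseline mean drawn from the upper quartile of the log-normal mean
    distribution (with a floor) and lower overdispersion — robustly detected
    and stable, the signal the filtering stages should retain.
``marker_like``
    ordinary mean, strongly up-regulated in one target cell type.
``noise``
    ordinary mean and dispersion; a designated subset can be made
    platform-sensitive (heavy extra dropout on one platform) and another
    subset is organised into Gaussian-copula correlated blocks.

Ageing atlases add three age groups (3m < 18m < 24m) with multiplicative
per-step mean shifts: uniform across cell types for age-main-effect genes,
sign-alternating over a small subset of cell types for interaction-only
genes (so the marginal age effect is ~null while the age x cell-type term is
strong), and a small sex effect on a disjoint gene set.

Every simulate call derives independent sub-streams from ``config.seed`` via
``np.random.default_rng([seed, k])`` with fixed ``k`` per purpose, so adding
gene classes does not reshuffle existing draws.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .data_model import ExpressionAtlas, ValidationError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_atlas",
    "simulate_correlated_block",
    "simulate_ageing_atlas",
]

AGE_LEVELS = ("3m", "18m", "24m")
MARKER_MULTIPLIER = 8.0


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the synthetic atlas; defaults are the study conditions.

    ``nb_dispersion`` is the NB size parameter theta (variance =
    mu + mu^2/theta); essential-like genes use
    ``nb_dispersion * dispersion_essential_factor`` (less overdispersed).
    ``age_effect = (fraction_of_genes_affected, fold_change_per_age_step)``
    controls both the age-main and interaction-only planted classes (each
    gets that fraction of genes).
    """

    n_cell_types: int = 5
    cells_per_type: int = 200
    n_donors: int = 4
    n_platforms: int = 3
    n_essential_like: int = 50
    n_marker_like: int = 30
    n_noise: int = 120
    mean_log_mu: float = 0.0
    sd_log_mu: float = 1.0
    nb_dispersion: float = 2.0
    dispersion_essential_factor: float = 4.0
    mu_floor_essential: float = 1.0
    dropout_prob_by_platform: Sequence[float] | None = None
    n_platform_sensitive: int = 0
    platform_sensitive_dropout: float = 1.0
    block_specs: Sequence[tuple[int, float]] = dataclasses.field(default_factory=list)
    age_effect: tuple[float, float] = (0.0, 1.3)
    n_interaction_celltypes: int = 2
    sex_effect: tuple[float, float] = (0.05, 1.3)
    size_factor_sd: float = 0.2
    seed: int = 123441

    def __post_init__(self) -> None:
        if self.dropout_prob_by_platform is None:
            self.dropout_prob_by_platform = [0.0] * self.n_platforms
        self.dropout_prob_by_platform = list(self.dropout_prob_by_platform)
        if len(self.dropout_prob_by_platform) != self.n_platforms:
            raise ValidationError("dropout_prob_by_platform length != n_platforms")
        for p in self.dropout_prob_by_platform:
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"dropout probability {p} outside [0,1]")
        if not 0.0 <= self.platform_sensitive_dropout <= 1.0:
            raise ValidationError("platform_sensitive_dropout outside [0,1]")
        for size, rho in self.block_specs:
            if size < 2:
                raise ValidationError(f"block size {size} < 2")
            _check_equicorrelation(size, rho)
        frac, _ = self.age_effect
        if not 0.0 <= frac <= 0.5:
            raise ValidationError("age_effect fraction outside [0, 0.5]")
        if min(self.n_cell_types, self.cells_per_type, self.n_donors,
               self.n_platforms) < 1:
            raise ValidationError("counts of cell types/cells/donors/platforms must be >= 1")
        if self.n_platform_sensitive > self.n_noise:
            raise ValidationError("n_platform_sensitive exceeds n_noise")

    @property
    def n_genes(self) -> int:
        return self.n_essential_like + self.n_marker_like + self.n_noise


@dataclasses.dataclass
class GroundTruth:
    """Planted answers: what each downstream stage should recover."""

    gene_class: dict[str, str]                    # gene -> essential_like|marker_like|noise
    marker_target: dict[str, str]                 # marker gene -> target cell type
    blocks: list[tuple[list[str], float]]         # (member genes, rho_target)
    platform_sensitive: set[str]
    age_main: dict[str, float]                    # gene -> fold change per age step
    age_interaction: dict[str, dict[str, float]]  # gene -> {cell_type: per-step fold change}
    sex_genes: dict[str, float]

    def genes_of_class(self, label: str) -> set[str]:
        return {g for g, c in self.gene_class.items() if c == label}


def _check_equicorrelation(size: int, rho: float) -> None:
    lo = -1.0 / (size - 1)
    if not (lo < rho < 1.0):
        raise ValidationError(
            f"rho_target {rho} outside PSD bound ({lo:.4f}, 1) for block size {size}"
        )


def _substream(seed: int, k: int) -> np.random.Generator:
    return np.random.default_rng([abs(int(seed)) % (2**31), k])


def _gene_names(config: SimulationConfig) -> tuple[list[str], dict[str, str]]:
    names, classes = [], {}
    for i in range(config.n_essential_like):
        g = f"ESS{i:04d}"
        names.append(g)
        classes[g] = "essential_like"
    for i in range(config.n_marker_like):
        g = f"MRK{i:04d}"
        names.append(g)
        classes[g] = "marker_like"
    for i in range(config.n_noise):
        g = f"NSE{i:04d}"
        names.append(g)
        classes[g] = "noise"
    return names, classes


def _baseline_means(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Log-normal baseline means; essential-like genes from the upper quartile."""
    n = config.n_genes
    mu = np.empty(n)
    n_ess = config.n_essential_like
    # upper-quartile draws via the quantile function
    q = rng.uniform(0.75, 1.0, size=n_ess)
    mu[:n_ess] = np.exp(config.mean_log_mu + config.sd_log_mu * stats.norm.ppf(q))
    mu[:n_ess] = np.maximum(mu[:n_ess], config.mu_floor_essential)
    mu[n_ess:] = rng.lognormal(config.mean_log_mu, config.sd_log_mu, size=n - n_ess)
    return mu


def _dispersions(config: SimulationConfig) -> np.ndarray:
    theta = np.full(config.n_genes, float(config.nb_dispersion))
    theta[:config.n_essential_like] *= config.dispersion_essential_factor
    return theta


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: np.ndarray) -> np.ndarray:
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def _copula_block_counts(rng, n_cells, rho, mean, theta) -> np.ndarray:
    """Equicorrelated Gaussian copula with NB marginals; rows are genes.

    ``mean`` is (block_size, n_cells) or (block_size,); ``theta`` (block_size,).
    """
    block_size = mean.shape[0]
    sigma = np.full((block_size, block_size), rho)
    np.fill_diagonal(sigma, 1.0)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise ValidationError(f"equicorrelation rho={rho} not PSD") from exc
    z = chol @ rng.standard_normal((block_size, n_cells))
    u = stats.norm.cdf(z)
    mean2 = mean if mean.ndim == 2 else mean[:, None] * np.ones((1, n_cells))
    p = theta[:, None] / (theta[:, None] + mean2)
    return stats.nbinom.ppf(u, theta[:, None], p).astype(np.int64)


def simulate_correlated_block(n_cells: int, block_size: int, rho_target: float,
                              marginal: tuple[float, float] = (5.0, 2.0),
                              seed: int = 123441) -> np.ndarray:
    """Counts for one correlated gene block (genes x cells).

    ``marginal = (mu, theta)`` sets a common NB marginal.  The feasible range
    of ``rho_target`` is the equicorrelation PSD bound
    (-1/(block_size-1), 1).
    """
    if n_cells < 10:
        raise ValidationError("n_cells must be >= 10")
    if block_size < 2:
        raise ValidationError("block_size must be >= 2")
    _check_equicorrelation(block_size, rho_target)
    mu, theta = marginal
    rng = _substream(seed, 40)
    mean = np.full((block_size, n_cells), float(mu))
    return _copula_block_counts(rng, n_cells, rho_target,
                                mean, np.full(block_size, float(theta)))


def _assemble_cells(config: SimulationConfig, rng: np.random.Generator,
                    age_groups: Sequence[str] | None = None,
                    donor_sex: dict[str, str] | None = None) -> pd.DataFrame:
    """Cell annotations: cell types crossed with platforms, donors random."""
    cell_types = [f"CT{i + 1}" for i in range(config.n_cell_types)]
    tissues = {ct: ("T1" if i < (config.n_cell_types + 1) // 2 else "T2")
               for i, ct in enumerate(cell_types)}
    rows = []
    groups = list(age_groups) if age_groups else [None]
    idx = 0
    for age in groups:
        for ct in cell_types:
            for j in range(config.cells_per_type):
                platform = f"P{j % config.n_platforms + 1}"
                if age is None:
                    donor = f"D{rng.integers(config.n_donors) + 1}"
                else:
                    donor = f"{age}_D{rng.integers(config.n_donors) + 1}"
                row = {
                    "cell_id": f"cell{idx:06d}",
                    "cell_type": ct,
                    "tissue": tissues[ct],
                    "donor": donor,
                    "platform": platform,
                }
                if age is not None:
                    row["age_group"] = age
                    row["sex"] = donor_sex[donor]
                rows.append(row)
                idx += 1
    return pd.DataFrame(rows)


def _marker_targets(config: SimulationConfig, names: list[str]) -> dict[str, str]:
    cell_types = [f"CT{i + 1}" for i in range(config.n_cell_types)]
    start = config.n_essential_like
    return {names[start + i]: cell_types[i % config.n_cell_types]
            for i in range(config.n_marker_like)}


def _mean_matrix(config: SimulationConfig, mu: np.ndarray, cells: pd.DataFrame,
                 marker_target: dict[str, str], names: list[str],
                 rng_cells: np.random.Generator) -> np.ndarray:
    """Per-gene per-cell NB mean: mu_g * size_factor_j * marker multiplier."""
    n_cells = len(cells)
    size_factors = rng_cells.lognormal(0.0, config.size_factor_sd, size=n_cells)
    mean = mu[:, None] * size_factors[None, :]
    name_idx = {g: i for i, g in enumerate(names)}
    ct = cells["cell_type"].to_numpy()
    for gene, target in marker_target.items():
        mean[name_idx[gene], ct == target] *= MARKER_MULTIPLIER
    return mean


def _apply_dropout(config: SimulationConfig, counts: np.ndarray,
                   cells: pd.DataFrame, platform_sensitive_idx: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    platforms = cells["platform"].to_numpy()
    for p_i, prob in enumerate(config.dropout_prob_by_platform):
        if prob <= 0:
            continue
        mask = platforms == f"P{p_i + 1}"
        drop = rng.random((counts.shape[0], int(mask.sum()))) < prob
        sub = counts[:, mask]
        sub[drop] = 0
        counts[:, mask] = sub
    if platform_sensitive_idx.size:
        mask = platforms == "P1"
        drop = rng.random((platform_sensitive_idx.size, int(mask.sum())))
        drop = drop < config.platform_sensitive_dropout
        sub = counts[np.ix_(platform_sensitive_idx, np.flatnonzero(mask))]
        sub[drop] = 0
        counts[np.ix_(platform_sensitive_idx, np.flatnonzero(mask))] = sub
    return counts


def _plant_blocks(config: SimulationConfig, counts: np.ndarray, mean: np.ndarray,
                  theta: np.ndarray, names: list[str],
                  rng: np.random.Generator) -> list[tuple[list[str], float]]:
    """Overwrite designated noise genes with copula-correlated draws."""
    blocks = []
    start = config.n_essential_like + config.n_marker_like + config.n_platform_sensitive
    cursor = start
    for size, rho in config.block_specs:
        idx = np.arange(cursor, cursor + size)
        if idx[-1] >= config.n_genes:
            raise ValidationError("block_specs exceed available noise genes")
        counts[idx, :] = _copula_block_counts(
            rng, counts.shape[1], rho, mean[idx, :], theta[idx])
        blocks.append(([names[i] for i in idx], rho))
        cursor += size
    return blocks


def simulate_atlas(config: SimulationConfig) -> tuple[ExpressionAtlas, GroundTruth]:
    """Generate one atlas (no age structure) with its ground truth."""
    names, classes = _gene_names(config)
    mu = _baseline_means(config, _substream(config.seed, 1))
    theta = _dispersions(config)
    cells = _assemble_cells(config, _substream(config.seed, 2))
    marker_target = _marker_targets(config, names)
    mean = _mean_matrix(config, mu, cells, marker_target, names,
                        _substream(config.seed, 3))
    counts = _nb_draw(_substream(config.seed, 4), mean, theta[:, None])
    blocks = _plant_blocks(config, counts, mean, theta, names,
                           _substream(config.seed, 5))
    ps_start = config.n_essential_like + config.n_marker_like
    ps_idx = np.arange(ps_start, ps_start + config.n_platform_sensitive)
    counts = _apply_dropout(config, counts, cells, ps_idx, _substream(config.seed, 6))
    truth = GroundTruth(
        gene_class=classes,
        marker_target=marker_target,
        blocks=blocks,
        platform_sensitive={names[i] for i in ps_idx},
        age_main={},
        age_interaction={},
        sex_genes={},
    )
    atlas = ExpressionAtlas(names, sp.csr_matrix(counts), cells)
    return atlas, truth


def simulate_ageing_atlas(config: SimulationConfig) -> tuple[ExpressionAtlas, GroundTruth]:
    """Atlas over three age groups with planted age / interaction / sex effects.

    Age-main genes shift by ``lfc`` per age step in every cell type;
    interaction-only genes shift in ``n_interaction_celltypes`` cell types
    with alternating sign (marginal age effect ~0); sex-affected genes (a
    disjoint set) shift multiplicatively in males.
    """
    frac, lfc = config.age_effect
    names, classes = _gene_names(config)
    mu = _baseline_means(config, _substream(config.seed, 1))
    theta = _dispersions(config)

    rng_sex = _substream(config.seed, 7)
    donor_sex = {}
    for age in AGE_LEVELS:
        for d in range(config.n_donors):
            donor_sex[f"{age}_D{d + 1}"] = "M" if rng_sex.random() < 0.5 else "F"
    cells = _assemble_cells(config, _substream(config.seed, 2),
                            age_groups=AGE_LEVELS, donor_sex=donor_sex)
    marker_target = _marker_targets(config, names)
    mean = _mean_matrix(config, mu, cells, marker_target, names,
                        _substream(config.seed, 3))

    # choose affected genes among the noise class (disjoint sets)
    noise_start = config.n_essential_like + config.n_marker_like
    n_aff = int(round(frac * config.n_genes))
    age_idx = np.arange(noise_start, noise_start + n_aff)
    int_idx = np.arange(noise_start + n_aff, noise_start + 2 * n_aff)
    n_sex = int(round(config.sex_effect[0] * config.n_genes))
    sex_idx = np.arange(noise_start + 2 * n_aff, noise_start + 2 * n_aff + n_sex)
    if len(sex_idx) and sex_idx[-1] >= config.n_genes:
        raise ValidationError("not enough noise genes for the planted age/sex classes")

    cell_types = [f"CT{i + 1}" for i in range(config.n_cell_types)]
    age_step = cells["age_group"].map({a: i for i, a in enumerate(AGE_LEVELS)}).to_numpy()
    ct_arr = cells["cell_type"].to_numpy()
    is_male = (cells["sex"] == "M").to_numpy()

    # Planted effects come in mean-matched up/down pairs so the expected
    # library size stays flat with age: with relative (library-normalised)
    # measurements, an unbalanced shift in 10% of genes would bleed a
    # spurious opposite shift into every other gene.  The down fold-change
    # g = sqrt(2 - f^2) cancels the up fold-change f exactly at the second
    # age step (f^2 - 1 = 1 - g^2) and nearly at the first; for f > sqrt(2)
    # exact cancellation is impossible and 1/f is used instead.
    fc_down = float(np.sqrt(2.0 - lfc ** 2)) if lfc <= np.sqrt(2.0) else 1.0 / lfc

    def _matched_pairs(idx: np.ndarray) -> list[tuple[int, int]]:
        by_mean = sorted(idx, key=lambda i: mu[i])
        return [(by_mean[j], by_mean[j + 1]) for j in range(0, len(by_mean) - 1, 2)]

    age_main: dict[str, float] = {}
    for i_up, i_dn in _matched_pairs(age_idx):
        mean[i_up, :] *= lfc ** age_step
        mean[i_dn, :] *= fc_down ** age_step
        age_main[names[i_up]] = lfc
        age_main[names[i_dn]] = fc_down
    if len(age_idx) % 2:  # odd leftover: planted unpaired
        i = sorted(age_idx, key=lambda i: mu[i])[-1]
        mean[i, :] *= lfc ** age_step
        age_main[names[i]] = lfc

    # interaction-only pairs are mirrored across two cell types (gene one up
    # in A / down in B, gene two the reverse) so each cell type's library is
    # balanced and the marginal age effect of each gene is ~null
    age_interaction: dict[str, dict[str, float]] = {}
    for p, (i1, i2) in enumerate(_matched_pairs(int_idx)):
        ct_a = cell_types[p % config.n_cell_types]
        ct_b = cell_types[(p + 1) % config.n_cell_types]
        for i, factors in ((i1, {ct_a: lfc, ct_b: fc_down}),
                           (i2, {ct_a: fc_down, ct_b: lfc})):
            per_ct = {}
            for ct, fc in factors.items():
                sel = ct_arr == ct
                mean[i, sel] *= fc ** age_step[sel]
                per_ct[ct] = fc
            age_interaction[names[i]] = per_ct
    if len(int_idx) % 2:
        i = sorted(int_idx, key=lambda i: mu[i])[-1]
        ct_a, ct_b = cell_types[0], cell_types[1 % config.n_cell_types]
        for ct, fc in ((ct_a, lfc), (ct_b, fc_down)):
            sel = ct_arr == ct
            mean[i, sel] *= fc ** age_step[sel]
        age_interaction[names[i]] = {ct_a: lfc, ct_b: fc_down}
    sex_genes: dict[str, float] = {}
    for i in sex_idx:
        mean[i, is_male] *= config.sex_effect[1]
        sex_genes[names[i]] = config.sex_effect[1]

    counts = _nb_draw(_substream(config.seed, 4), mean, theta[:, None])
    ps_idx = np.arange(0)
    counts = _apply_dropout(config, counts, cells, ps_idx, _substream(config.seed, 6))
    truth = GroundTruth(
        gene_class=classes,
        marker_target=marker_target,
        blocks=[],
        platform_sensitive=set(),
        age_main=age_main,
        age_interaction=age_interaction,
        sex_genes=sex_genes,
    )
    atlas = ExpressionAtlas(names, sp.csr_matrix(counts), cells)
    return atlas, truth
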