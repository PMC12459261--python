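import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scessentials import (ExpressionAtlas, SimulationConfig, ValidationError,
                          classify_genes, fit_gene_age_model,
                          per_celltype_counts, prepare_ageing_atlas,
                          simulate_ageing_atlas)
from scessentials.ageing import AgeingDesign


def _design(y, sex, age, celltype, age_levels=("3m", "18m", "24m")):
    y = np.atleast_2d(np.asarray(y, dtype=float))
    return AgeingDesign(
        genes=[f"g{i}" for i in range(y.shape[0])],
        y=y,
        sex=np.asarray(sex, dtype=object),
        age=np.asarray(age, dtype=object),
        celltype=np.asarray(celltype, dtype=object),
        age_levels=tuple(lv for lv in age_levels if lv in set(age)),
        celltype_levels=tuple(sorted(set(celltype))),
    )


def _balanced_factors(n_per_cell=20, cts=("CT1", "CT2"), rng=None):
    rng = rng or np.random.default_rng(0)
    sex, age, ct = [], [], []
    for c in cts:
        for a in ("3m", "18m", "24m"):
            for i in range(n_per_cell):
                sex.append("M" if i % 2 else "F")
                age.append(a)
                ct.append(c)
    return (np.array(sex, dtype=object), np.array(age, dtype=object),
            np.array(ct, dtype=object))


class TestPrepare:
    @staticmethod
    def _atlas(ct_sizes):
        rows = []
        i = 0
        for ct, n in ct_sizes.items():
            for _ in range(n):
                rows.append({"cell_id": f"c{i}", "cell_type": ct,
                             "platform": "facs",
                             "age_group": ["3m", "18m", "24m"][i % 3],
                             "sex": "M" if i % 2 else "F",
                             "donor": f"d{i % 2}"})
                i += 1
        meta = pd.DataFrame(rows)
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(4, len(meta))) + 1
        return ExpressionAtlas([f"g{i}" for i in range(4)], counts, meta)

    def test_celltype_at_boundary_kept_and_below_dropped(self):
        atlas = self._atlas({"A": 99, "B": 100})
        design = prepare_ageing_atlas(atlas, "facs", min_cells=100)
        assert design.celltype_levels == ("B",)
        assert design.dropped_celltypes == {"A": 99}

    def test_three_sizes_two_retained(self):
        atlas = self._atlas({"A": 50, "B": 100, "C": 400})
        design = prepare_ageing_atlas(atlas, "facs", min_cells=100)
        assert design.celltype_levels == ("B", "C")

    def test_wrong_platform_rejected(self):
        atlas = self._atlas({"A": 120})
        with pytest.raises(ValidationError, match="platform"):
            prepare_ageing_atlas(atlas, "10x", min_cells=100)


class TestFitGeneAgeModel:
    def test_single_age_level_rejected(self):
        sex, age, ct = _balanced_factors()
        age[:] = "3m"
        with pytest.raises(ValidationError):
            _design(np.random.default_rng(0).normal(size=age.size),
                    sex, age, ct)

    def test_null_p_values_uniform(self):
        sex, age, ct = _balanced_factors(n_per_cell=10)
        rng = np.random.default_rng(1)
        y = rng.normal(size=(500, sex.size))
        fits = fit_gene_age_model(_design(y, sex, age, ct))
        frac = (fits["p_age"] < 0.05).mean()
        # binomial 99% band around 0.05 with n=500
        band = 2.576 * np.sqrt(0.05 * 0.95 / 500)
        assert 0.05 - band <= frac <= 0.05 + band
        frac_int = (fits["p_int"] < 0.05).mean()
        assert 0.05 - band <= frac_int <= 0.05 + band

    def test_planted_uniform_twofold_shift_detected(self):
        sex, age, ct = _balanced_factors(n_per_cell=50)  # 300 cells
        rng = np.random.default_rng(2)
        step = np.array([{"3m": 0, "18m": 1, "24m": 2}[a] for a in age])
        y = rng.normal(size=(1, sex.size)) + step  # log2(2) per step
        fits = fit_gene_age_model(_design(y, sex, age, ct))
        assert fits["p_age"].iloc[0] < 0.01

    def test_interaction_reduces_to_additive_on_constructed_data(self):
        # y built from an exactly additive model: interaction SSR gain is 0
        sex, age, ct = _balanced_factors(n_per_cell=8)
        sex_eff = (sex == "M") * 0.5
        age_eff = np.array([{"3m": 0.0, "18m": 1.0, "24m": 2.0}[a] for a in age])
        ct_eff = (ct == "CT2") * 1.5
        y = 1.0 + sex_eff + age_eff + ct_eff
        fits = fit_gene_age_model(_design(y, sex, age, ct))
        # perfect additive fit: residual variance zero -> flagged not ok
        assert not fits["ok"].iloc[0]
        # with noise added, the interaction F stays at its null scale
        rng = np.random.default_rng(3)
        y2 = y + rng.normal(0, 0.1, size=y.size)
        fits2 = fit_gene_age_model(_design(y2, sex, age, ct))
        assert fits2["p_age"].iloc[0] < 1e-6
        assert fits2["p_int"].iloc[0] > 1e-4

    def test_matches_statsmodels_anova(self):
        import statsmodels.formula.api as smf
        sex, age, ct = _balanced_factors(n_per_cell=6)
        rng = np.random.default_rng(4)
        y = rng.normal(size=sex.size)
        fits = fit_gene_age_model(_design(y, sex, age, ct))
        df = pd.DataFrame({"y": y, "sex": sex, "age": age, "ct": ct})
        full = smf.ols("y ~ C(sex) + C(age, levels=['3m','18m','24m']) * C(ct)",
                       df).fit()
        add = smf.ols("y ~ C(sex) + C(age, levels=['3m','18m','24m']) + C(ct)",
                      df).fit()
        red = smf.ols("y ~ C(sex) + C(ct)", df).fit()
        f_age = ((red.ssr - add.ssr) / 2) / (add.ssr / add.df_resid)
        p_age = stats.f.sf(f_age, 2, add.df_resid)
        f_int = ((add.ssr - full.ssr) / 2) / (full.ssr / full.df_resid)
        p_int = stats.f.sf(f_int, 2, full.df_resid)
        assert fits["p_age"].iloc[0] == pytest.approx(p_age, abs=1e-10)
        assert fits["p_int"].iloc[0] == pytest.approx(p_int, abs=1e-10)


class TestClassification:
    def _fits(self, p_age, p_int):
        n = len(p_age)
        return pd.DataFrame({
            "p_age": p_age, "p_int": p_int,
            "f_age": np.ones(n), "f_int": np.ones(n),
            "p_age_overall": p_age, "ok": [True] * n,
        }, index=pd.Index([f"g{i}" for i in range(n)], name="gene"))

    def test_all_p_one_all_stable(self):
        out = classify_genes(self._fits([1.0] * 5, [1.0] * 5))
        assert (out["classification"] == "stable").all()

    def test_age_takes_precedence_over_interaction(self):
        out = classify_genes(self._fits([1e-6, 1.0], [1e-6, 1.0]))
        assert out["classification"].tolist() == ["age_significant", "stable"]

    def test_interaction_only_when_age_null(self):
        out = classify_genes(self._fits([0.9, 1.0], [1e-6, 1.0]))
        assert out["classification"].tolist() == [
            "interaction_significant", "stable"]

    def test_q_at_least_p(self):
        rng = np.random.default_rng(5)
        out = classify_genes(self._fits(rng.uniform(size=50),
                                        rng.uniform(size=50)))
        assert (out["q_age"] >= out["p_age"] - 1e-15).all()
        assert (out["q_int"] >= out["p_int"] - 1e-15).all()

    def test_planted_class_recovery_on_simulation(self):
        cfg = SimulationConfig(n_cell_types=3, cells_per_type=300, n_donors=3,
                               n_platforms=1, n_essential_like=10,
                               n_marker_like=0, n_noise=90,
                               age_effect=(0.1, 1.3), seed=123441)
        atlas, truth = simulate_ageing_atlas(cfg)
        design = prepare_ageing_atlas(atlas, "P1", min_cells=100)
        fits = classify_genes(fit_gene_age_model(design))
        cls = fits["classification"]
        age_recall = np.mean([cls[g] == "age_significant" for g in truth.age_main])
        int_recall = np.mean([cls[g] == "interaction_significant"
                              for g in truth.age_interaction])
        assert age_recall >= 0.8
        assert int_recall >= 0.8
        nulls = [g for g in fits.index
                 if g not in truth.age_main and g not in truth.age_interaction
                 and g not in truth.sex_genes]
        fp = np.mean([cls[g] != "stable" for g in nulls])
        assert fp <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(nulls))


class TestPerCelltypeCounts:
    def test_no_significant_genes_all_zero(self):
        sex, age, ct = _balanced_factors(n_per_cell=10)
        rng = np.random.default_rng(6)
        design = _design(rng.normal(size=(5, sex.size)), sex, age, ct)
        fits = classify_genes(fit_gene_age_model(design))
        counts = per_celltype_counts(fits, design)
        assert (counts == 0).all()

    def test_planted_single_celltype_effect_localised(self):
        sex, age, ct = _balanced_factors(n_per_cell=60, cts=("CT1", "CT2", "CT3"))
        rng = np.random.default_rng(7)
        step = np.array([{"3m": 0, "18m": 1, "24m": 2}[a] for a in age])
        y = rng.normal(size=(1, sex.size))
        y[0, ct == "CT2"] += 2.0 * step[ct == "CT2"]
        design = _design(y, sex, age, ct)
        counts = per_celltype_counts(pd.DataFrame(), design, genes=["g0"])
        assert counts["CT2"] == 1
        assert counts["CT1"] == 0 and counts["CT3"] == 0

    def test_counts_invariant_to_cell_order(self):
        sex, age, ct = _balanced_factors(n_per_cell=20)
        rng = np.random.default_rng(8)
        y = rng.normal(size=(3, sex.size))
        y[0] += np.array([{"3m": 0, "18m": 1, "24m": 2}[a] for a in age]) * \
            (ct == "CT1")
        perm = rng.permutation(sex.size)
        d1 = _design(y, sex, age, ct)
        d2 = _design(y[:, perm], sex[perm], age[perm], ct[perm])
        c1 = per_celltype_counts(pd.DataFrame(), d1, genes=["g0", "g1", "g2"])
        c2 = per_celltype_counts(pd.DataFrame(), d2, genes=["g0", "g1", "g2"])
        pd.testing.assert_series_equal(c1, c2)
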