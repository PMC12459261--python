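from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from scessentials import (GDITable, MarkerTable, PeakTable, TSSAnnotation,
                          ValidationError, correlate_es_accessibility,
                          essentiality_score, gdi_variability_test,
                          gene_accessibility, tf_enrichment)
from scessentials.filtering import DetectabilityReport


def _report(det: dict[str, dict[str, float]]) -> DetectabilityReport:
    """det: gene -> {cell_type: detection fraction} with group size 100."""
    rows = []
    for gene, groups in det.items():
        for group, frac in groups.items():
            rows.append({"gene": gene, "group": group,
                         "n_nonzero_cells": int(frac * 100),
                         "group_size": 100, "detection_fraction": frac})
    table = pd.DataFrame(rows)
    passes = pd.Series(True, index=sorted(det))
    return DetectabilityReport("cell_type", 3, table, passes)


def _markers(records):
    return MarkerTable(pd.DataFrame(records, columns=["gene", "cell_type"]))


class TestEssentialityScore:
    def test_full_detection_no_marker_scores_one(self):
        es = essentiality_score(_report({"g": {"A": 1.0, "B": 1.0}}),
                                _markers([]))
        assert es.loc["g", "es"] == 1.0

    def test_marker_evidence_halves_score(self):
        es = essentiality_score(_report({"g": {"A": 0.5, "B": 0.5}}),
                                _markers([("g", "A")]))
        assert es.loc["g", "es"] == 0.25
        assert es.loc["g", "marker_evidence"] == 1

    def test_score_strictly_decreasing_in_marker_count(self):
        scores = []
        for m in range(4):
            markers = _markers([("g", f"ct{i}") for i in range(m)])
            es = essentiality_score(_report({"g": {"A": 0.8}}), markers)
            scores.append(es.loc["g", "es"])
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_es_bounded_by_mean_detection(self):
        es = essentiality_score(
            _report({"g1": {"A": 0.9, "B": 0.3}, "g2": {"A": 0.2, "B": 0.4}}),
            _markers([("g1", "A"), ("g2", "B"), ("g2", "C")]))
        assert (es["es"] <= es["mean_detection"] + 1e-15).all()

    def test_duplicating_every_cell_type_leaves_es_unchanged(self):
        base = {"g1": {"A": 0.9, "B": 0.3}, "g2": {"A": 0.5, "B": 0.7}}
        doubled = {g: {**cts, **{ct + "_copy": v for ct, v in cts.items()}}
                   for g, cts in base.items()}
        m = _markers([("g1", "A")])
        es1 = essentiality_score(_report(base), m)
        es2 = essentiality_score(_report(doubled), m)
        assert np.allclose(es1["es"], es2.loc[es1.index, "es"])

    def test_ranking_ties_broken_by_gene_id(self):
        es = essentiality_score(
            _report({"gb": {"A": 0.5}, "ga": {"A": 0.5}}), _markers([]))
        assert list(es.index) == ["ga", "gb"]


class TestGDIVariability:
    @staticmethod
    def _gdi(n_low=10, n_med=60, n_high=10):
        genes, cats = [], []
        for cat, n in (("low", n_low), ("medium", n_med), ("high", n_high)):
            for i in range(n):
                genes.append(f"{cat}{i}")
                cats.append(cat)
        return GDITable(pd.DataFrame({
            "gene": genes, "gdi_phred": np.ones(len(genes)), "category": cats}))

    def test_identical_residuals_give_p_one(self):
        gdi = self._gdi()
        residuals = pd.Series(1.0, index=gdi.table["gene"])
        out = gdi_variability_test(residuals, gdi, reps=5, seed=1)
        per_rep = out[out["rep"] != "median"]
        assert (per_rep["H"] == 0.0).all()
        assert (per_rep["p_value"] == 1.0).all()

    def test_planted_high_category_shift_detected(self):
        gdi = self._gdi(n_low=39, n_med=200, n_high=39)
        rng = np.random.default_rng(2)
        residuals = pd.Series(rng.normal(size=len(gdi.table)),
                              index=gdi.table["gene"])
        high = [g for g in residuals.index if g.startswith("high")]
        residuals.loc[high] += 2.0
        out = gdi_variability_test(residuals, gdi, downsample_to=39,
                                   reps=10, seed=3)
        assert out.loc[out["rep"] == "median", "p_value"].iloc[0] < 0.05

    def test_same_seed_identical_results(self):
        gdi = self._gdi()
        rng = np.random.default_rng(4)
        residuals = pd.Series(rng.normal(size=len(gdi.table)),
                              index=gdi.table["gene"])
        o1 = gdi_variability_test(residuals, gdi, reps=5, seed=7)
        o2 = gdi_variability_test(residuals, gdi, reps=5, seed=7)
        pd.testing.assert_frame_equal(o1, o2)

    def test_oversized_downsample_rejected(self):
        gdi = self._gdi(n_med=5)
        residuals = pd.Series(1.0, index=gdi.table["gene"])
        with pytest.raises(ValidationError, match="downsample"):
            gdi_variability_test(residuals, gdi, downsample_to=10)


class TestAccessibility:
    @staticmethod
    def _tables(peaks, tss):
        pt = PeakTable(pd.DataFrame(peaks, columns=["chrom", "start", "end", "ct1"]))
        tt = TSSAnnotation(pd.DataFrame(tss, columns=["chrom", "tss", "strand", "gene"]))
        return pt, tt

    def test_non_overlapping_gene_omitted(self):
        pt, tt = self._tables([("chr1", 100, 200, 0.5)],
                              [("chr1", 1500, "+", "g")])
        assert gene_accessibility(pt, tt, window_bp=1000).empty

    def test_mean_of_two_overlapping_peaks(self):
        pt, tt = self._tables([("chr1", 100, 200, 0.4), ("chr1", 300, 400, 0.8)],
                              [("chr1", 150, "+", "g")])
        out = gene_accessibility(pt, tt, window_bp=1000)
        assert out.iloc[0]["accessibility"] == pytest.approx(0.6)
        assert out.iloc[0]["n_peaks"] == 2

    def test_window_zero_requires_containment(self):
        pt, tt = self._tables([("chr1", 100, 200, 0.4)],
                              [("chr1", 150, "+", "in"),
                               ("chr1", 200, "+", "out")])
        out = gene_accessibility(pt, tt, window_bp=0)
        assert list(out["gene"]) == ["in"]

    def test_sum_aggregation_by_flag(self):
        pt, tt = self._tables([("chr1", 100, 200, 0.4), ("chr1", 300, 400, 0.8)],
                              [("chr1", 150, "+", "g")])
        out = gene_accessibility(pt, tt, window_bp=1000, aggregate="sum")
        assert out.iloc[0]["accessibility"] == pytest.approx(1.2)

    def test_peak_order_invariance(self):
        peaks = [("chr1", 300, 400, 0.8), ("chr1", 100, 200, 0.4)]
        pt1, tt = self._tables(peaks, [("chr1", 150, "+", "g")])
        pt2, _ = self._tables(peaks[::-1], [("chr1", 150, "+", "g")])
        o1 = gene_accessibility(pt1, tt)
        o2 = gene_accessibility(pt2, tt)
        pd.testing.assert_frame_equal(o1, o2)

    def test_chromosome_mismatch_no_assignment(self):
        pt, tt = self._tables([("chr2", 100, 200, 0.4)],
                              [("chr1", 150, "+", "g")])
        assert gene_accessibility(pt, tt).empty


class TestESAccessibilityCorrelation:
    @staticmethod
    def _es(values: dict):
        return pd.DataFrame({"es": pd.Series(values)},
                            index=pd.Index(values, name="gene"))

    def test_monotone_accessibility_gives_rho_one(self):
        es = self._es({f"g{i}": 0.1 * (i + 1) for i in range(6)})
        acc = pd.DataFrame({"gene": es.index, "cell_type": "A",
                            "accessibility": np.arange(6) * 2.0, "n_peaks": 1})
        rho, p = correlate_es_accessibility(es, acc, "A")
        assert rho == 1.0 and p < 0.01

    def test_disjoint_gene_sets_rejected(self):
        es = self._es({"a": 0.5, "b": 0.6, "c": 0.7})
        acc = pd.DataFrame({"gene": ["x", "y", "z"], "cell_type": "A",
                            "accessibility": [1.0, 2.0, 3.0], "n_peaks": 1})
        with pytest.raises(ValidationError):
            correlate_es_accessibility(es, acc, "A")


class TestTFEnrichment:
    def test_zero_overlap_p_one(self):
        k, p = tf_enrichment({"a", "b"}, {"c", "d"}, background_size=100)
        assert k == 0 and p == 1.0

    def test_worked_case_five_over_210(self):
        # N=10, K=5 TFs, n=4 drawn, overlap 4: C(5,4)C(5,0)/C(10,4) = 5/210
        gene_set = {"t1", "t2", "t3", "t4"}
        tfs = {"t1", "t2", "t3", "t4", "t5"}
        k, p = tf_enrichment(gene_set, tfs, background_size=10)
        assert k == 4
        assert p == pytest.approx(5 / 210, abs=1e-12)

    def test_everything_is_tf_p_one(self):
        genes = {f"g{i}" for i in range(10)}
        k, p = tf_enrichment(genes, genes, background_size=10)
        assert k == 10 and p == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small_universe(self):
        # P(X >= k) by direct combinatorics for N <= 12
        for n_universe in (8, 10, 12):
            for n_tf in (3, 5):
                for n_set in (2, 4):
                    for k in range(0, min(n_tf, n_set) + 1):
                        expected = sum(
                            comb(n_tf, j) * comb(n_universe - n_tf, n_set - j)
                            for j in range(k, min(n_tf, n_set) + 1)
                            if n_set - j <= n_universe - n_tf
                        ) / comb(n_universe, n_set)
                        genes = {f"t{i}" for i in range(k)} | \
                                {f"x{i}" for i in range(n_set - k)}
                        tfs = {f"t{i}" for i in range(n_tf)}
                        _, p = tf_enrichment(genes, tfs, n_universe)
                        assert p == pytest.approx(expected, abs=1e-12)
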