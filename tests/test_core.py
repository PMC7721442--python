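"""Unit tests for the scoring core: MAD, origin OLS, RANSAC, raw/RM scores, calls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from flexiquantlf import (
    Category,
    FitError,
    RansacConfig,
    analyze_protein,
    best_of_k_fits,
    classify,
    fit_origin_ols,
    flag_high_outliers,
    mad,
    median_reference_vector,
    ransac_fit,
    raw_scores,
    rm_scores,
)
from conftest import make_table


class TestMad:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 1, 1], 0.0),
            ([10, 20, 30, 30, 40, 50], 10.0),
            ([1, 2, 3, 4, 5], 1.0),
        ],
    )
    def test_values(self, values, expected):
        assert mad(values) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mad([])

    def test_no_consistency_factor(self):
        # deviation unit is the MAD itself, not 1.4826*MAD
        assert mad([0, 0, 1, 1]) == 0.5


class TestOriginOls:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [2, 4, 6], 2.0),
            ([1, 2], [2, 3], 1.6),  # closed form sum(xy)/sum(x^2) = 8/5
            ([10, 20, 30, 40, 50], [10, 20, 30, 40, 50], 1.0),
        ],
    )
    def test_slope(self, x, y, expected):
        assert fit_origin_ols(np.array(x), np.array(y)) == pytest.approx(expected)

    def test_subset(self):
        x = np.array([1.0, 2.0, 100.0])
        y = np.array([2.0, 4.0, 1.0])
        assert fit_origin_ols(x, y, subset=[0, 1]) == pytest.approx(2.0)

    def test_degenerate(self):
        with pytest.raises(FitError):
            fit_origin_ols(np.array([0.0, 0.0]), np.array([1.0, 2.0]))


class TestReferenceVector:
    def test_median_of_three(self):
        table = make_table(
            {"r1": [10, 20], "r2": [12, 22], "r3": [11, 21]},
            [("A", "p1"), ("A", "p2")],
            reference=["r1", "r2", "r3"],
        )
        ref, dropped = median_reference_vector(table, "A")
        assert list(ref) == [11, 21]
        assert dropped == []

    def test_single_reference_is_identity(self):
        table = make_table(
            {"r1": [5, 7, 9]},
            [("A", "p1"), ("A", "p2"), ("A", "p3")],
            reference=["r1"],
        )
        ref, _ = median_reference_vector(table, "A")
        assert list(ref) == [5, 7, 9]

    def test_zero_reference_peptide_excluded(self):
        table = make_table(
            {"r1": [10, 0], "r2": [12, 0]},
            [("A", "p1"), ("A", "p2")],
            reference=["r1", "r2"],
        )
        ref, dropped = median_reference_vector(table, "A")
        assert list(ref) == [11]
        assert dropped == ["p2"]


class TestRansac:
    def test_worked_example(self):
        x = np.array([10.0, 20, 30, 40, 50, 60])
        y = np.array([10.0, 20, 30, 40, 50, 30])
        fit = ransac_fit(x, y, seed=0)
        # MAD(y) = 10, so peptide 6 (residual -30 at slope 1) is the only outlier
        assert fit.slope == pytest.approx(1.0)
        assert list(fit.inlier_mask) == [True] * 5 + [False]
        assert fit.residual_threshold == pytest.approx(100.0)

    @pytest.mark.parametrize("scale", [1.0, 3.0])
    def test_exact_proportionality(self, scale):
        x = np.array([1.0, 2, 3, 4, 5])
        fit = ransac_fit(x, scale * x, seed=1)
        assert fit.slope == pytest.approx(scale)
        assert fit.inlier_mask.all()
        assert fit.r_squared == pytest.approx(1.0)

    def test_zero_mad_no_consensus_fails(self):
        # constant y over distinct x: no two points share an exact origin line
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.full(5, 5.0)
        with pytest.raises(FitError):
            ransac_fit(x, y, seed=0)

    def test_deterministic_given_seed(self, rng):
        x = 10 ** rng.normal(2, 0.4, 8)
        y = 1.7 * x * np.exp(rng.normal(0, 0.08, 8))
        a = ransac_fit(x, y, seed=42)
        b = ransac_fit(x, y, seed=42)
        assert a.slope == b.slope
        assert (a.inlier_mask == b.inlier_mask).all()


class TestBestOfK:
    def test_clean_data_first_initiation_wins(self):
        x = np.array([1.0, 2, 3, 4, 5])
        fit = best_of_k_fits(x, 2 * x, seed=7)
        assert fit.initiation_index == 0
        assert fit.slope == pytest.approx(2.0)

    def test_worked_example_all_initiations_agree(self):
        x = np.array([10.0, 20, 30, 40, 50, 60])
        y = np.array([10.0, 20, 30, 40, 50, 30])
        fit = best_of_k_fits(x, y, RansacConfig(n_initiations=30), seed=11)
        assert fit.slope == pytest.approx(1.0)

    def test_selects_higher_r2_consensus(self, two_consensus_table):
        # with many initiations the refit with smaller full-data residuals wins
        ref, _ = median_reference_vector(two_consensus_table, "B")
        x = ref.to_numpy()
        y = two_consensus_table.data.loc["s"].to_numpy()
        fit = best_of_k_fits(x, y, RansacConfig(n_initiations=30), seed=3)
        assert fit.slope == pytest.approx(2.0)


class TestRawScores:
    def test_on_line_scores_one(self):
        x = np.array([10.0, 20.0])
        assert raw_scores(x, 1.5 * x, 1.5) == pytest.approx([1.0, 1.0])

    def test_half_intensity(self):
        assert raw_scores(np.array([60.0]), np.array([30.0]), 1.0)[0] == pytest.approx(0.5)

    def test_complete_loss(self):
        assert raw_scores(np.array([60.0]), np.array([0.0]), 1.0)[0] == 0.0

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            raw_scores(np.array([1.0]), np.array([1.0]), 0.0)


class TestOutlierGate:
    def test_zero_mad_no_flags(self):
        flags, thr = flag_high_outliers(np.array([1, 1, 1, 1, 1, 0.5]))
        assert thr == pytest.approx(1.0)
        assert not flags.any()

    def test_flags_only_high_side(self):
        flags, thr = flag_high_outliers(np.array([1.0, 1.0, 1.02, 0.98, 2.0]))
        assert thr == pytest.approx(1.06)
        assert list(flags) == [False, False, False, False, True]

    @pytest.mark.parametrize("c", [0.2, 1.0, 5.0])
    def test_constant_scores_unflagged(self, c):
        flags, _ = flag_high_outliers(np.full(3, c))
        assert not flags.any()


class TestRmScores:
    def test_top3_median_of_ones(self):
        s = np.array([1, 1, 1, 1, 1, 0.5])
        rm, scaling = rm_scores(s, np.zeros(6, dtype=bool))
        assert scaling == 1.0
        assert rm == pytest.approx(s)

    def test_top3_median_is_middle_value(self):
        s = np.array([0.9, 1.0, 1.1, 0.5])
        rm, scaling = rm_scores(s, np.zeros(4, dtype=bool))
        assert scaling == 1.0
        assert rm == pytest.approx(s)

    @pytest.mark.parametrize("c", [0.3, 1.0, 7.0])
    def test_self_normalisation(self, c):
        rm, _ = rm_scores(np.full(5, c), np.zeros(5, dtype=bool))
        assert rm == pytest.approx(np.ones(5))

    def test_flagged_positions_nan(self):
        s = np.array([1.0, 1.0, 1.0, 1.0, 3.0])
        flags = np.array([False, False, False, False, True])
        rm, _ = rm_scores(s, flags)
        assert np.isnan(rm[4]) and np.isfinite(rm[:4]).all()

    def test_fewer_than_three_survivors_errors(self):
        with pytest.raises(FitError):
            rm_scores(np.array([1.0, 1.0, 1.0]), np.array([True, True, False]))


class TestClassify:
    @pytest.mark.parametrize(
        "rm, expected",
        [
            (0.49, Category.LIKELY),
            (0.5, Category.POSSIBLY),
            (0.59, Category.POSSIBLY),
            (0.6, Category.LIKELY_NOT),
            (1.0, Category.LIKELY_NOT),
            (0.0, Category.LIKELY),
        ],
    )
    def test_boundaries(self, rm, expected):
        assert classify(rm) is expected

    def test_custom_cutoffs(self):
        config = RansacConfig(cutoff_likely=0.3, cutoff_possibly=0.8)
        assert classify(0.4, config) is Category.POSSIBLY


class TestAnalyzeProtein:
    def test_worked_example_end_to_end(self, six_peptide_table):
        res = analyze_protein(six_peptide_table, "A", seed=1)
        assert res.fits["t1"].slope == pytest.approx(1.0)
        assert res.scores["t1"].raw_scores == pytest.approx([1, 1, 1, 1, 1, 0.5])
        assert not res.scores["t1"].outlier_flags.any()
        assert res.scores["t1"].rm_scores == pytest.approx([1, 1, 1, 1, 1, 0.5])
        calls = res.calls("t1").set_index("peptide")["category"]
        assert calls["p6"] == "possibly"
        assert (calls.drop("p6") == "likely_not").all()

    def test_sample_equal_to_reference(self, rng):
        x = 10 ** rng.normal(6, 0.5, 8)
        table = make_table(
            {"ref": list(x), "s": list(x)},
            [("A", f"p{i}") for i in range(8)],
            reference=["ref"],
        )
        res = analyze_protein(table, "A", seed=0)
        assert res.scores["s"].rm_scores == pytest.approx(np.ones(8))
        assert (res.calls("s")["category"] == "likely_not").all()

    def test_global_abundance_change_absorbed_by_slope(self, rng):
        x = 10 ** rng.normal(6, 0.5, 8)
        table = make_table(
            {"ref": list(x), "s": list(2 * x)},
            [("A", f"p{i}") for i in range(8)],
            reference=["ref"],
        )
        res = analyze_protein(table, "A", seed=0)
        assert res.fits["s"].slope == pytest.approx(2.0)
        assert res.scores["s"].rm_scores == pytest.approx(np.ones(8))

    def test_too_few_peptides_mentions_superprotein(self):
        table = make_table(
            {"ref": [1, 2, 3], "s": [1, 2, 3]},
            [("A", f"p{i}") for i in range(3)],
            reference=["ref"],
        )
        with pytest.raises(FitError, match="superprotein"):
            analyze_protein(table, "A")

    def test_zero_reference_peptide_dropped_before_min_check(self):
        table = make_table(
            {"ref": [10, 20, 30, 40, 50, 0], "s": [10, 20, 30, 40, 50, 60]},
            [("A", f"p{i}") for i in range(6)],
            reference=["ref"],
        )
        res = analyze_protein(table, "A", seed=0)
        assert res.dropped_peptides == ["p5"]
        assert len(res.peptides) == 5

    def test_failed_sample_recorded_not_crashing(self):
        # constant y has MAD 0 and no exact 2-point origin consensus
        table = make_table(
            {"ref": [1, 2, 3, 4, 5], "bad": [5, 5, 5, 5, 5], "good": [2, 4, 6, 8, 10]},
            [("A", f"p{i}") for i in range(5)],
            reference=["ref"],
        )
        res = analyze_protein(table, "A", seed=0)
        assert res.failed_samples == ["bad"]
        assert np.isnan(res.scores["bad"].rm_scores).all()
        assert res.fits["good"].slope == pytest.approx(2.0)
        assert (res.calls("bad")["category"] == "not_evaluated").all()

    def test_modification_extent_conservation(self, six_peptide_table):
        res = analyze_protein(six_peptide_table, "A", seed=5)
        sc = res.scores["t1"]
        np.testing.assert_array_equal(sc.modification_extent, 1.0 - sc.rm_scores)
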