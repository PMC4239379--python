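"""Digital-expression rules and qPCR standard-curve quantification."""
import numpy as np
import pandas as pd
import pytest

import oracles
from xylptools.expression import (
    est_specificity,
    fit_standard_curve,
    fold_change_filter,
    hierarchical_cluster,
    mpss_classify,
    normalize_microarray,
    relative_expression,
)
from xylptools.io import ExpressionMatrix, FormatError


def _matrix(data, units, columns=None):
    return ExpressionMatrix(pd.DataFrame(data, columns=columns), units)


class TestEstSpecificity:
    def test_majority_tissue_flagged(self):
        m = _matrix({"stem": [6], "root": [2], "leaf": [2]}, "count")
        (r,) = est_specificity(m)
        assert r.specific and r.specific_tissue == "stem" and r.total == 10

    def test_exact_half_is_not_specific(self):
        m = _matrix({"stem": [5], "root": [5]}, "count")
        (r,) = est_specificity(m)
        assert not r.specific and r.specific_tissue is None

    def test_zero_total_is_not_specific(self):
        (r,) = est_specificity(_matrix({"a": [0], "b": [0]}, "count"))
        assert not r.specific

    def test_non_integer_counts_rejected(self):
        with pytest.raises(FormatError):
            est_specificity(_matrix({"a": [1.5], "b": [2.0]}, "count"))

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(19)
        for _ in range(100):
            counts = {f"t{i}": [int(v)] for i, v in
                      enumerate(rng.integers(0, 20, size=4))}
            (r,) = est_specificity(_matrix(counts, "count"))
            want = oracles.est_specific_bruteforce(
                {k: v[0] for k, v in counts.items()})
            assert (r.specific_tissue if r.specific else None) == want


class TestMpssClassify:
    @pytest.mark.parametrize("max_tpm,expected", [
        (49, "low"), (50, "moderate"), (500, "moderate"), (501, "strong")])
    def test_boundaries(self, max_tpm, expected):
        m = _matrix({"lib1": [1.0], "lib2": [float(max_tpm)]}, "tpm")
        (r,) = mpss_classify(m)
        assert r.gene_class == expected and r.statistic == max_tpm

    def test_every_gene_gets_exactly_one_class(self):
        rng = np.random.default_rng(2)
        m = _matrix({f"l{i}": rng.uniform(0, 1000, 30) for i in range(5)}, "tpm")
        classes = [r.gene_class for r in mpss_classify(m)]
        assert len(classes) == 30
        assert set(classes) <= {"low", "moderate", "strong"}

    def test_class_is_monotone_in_statistic(self):
        m = _matrix({"l1": [10.0, 100.0, 1000.0]}, "tpm")
        classes = [r.gene_class for r in mpss_classify(m)]
        assert classes == ["low", "moderate", "strong"]

    def test_mean_statistic_option(self):
        m = _matrix({"l1": [600.0], "l2": [0.0]}, "tpm")
        assert mpss_classify(m)[0].gene_class == "strong"
        assert mpss_classify(m, statistic="mean")[0].gene_class == "moderate"


class TestNormalization:
    def test_constant_matrix_normalizes_to_zero(self):
        m = _matrix({"a": [7.0, 7.0], "b": [7.0, 7.0]}, "signal")
        for mode in ("global-mean", "gene-mean"):
            out = normalize_microarray(m, mode)
            assert np.allclose(out.log_ratios.to_numpy(), 0.0)

    def test_global_mean_worked_example(self):
        m = _matrix({"t": [2.0, 4.0]}, "signal")
        out = normalize_microarray(m, "global-mean", log_base=2)
        assert out.log_ratios["t"].tolist() == pytest.approx(
            [-0.585, 0.415], abs=5e-4)

    def test_gene_mean_worked_example(self):
        m = _matrix({"t1": [2.0], "t2": [8.0]}, "signal")
        out = normalize_microarray(m, "gene-mean", log_base=2)
        assert out.log_ratios.iloc[0].tolist() == pytest.approx([-1.0, 1.0])

    def test_nonpositive_signal_rejected(self):
        with pytest.raises(FormatError):
            normalize_microarray(_matrix({"t": [0.0, 1.0]}, "signal"))

    def test_grand_mean_recomputed_after_adding_mean_gene(self):
        base = _matrix({"t1": [2.0, 6.0], "t2": [4.0, 8.0]}, "signal")
        out1 = normalize_microarray(base)
        grand = base.data.to_numpy().mean()
        extended = _matrix({"t1": [2.0, 6.0, grand], "t2": [4.0, 8.0, grand]},
                           "signal")
        out2 = normalize_microarray(extended)
        # the added gene equals the grand mean, so the divisor is unchanged
        assert np.allclose(out1.log_ratios.to_numpy(),
                           out2.log_ratios.to_numpy()[:2])
        assert np.allclose(out2.log_ratios.to_numpy()[2], 0.0)


class TestClustering:
    def test_identical_rows_merge_at_height_zero(self):
        m = _matrix({"t1": [1.0, 1.0, 5.0], "t2": [2.0, 2.0, 1.0],
                     "t3": [3.0, 3.0, 4.0]}, "signal")
        tree = hierarchical_cluster(normalize_microarray(m))
        assert tree.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_correlated_pairs_merge_first(self):
        # rows 0,1 perfectly correlated; rows 2,3 perfectly correlated;
        # the two pairs anti-correlated with each other
        data = pd.DataFrame([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0],
                             [3.0, 2.0, 1.0], [6.0, 4.0, 2.0]],
                            index=list("abcd"), columns=["t1", "t2", "t3"])
        norm = normalize_microarray(ExpressionMatrix(data, "signal"), "gene-mean")
        tree = hierarchical_cluster(norm)
        clusters = tree.flat_clusters(2)
        assert clusters["a"] == clusters["b"]
        assert clusters["c"] == clusters["d"]
        assert clusters["a"] != clusters["c"]

    def test_row_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame(rng.uniform(1, 10, (6, 4)),
                            index=[f"g{i}" for i in range(6)])
        m = ExpressionMatrix(data, "signal")
        t1 = hierarchical_cluster(normalize_microarray(m))
        shuffled = ExpressionMatrix(data.iloc[::-1], "signal")
        t2 = hierarchical_cluster(normalize_microarray(shuffled))
        assert t1.flat_clusters(3) == t2.flat_clusters(3)

    def test_zero_variance_gene_requires_fallback(self):
        m = _matrix({"t1": [1.0, 2.0], "t2": [1.0, 3.0]}, "signal")
        norm = normalize_microarray(m, "gene-mean")
        norm.log_ratios.iloc[0] = 0.0  # flat profile
        with pytest.raises(ValueError, match="zero-variance"):
            hierarchical_cluster(norm)
        tree = hierarchical_cluster(norm, fallback_to_euclidean=True)
        assert tree.metric == "euclidean"


class TestFoldChange:
    @pytest.mark.parametrize("treated,flagged,direction", [
        (200.0, True, "up"),     # exactly 2-fold: boundary inclusive
        (150.0, False, "none"),
        (50.0, True, "down"),
    ])
    def test_boundaries(self, treated, flagged, direction):
        c = _matrix({"ds": [100.0]}, "signal")
        t = _matrix({"ds": [treated]}, "signal")
        (r,) = fold_change_filter(c, t)
        assert r.flagged is flagged and r.direction == direction

    def test_zero_control_rejected(self):
        c = _matrix({"ds": [0.0]}, "signal")
        t = _matrix({"ds": [10.0]}, "signal")
        with pytest.raises(FormatError):
            fold_change_filter(c, t)

    def test_mismatched_gene_sets_rejected(self):
        c = ExpressionMatrix(pd.DataFrame({"ds": [1.0]}, index=["g1"]), "signal")
        t = ExpressionMatrix(pd.DataFrame({"ds": [1.0]}, index=["g2"]), "signal")
        with pytest.raises(FormatError):
            fold_change_filter(c, t)


PERFECT_CTS = {1.0: [24.755], 3.0: [23.170], 9.0: [21.585], 27.0: [20.000]}


class TestStandardCurve:
    def test_perfect_doubling_series(self):
        curve = fit_standard_curve(PERFECT_CTS, "UBQ5")
        assert curve.slope == pytest.approx(-3.322, abs=5e-4)
        assert curve.efficiency == pytest.approx(1.00, abs=5e-3)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.valid

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve({1.0: [24.0], 3.0: [23.0]})

    def test_rising_slope_flagged_invalid(self):
        curve = fit_standard_curve({1.0: [20.0], 3.0: [21.0], 9.0: [22.0]})
        assert not curve.valid
        with pytest.raises(ValueError):
            curve.quantity(21.0)

    def test_replicates_averaged_before_regression(self):
        jittered = {q: [ct[0] - 0.2, ct[0] + 0.2]
                    for q, ct in PERFECT_CTS.items()}
        curve = fit_standard_curve(jittered)
        assert curve.slope == pytest.approx(-3.322, abs=5e-4)

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(12)
        true_eff = 0.95
        slope = -1.0 / np.log10(1.0 + true_eff)
        cts = {q: list(25.0 + slope * np.log10(q) + rng.normal(0, 0.05, 3))
               for q in (1.0, 3.0, 9.0, 27.0)}
        curve = fit_standard_curve(cts)
        assert abs(curve.efficiency - true_eff) < 0.05


class TestRelativeExpression:
    def test_equal_cts_at_quantity_one_give_unit_level(self):
        target = fit_standard_curve(PERFECT_CTS, "gene")
        ref = fit_standard_curve({q: [ct[0] + 1.0] for q, ct in PERFECT_CTS.items()},
                                 "UBQ5")
        r = relative_expression(target, ref, 24.755, 25.755)
        assert r.relative_level == pytest.approx(1.0)

    def test_unknown_ct_quantity_closed_form(self):
        curve = fit_standard_curve(PERFECT_CTS, "gene")
        assert curve.quantity(22.0) == pytest.approx(6.75, abs=5e-3)

    def test_doubling_target_quantity_doubles_level(self):
        curve = fit_standard_curve(PERFECT_CTS, "gene")
        ref = fit_standard_curve(PERFECT_CTS, "UBQ5")
        base = relative_expression(curve, ref, 22.0, 24.0).relative_level
        # one fewer cycle on a perfect curve means twice the template
        doubled = relative_expression(curve, ref, 22.0 + curve.slope * np.log10(2),
                                      24.0).relative_level
        assert doubled == pytest.approx(2.0 * base, rel=1e-6)
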