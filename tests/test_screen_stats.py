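"""Screen statistics: aggregation, synergy, spectrum, Fisher, outliers, Dunnett."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from flyssvep import (
    GenotypeSummary,
    SignalingPoint,
    SynergyPoint,
    anova_dunnett,
    detect_outliers,
    enrichment_test,
    fisher_exact_2x2,
    fit_spectrum,
    fold_change,
    signaling_points,
    summarize_genotype,
    synergy_xy,
)


# ---------------------------------------------------------------------------
# independent oracles


def fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided Fisher p by rational hypergeometric enumeration.

    Sums P(table) over all tables with the observed margins whose
    probability does not exceed the observed table's.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom) for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


# ---------------------------------------------------------------------------
# aggregation


class TestSummarizeGenotype:
    def test_constant_sample(self):
        s = summarize_genotype([3.0, 3.0, 3.0])
        assert (s.mean, s.se, s.median, s.iqr) == (3.0, 0.0, 3.0, 0.0)

    def test_known_se(self):
        s = summarize_genotype([1.0, 2.0, 3.0, 4.0])
        assert s.mean == 2.5
        assert s.se == pytest.approx(np.std([1, 2, 3, 4], ddof=1) / 2)
        assert s.se == pytest.approx(0.6455, abs=1e-4)

    def test_single_value_convention(self):
        s = summarize_genotype([7.0])
        assert (s.n, s.mean, s.se, s.median) == (1, 7.0, 0.0, 7.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_genotype([])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        data=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30),
        k=st.floats(0.01, 50),
    )
    def test_permutation_invariance_and_scale_equivariance(self, data, k):
        a = summarize_genotype(data)
        b = summarize_genotype(data[::-1])
        for field in ("mean", "se", "median", "iqr"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), rel=1e-12)
        s = summarize_genotype([k * x for x in data])
        for field in ("mean", "se", "median", "iqr"):
            assert getattr(s, field) == pytest.approx(
                k * getattr(a, field), rel=1e-9, abs=1e-9
            )


class TestFoldChange:
    def test_equal_means_give_unity(self):
        a = summarize_genotype([2.0, 2.0])
        assert fold_change(a, a) == 1.0

    def test_direct_ratio(self):
        assert fold_change(
            summarize_genotype([8.2]), summarize_genotype([2.0])
        ) == pytest.approx(4.1)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            fold_change(summarize_genotype([1.0]), summarize_genotype([0.0]))


# ---------------------------------------------------------------------------
# synergy


def gsum(mean, se=0.0, harmonic="2F1", rab=None, label="control"):
    return GenotypeSummary(
        n=10, mean=mean, se=se, median=mean, iqr=0.0,
        harmonic=harmonic, genotype_label=label, rab_id=rab,
    )


class TestSynergyXY:
    def test_null_point(self):
        p = synergy_xy(gsum(1.0), gsum(1.0, rab="Rab7"), gsum(1.0, rab="Rab7"))
        assert (p.X, p.Y) == (0.0, 0.0)

    def test_subtraction(self):
        p = synergy_xy(gsum(2.0), gsum(5.0, rab="Rab7"), gsum(9.0, rab="Rab7"))
        assert (p.X, p.Y) == (3.0, 4.0)

    def test_se_in_quadrature(self):
        p = synergy_xy(gsum(0, se=0.3), gsum(0, se=0.4, rab="R"), gsum(0, se=0.0, rab="R"))
        assert p.se_X == pytest.approx(0.5)
        assert p.se_Y == pytest.approx(0.4)

    def test_harmonic_mismatch_rejected(self):
        with pytest.raises(ValueError, match="harmonic"):
            synergy_xy(gsum(1, harmonic="1F1"), gsum(1), gsum(1))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        means=st.tuples(
            st.floats(-100, 100), st.floats(-100, 100), st.floats(-100, 100)
        )
    )
    def test_conservation(self, means):
        ctrl, rab, both = (gsum(m, rab="R") for m in means)
        p = synergy_xy(ctrl, rab, both)
        assert p.X + p.Y == pytest.approx(both.mean - ctrl.mean, rel=1e-12, abs=1e-12)


# ---------------------------------------------------------------------------
# spectrum fit


def spoint(rab, x, y):
    return SynergyPoint(rab_id=rab, X=x, Y=y, se_X=0.0, se_Y=0.0, harmonic="2F1")


class TestFitSpectrum:
    def test_exact_line_recovered(self):
        pts = [spoint(f"R{i}", x, 2 * x + 1) for i, x in enumerate([0.0, 1.0, 2.0, 5.0])]
        fit = fit_spectrum(pts)
        assert fit.slope == pytest.approx(2.0, rel=1e-9)
        assert fit.intercept == pytest.approx(1.0, rel=1e-9)
        assert np.allclose(fit.residuals, 0.0, atol=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_order_invariance(self):
        pts = [spoint("a", 0, 1), spoint("b", 1, 5), spoint("c", 2, 2)]
        f1, f2 = fit_spectrum(pts), fit_spectrum(pts[::-1])
        assert f1.slope == pytest.approx(f2.slope)
        assert f1.intercept == pytest.approx(f2.intercept)

    def test_inverse_relation_gives_negative_slope(self):
        rng = np.random.default_rng(0)
        # high-synergy Rabs: small X, large Y; high-solo Rabs: large X, small Y
        pts = [spoint(f"syn{i}", rng.normal(0, 0.2), 8 + rng.normal(0, 0.5)) for i in range(5)]
        pts += [spoint(f"solo{i}", 6 + rng.normal(0, 0.2), rng.normal(0, 0.5)) for i in range(5)]
        assert fit_spectrum(pts).slope < 0

    def test_residuals_sum_to_zero_and_classification(self):
        pts = [spoint("a", 0, 0), spoint("b", 1, 3), spoint("c", 2, 2), spoint("d", 3, 7)]
        fit = fit_spectrum(pts)
        assert np.sum(fit.residuals) == pytest.approx(0.0, abs=1e-9)
        assert np.array_equal(fit.above_line, fit.residuals > 0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_spectrum([spoint("a", 0, 1), spoint("b", 1, 2)])
        with pytest.raises(ValueError, match="variance"):
            fit_spectrum([spoint("a", 1, 1), spoint("b", 1, 2), spoint("c", 1, 3)])

    def test_matches_statsmodels_ols(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=12)
        pts = [spoint(f"R{i}", xi, yi) for i, (xi, yi) in enumerate(zip(x, y))]
        fit = fit_spectrum(pts)
        sm_fit = statsmodels.OLS(y, statsmodels.add_constant(x)).fit()
        assert fit.slope == pytest.approx(sm_fit.params[1], rel=1e-9)
        assert fit.intercept == pytest.approx(sm_fit.params[0], rel=1e-9)
        assert fit.r_squared == pytest.approx(sm_fit.rsquared, rel=1e-9)


# ---------------------------------------------------------------------------
# Fisher exact


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[3, 1], [1, 3]], Fraction(34, 70)),
            ([[5, 0], [0, 5]], Fraction(2, 252)),
        ],
    )
    def test_worked_values(self, table, expected):
        p, _ = fisher_exact_2x2(np.array(table))
        assert p == pytest.approx(float(expected), rel=1e-12)

    def test_degenerate_table_p_one(self):
        p, odds = fisher_exact_2x2(np.zeros((2, 2), dtype=int))
        assert p == 1.0 and np.isnan(odds)

    def test_odds_ratio_conventions(self):
        assert fisher_exact_2x2(np.array([[2, 1], [1, 2]]))[1] == pytest.approx(4.0)
        assert fisher_exact_2x2(np.array([[2, 0], [1, 2]]))[1] == np.inf
        assert fisher_exact_2x2(np.array([[0, 1], [1, 2]]))[1] == 0.0

    def test_matches_enumeration_oracle_on_small_margins(self):
        for a in range(5):
            for b in range(5):
                for c in range(5):
                    for d in range(5):
                        p, _ = fisher_exact_2x2(np.array([[a, b], [c, d]]))
                        if min(a + b, c + d, a + c, b + d) == 0:
                            assert p == 1.0
                        else:
                            oracle = float(fisher_two_sided_oracle(a, b, c, d))
                            assert p == pytest.approx(oracle, rel=1e-9), (a, b, c, d)

    def test_enrichment_from_fit_builds_correct_table(self):
        pts = [spoint(f"R{i}", x, y) for i, (x, y) in enumerate(
            [(0, 5), (1, 5), (2, 0), (3, 0), (4, 2.4), (5, 1)]
        )]
        fit = fit_spectrum(pts)
        ann = {f"R{i}": i < 3 for i in range(6)}
        res = enrichment_test(fit, ann)
        assert res.table.sum() == 6
        assert res.table[0].sum() == 3  # annotated row margin
        with pytest.raises(ValueError, match="missing"):
            enrichment_test(fit, {"R0": True})


# ---------------------------------------------------------------------------
# signaling and outliers


class TestSignalingPoints:
    def summaries(self, rab, m1_rab, m1_both, m2_rab, m2_both):
        return {
            ("rab_only", "1F1"): gsum(m1_rab, harmonic="1F1", rab=rab),
            ("both", "1F1"): gsum(m1_both, harmonic="1F1", rab=rab),
            ("rab_only", "2F1"): gsum(m2_rab, rab=rab),
            ("both", "2F1"): gsum(m2_both, rab=rab),
        }

    def test_identical_arms_give_origin(self):
        pts = signaling_points({"R": self.summaries("R", 2, 2, 1, 1)})
        assert (pts[0].x_photoreceptor, pts[0].y_lamina) == (0.0, 0.0)

    def test_increase_coordinates(self):
        pts = signaling_points({"R": self.summaries("R", 2, 5, 1, 9)})
        assert (pts[0].x_photoreceptor, pts[0].y_lamina) == (3.0, 8.0)

    def test_missing_arm_rejected(self):
        s = self.summaries("R", 2, 5, 1, 9)
        del s[("both", "2F1")]
        with pytest.raises(ValueError, match="missing"):
            signaling_points({"R": s})


class TestDetectOutliers:
    def line_points(self, ys):
        return [
            SignalingPoint(rab_id=f"R{i}", x_photoreceptor=float(i + 1), y_lamina=float(y))
            for i, y in enumerate(ys)
        ]

    def test_perfect_line_unflagged(self):
        rep = detect_outliers(self.line_points([1, 2, 3, 4, 5]))
        assert not rep.flagged.any()

    def test_far_point_flagged_with_ratio_five(self):
        rep = detect_outliers(self.line_points([1, 2, 3, 4, 25]))
        assert rep.flagged_rabs() == ["R4"]
        # leave-one-out line through the first four is y = x, so yhat(5) = 5
        assert rep.predicted[4] == pytest.approx(5.0, rel=1e-9)
        assert rep.ratio[4] == pytest.approx(5.0, rel=1e-9)

    def test_infinite_threshold_never_flags(self):
        rep = detect_outliers(self.line_points([1, 2, 3, 4, 25]), threshold=np.inf)
        assert not rep.flagged.any()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            detect_outliers(self.line_points([1, 2, 3]))

    def test_degenerate_loo_fit_warns_not_flags(self):
        pts = [
            SignalingPoint(rab_id="a", x_photoreceptor=0.0, y_lamina=0.0),
            SignalingPoint(rab_id="b", x_photoreceptor=1.0, y_lamina=50.0),
            SignalingPoint(rab_id="c", x_photoreceptor=1.0, y_lamina=1.0),
            SignalingPoint(rab_id="d", x_photoreceptor=1.0, y_lamina=2.0),
        ]
        rep = detect_outliers(pts)
        assert not rep.flagged[0]  # remaining points share one x: no fit
        assert any("a" in w for w in rep.warnings)

    def test_studentized_matches_statsmodels_prediction_se(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(9)
        x = np.linspace(1, 10, 8)
        y = 2 * x + rng.normal(0, 1, 8)
        pts = [
            SignalingPoint(rab_id=f"R{i}", x_photoreceptor=xi, y_lamina=yi)
            for i, (xi, yi) in enumerate(zip(x, y))
        ]
        rep = detect_outliers(pts)
        i = 3
        keep = np.arange(8) != i
        fit = statsmodels.OLS(y[keep], statsmodels.add_constant(x[keep])).fit()
        pred = fit.get_prediction(np.array([[1.0, x[i]]]))
        se_obs = np.sqrt(pred.var_pred_mean + fit.mse_resid)[0]
        expected = (y[i] - pred.predicted_mean[0]) / se_obs
        assert rep.studentized[i] == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------------------
# ANOVA / Dunnett


class TestAnovaDunnett:
    def test_identical_groups_f_zero_p_one(self):
        res = anova_dunnett({"ctrl": [1.0, 2.0, 3.0], "trt": [1.0, 2.0, 3.0]}, "ctrl")
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.comparisons["trt"][2] == 1.0

    def test_anova_matches_scipy(self):
        rng = np.random.default_rng(1)
        groups = {f"g{i}": rng.normal(i * 0.5, 1, 12) for i in range(3)}
        res = anova_dunnett(groups, "g0", n_draws=10_000)
        f, p = sps.f_oneway(*groups.values())
        assert res.f == pytest.approx(f, rel=1e-9)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_two_groups_reduce_to_t_test(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 10), rng.normal(1.0, 1, 10)
        res = anova_dunnett({"ctrl": a, "trt": b}, "ctrl", n_draws=200_000, seed=0)
        t_p = sps.ttest_ind(b, a).pvalue
        assert res.comparisons["trt"][2] == pytest.approx(t_p, abs=0.005)

    def test_matches_scipy_dunnett(self):
        rng = np.random.default_rng(4)
        ctrl = rng.normal(0, 1, 10)
        g1 = rng.normal(0.8, 1, 10)
        g2 = rng.normal(-0.3, 1, 10)
        res = anova_dunnett(
            {"ctrl": ctrl, "g1": g1, "g2": g2}, "ctrl", n_draws=400_000, seed=1
        )
        ref = sps.dunnett(g1, g2, control=ctrl)
        assert res.comparisons["g1"][2] == pytest.approx(ref.pvalue[0], abs=0.01)
        assert res.comparisons["g2"][2] == pytest.approx(ref.pvalue[1], abs=0.01)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            anova_dunnett({"a": [1.0, 1.0], "b": [2.0, 2.0]}, "a")

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_dunnett({"a": [1.0], "b": [1.0, 2.0]}, "a")
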