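"""Marker-panel statistics: detection power, exact CIs, G-tests, and the
preferential pairing estimator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from polyseg.inference import (
    LRTStatus,
    MarkerObservation,
    MarkerPanelModel,
    PairingAssumption,
    apparent_heterozygosity,
    clopper_pearson_ci,
    estimate_preferential_pairing,
    gtest_goodness_of_fit,
    heterogeneity_gtest,
    lrt_preferential_pairing,
    prob_fail_to_detect,
)
from polyseg.pairing import PairingModel, ProgenyDesign, wu_gn_frequency

BC1N_COUNTS = [  # (marker, het, loss) of 48 scored each
    ("MgSTS_98", 46, 2),
    ("MgSTS_787", 47, 1),
    ("MgSTS_724", 45, 3),
    ("MgSTS_376", 48, 0),
    ("MgSTS_358", 47, 1),
    ("MgSTS_780", 47, 1),
    ("MgSTS_847", 46, 2),
]


@pytest.fixture
def bc1n_panel():
    return [
        MarkerObservation(marker_id=m, n_scored=48, n_het=h, n_loss=l)
        for m, h, l in BC1N_COUNTS
    ]


class TestMarkerObservation:
    def test_counts_validated(self):
        with pytest.raises(ValueError):
            MarkerObservation("x", n_scored=10, n_het=9, n_loss=2)
        with pytest.raises(ValueError):
            MarkerObservation("x", n_scored=10, n_het=-1, n_loss=0)


class TestApparentHeterozygosity:
    def test_pooled_backcross_panel(self, bc1n_panel):
        assert apparent_heterozygosity(bc1n_panel) == pytest.approx(326 / 336)

    def test_pooled_with_outlier_excluded(self):
        panel = [
            MarkerObservation("a", 48, 46, 2, n_loss_excl=1),
            MarkerObservation("b", 48, 45, 3, n_loss_excl=2),
        ]
        # the outlier's calls become heterozygous
        assert apparent_heterozygosity(panel, exclude_outlier=True) == pytest.approx(
            93 / 96
        )

    def test_no_loss_gives_one(self):
        assert apparent_heterozygosity(MarkerObservation("a", 48, 48, 0)) == 1.0

    def test_zero_scored_rejected(self):
        with pytest.raises(ValueError):
            apparent_heterozygosity(MarkerObservation("a", 0, 0, 0))


class TestProbFailToDetect:
    @pytest.mark.parametrize(
        "design, n, expected, rel",
        [
            (ProgenyDesign.SELF, 309, 2.14e-8, 5e-3),
            (ProgenyDesign.SELF, 308, 2.26e-8, 5e-3),
            (ProgenyDesign.SELF, 24, 0.25, 2e-2),
            (ProgenyDesign.BACKCROSS_TO_RECESSIVE, 48, 1.58e-4, 5e-3),
            (ProgenyDesign.BACKCROSS_TO_RECESSIVE, 336, 2.48e-27, 5e-3),
        ],
    )
    def test_published_values(self, design, n, expected, rel):
        value = prob_fail_to_detect(PairingModel.RANDOM_CHROMOSOME, design, n)
        assert value == pytest.approx(expected, rel=rel)

    def test_zero_observations_gives_one(self):
        assert prob_fail_to_detect(PairingModel.RANDOM_CHROMATID, ProgenyDesign.SELF, 0) == 1.0

    def test_decreasing_in_n_and_homozygote_frequency(self):
        vals = [
            prob_fail_to_detect(PairingModel.RANDOM_CHROMOSOME, ProgenyDesign.SELF, n)
            for n in (1, 10, 100)
        ]
        assert vals[0] > vals[1] > vals[2]
        # backcross q=1/6 > self q=1/18 at equal n
        assert prob_fail_to_detect(
            PairingModel.RANDOM_CHROMOSOME, ProgenyDesign.BACKCROSS_TO_RECESSIVE, 48
        ) < prob_fail_to_detect(
            PairingModel.RANDOM_CHROMOSOME, ProgenyDesign.SELF, 48
        )


class TestClopperPearson:
    def test_all_heterozygous_marker(self):
        ci = clopper_pearson_ci(48, 48)
        assert ci.lower == pytest.approx(0.926, abs=5e-4)
        assert ci.upper == 1.0

    def test_boundary_closed_form(self):
        # at k=n the exact lower bound is (alpha/2)**(1/n)
        for n in (10, 48, 309):
            assert clopper_pearson_ci(n, n).lower == pytest.approx(
                0.025 ** (1 / n), abs=1e-12
            )

    def test_pooled_backcross_interval(self):
        ci = clopper_pearson_ci(326, 336)
        assert ci.lower == pytest.approx(0.946, abs=5e-4)
        assert ci.upper == pytest.approx(0.986, abs=5e-4)

    def test_direct_beta_quantile_oracle(self):
        # independent construction from beta quantiles
        k, n, conf = 326, 336, 0.95
        lower = stats.beta.ppf((1 - conf) / 2, k, n - k + 1)
        upper = stats.beta.ppf(1 - (1 - conf) / 2, k + 1, n - k)
        ci = clopper_pearson_ci(k, n, conf)
        assert ci.lower == pytest.approx(lower, abs=1e-12)
        assert ci.upper == pytest.approx(upper, abs=1e-12)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson_ci(0, 0)

    def test_simulated_coverage_at_least_nominal(self):
        # exact interval is conservative: empirical coverage >= 0.93 here
        rng = np.random.default_rng(2026)
        n = 48
        for p in (0.8, 0.95, 0.99):
            ks = rng.binomial(n, p, size=1000)
            lower = stats.beta.ppf(0.025, ks, n - ks + 1)
            lower = np.where(ks == 0, 0.0, lower)
            upper = stats.beta.ppf(0.975, ks + 1, np.maximum(n - ks, 1e-12))
            upper = np.where(ks == n, 1.0, upper)
            coverage = np.mean((lower <= p) & (p <= upper))
            assert coverage >= 0.93

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=1, max_value=200), st.data())
    def test_interval_brackets_point_estimate(self, n, data):
        k = data.draw(st.integers(min_value=0, max_value=n))
        ci = clopper_pearson_ci(k, n)
        assert 0.0 <= ci.lower <= k / n <= ci.upper <= 1.0


class TestGTest:
    def test_pooled_backcross_gtest(self):
        res = gtest_goodness_of_fit([326, 10], [5 / 6, 1 / 6], williams=True)
        assert res.G == pytest.approx(64.72, abs=0.01)
        assert res.q_williams == pytest.approx(1 + 3 / (6 * 336), abs=1e-12)
        assert res.df == 1
        assert res.p_value == pytest.approx(9.07e-16, rel=0.01)

    def test_uncorrected_statistic_matches_direct_formula(self):
        o = np.array([326.0, 10.0])
        e = np.array([5 / 6, 1 / 6]) * 336
        expected = 2 * np.sum(o * np.log(o / e))
        res = gtest_goodness_of_fit([326, 10], [5 / 6, 1 / 6], williams=False)
        assert res.G == pytest.approx(expected, abs=1e-9)
        assert res.G_adj == res.G

    def test_perfect_fit_gives_zero(self):
        res = gtest_goodness_of_fit([50, 10], [5 / 6, 1 / 6], williams=False)
        assert res.G == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_expected_with_nonzero_observed_is_degenerate(self):
        res = gtest_goodness_of_fit([5, 5], [1.0, 0.0])
        assert res.degenerate
        assert res.p_value == 0.0

    def test_pvalue_matches_series_chi2_tail_df1(self):
        # independent chi-square upper tail for df=1: erfc(sqrt(x/2))
        res = gtest_goodness_of_fit([326, 10], [5 / 6, 1 / 6], williams=True)
        assert res.p_value == pytest.approx(math.erfc(math.sqrt(res.G_adj / 2)), rel=1e-9)


class TestHeterogeneityG:
    def test_published_heterogeneity_over_loss_markers(self, bc1n_panel):
        loss_markers = [o for o in bc1n_panel if o.n_loss > 0]
        res = heterogeneity_gtest(loss_markers)
        assert res.G == pytest.approx(1.99, abs=0.01)
        assert res.df == 5
        assert res.p_value == pytest.approx(0.85, abs=0.005)

    def test_identical_proportions_give_zero(self):
        panel = [MarkerObservation(f"m{i}", 48, 44, 4) for i in range(4)]
        assert heterogeneity_gtest(panel).G == pytest.approx(0.0, abs=1e-12)

    def test_additive_decomposition_oracle(self):
        # G_H == sum of per-marker G minus pooled G, against any common ratio
        panel = [
            MarkerObservation("a", 50, 44, 6),
            MarkerObservation("b", 60, 57, 3),
        ]

        def g(o_het, o_loss):
            n = o_het + o_loss
            e = np.array([5 / 6, 1 / 6]) * n
            o = np.array([o_het, o_loss], dtype=float)
            return 2 * np.sum(o * np.log(o / e))

        expected = sum(g(o.n_het, o.n_loss) for o in panel) - g(101, 9)
        assert heterogeneity_gtest(panel).G == pytest.approx(expected, abs=1e-9)

    def test_single_marker_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity_gtest([MarkerObservation("a", 48, 46, 2)])


class TestPreferentialPairingEstimate:
    @pytest.mark.parametrize(
        "loss, expected", [(2, 0.54), (3, 0.46), (1, 0.60), (0, 0.67)]
    )
    def test_published_point_estimates(self, loss, expected):
        obs = MarkerObservation("m", 48, 48 - loss, loss)
        est = estimate_preferential_pairing(obs)
        assert round(est.p_hat, 2) == expected

    def test_upper_bound_iff_no_loss(self):
        est0 = estimate_preferential_pairing(MarkerObservation("m", 48, 48, 0))
        assert est0.p_hat == pytest.approx(2 / 3, abs=1e-12)
        est1 = estimate_preferential_pairing(MarkerObservation("m", 48, 47, 1))
        assert est1.p_hat < 2 / 3

    def test_strictly_decreasing_in_loss(self):
        # up to 8 losses of 48 the inferred f_GN stays >= 2/3 and the root is
        # interior; beyond that the estimate clamps at 0
        phats = [
            estimate_preferential_pairing(MarkerObservation("m", 48, 48 - l, l)).p_hat
            for l in range(0, 9)
        ]
        assert all(a > b for a, b in zip(phats, phats[1:]))

    def test_forward_backward_consistency(self):
        for loss in range(0, 9):
            est = estimate_preferential_pairing(MarkerObservation("m", 48, 48 - loss, loss))
            assert wu_gn_frequency(est.p_hat, 0.0) == pytest.approx(
                est.f_gn_obs, abs=1e-9
            )

    def test_quadrivalent_assumption_has_small_effect(self):
        obs = MarkerObservation("m", 48, 46, 2)
        biv = estimate_preferential_pairing(obs, PairingAssumption.BIVALENT_ONLY)
        quad = estimate_preferential_pairing(obs, PairingAssumption.QUADRIVALENT_DR)
        # quadrivalent accounting absorbs part of the loss, so p_hat is larger,
        # but only slightly
        assert quad.p_hat > biv.p_hat
        assert quad.p_hat - biv.p_hat < 0.06

    def test_excess_loss_rejected(self):
        with pytest.raises(ValueError, match="no root"):
            estimate_preferential_pairing(MarkerObservation("m", 48, 0, 25))

    def test_inferred_gamete_counts(self):
        est = estimate_preferential_pairing(MarkerObservation("m", 48, 46, 2))
        assert (est.n_gn, est.n_gg, est.n_nn) == (44, 2, 2)


class TestLRT:
    def test_no_loss_against_null_is_exactly_null(self):
        obs = MarkerObservation("m", 48, 48, 0)
        est = estimate_preferential_pairing(obs)
        stat, p, status = lrt_preferential_pairing(obs, est, null_p=2 / 3)
        assert status is LRTStatus.OK
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_loss_against_strict_null_is_degenerate(self):
        obs = MarkerObservation("m", 48, 47, 1)
        est = estimate_preferential_pairing(obs)
        stat, p, status = lrt_preferential_pairing(obs, est, null_p=2 / 3)
        assert status is LRTStatus.DEGENERATE
        assert stat is None and p is None

    def test_interior_null_gives_finite_positive_statistic(self):
        obs = MarkerObservation("m", 48, 46, 2)
        est = estimate_preferential_pairing(obs)
        stat, p, status = lrt_preferential_pairing(obs, est, null_p=0.60)
        assert status is LRTStatus.OK
        assert stat > 0
        # direct likelihood evaluation at both parameter values
        def ll(pp):
            f = wu_gn_frequency(pp)
            off = (1 - f) / 2
            return 44 * np.log(f) + 2 * np.log(off) + 2 * np.log(off)

        assert stat == pytest.approx(2 * (ll(est.p_hat) - ll(0.60)), abs=1e-9)
        assert 0 < p < 1


class TestPanelModel:
    def test_parameter_recovery_at_realistic_truth(self):
        # simulated backcross panels at p = 0.50: mean estimate within 0.02
        from polyseg.simulate import WuModelParams, simulate_marker_panel

        panel = simulate_marker_panel(WuModelParams(p=0.50), 5000, 200, seed=7)
        phats = [estimate_preferential_pairing(o).p_hat for o in panel]
        assert np.mean(phats) == pytest.approx(0.50, abs=0.02)

    def test_bundled_panel_reproduces_published_table(self):
        res = MarkerPanelModel.bundled("BC1N").fit()
        assert res.pooled_ci.lower == pytest.approx(0.946, abs=5e-4)
        assert res.pooled_gtest.p_value == pytest.approx(9.07e-16, rel=0.01)
        assert res.heterogeneity.G == pytest.approx(1.99, abs=0.01)
        table = res.per_marker.set_index("marker_id")
        assert round(table.loc["MgSTS_98", "p_hat"], 2) == 0.54
        assert round(table.loc["MgSTS_724", "p_hat"], 2) == 0.46
        assert round(table.loc["MgSTS_376", "p_hat"], 2) == 0.67

    def test_exclude_outlier_recomputes_counts(self):
        res = MarkerPanelModel.bundled("BC1N").fit(exclude_outlier=True)
        assert res.pooled_loss == 4
        assert res.pooled_apparent_het == pytest.approx(332 / 336)

    def test_summary_contains_pooled_statistics(self):
        text = MarkerPanelModel.bundled("BC1N").fit().summary()
        assert "9.07E-16" in text
        assert "G_H = 1.9925" in text
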