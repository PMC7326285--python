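import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from introsweep import (
    FLANK_DECAY_CONSTANT,
    SelectionContext,
    SweepParameters,
    alpha_from_selection,
    classic_recovery_distance,
    conditional_background,
    conditional_sweep,
    escape_count_pmf,
    escape_probability,
    expected_heterozygosity,
    neutral_spectrum,
    selection_bound_from_halfwidth,
    sweep_case_probabilities,
    transformed_spectrum,
    volcano_geometry,
)

THETA = 0.002


class TestEscape:
    def test_zero_distance(self):
        assert escape_probability(1e-4, 0.0) == 0.0

    def test_half_at_log2(self):
        assert escape_probability(1.0, np.log(2)) == pytest.approx(0.5, rel=1e-14)

    def test_saturates(self):
        assert escape_probability(1.0, 50.0) == pytest.approx(1.0, abs=1e-15)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            escape_probability(1e-4, -1.0)

    def test_alpha_from_selection_values(self):
        ctx = SelectionContext(r=1e-7, s=0.06, N=5000)
        assert alpha_from_selection(ctx) == pytest.approx(1.5351e-5, rel=1e-4)
        ctx2 = SelectionContext(r=1e-8, s=1e-2, N=1e4)
        assert alpha_from_selection(ctx2) == pytest.approx(9.9035e-6, rel=1e-4)

    def test_alpha_inverse_in_s(self):
        a1 = alpha_from_selection(SelectionContext(r=1e-8, s=0.01, N=1e4))
        a2 = alpha_from_selection(SelectionContext(r=1e-8, s=0.02, N=1e4))
        assert a1 == pytest.approx(2.0 * a2, rel=1e-14)


class TestEscapeCounts:
    def test_point_mass_at_zero(self):
        pmf = escape_count_pmf(5, 1e-4, 0.0)
        np.testing.assert_allclose(pmf, [1, 0, 0, 0, 0, 0], atol=1e-15)

    def test_point_mass_at_n(self):
        pmf = escape_count_pmf(4, 1.0, 200.0)
        np.testing.assert_allclose(pmf, [0, 0, 0, 0, 1], atol=1e-15)

    def test_pairwise_at_log2(self):
        np.testing.assert_allclose(
            escape_count_pmf(2, 1.0, np.log(2)), [0.25, 0.5, 0.25], rtol=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(n=st.integers(2, 60), s=st.floats(0.0, 30.0))
    def test_sums_to_one(self, n, s):
        assert escape_count_pmf(n, 1.0, s).sum() == pytest.approx(1.0, abs=1e-10)

    def test_stochastic_ordering_in_distance(self):
        n = 8
        near, far = escape_count_pmf(n, 1e-4, 2_000), escape_count_pmf(n, 1e-4, 8_000)
        # larger d shifts mass toward more escapes: far CDF dominated by near CDF
        assert np.all(np.cumsum(far) <= np.cumsum(near) + 1e-12)

    def test_case_probabilities_equal_pairwise_pmf(self):
        for s in [0.01, 0.3, 1.0, 4.0]:
            pmf = escape_count_pmf(2, 1.0, s)
            cases = sweep_case_probabilities(1.0, s)
            assert cases.P_B == pytest.approx(pmf[0], rel=1e-12)
            assert cases.P_Bb == pytest.approx(pmf[1], rel=1e-12)
            assert cases.P_bb == pytest.approx(pmf[2], rel=1e-12)
            assert cases.P_b == 0.0
            assert cases.as_array().sum() == pytest.approx(1.0, abs=1e-12)

    def test_case_probabilities_limits(self):
        c0 = sweep_case_probabilities(1e-4, 0.0)
        assert (c0.P_B, c0.P_Bb, c0.P_bb) == (1.0, 0.0, 0.0)
        chalf = sweep_case_probabilities(1.0, np.log(2))
        assert chalf.P_B == pytest.approx(0.25, rel=1e-12)
        assert chalf.P_Bb == pytest.approx(0.5, rel=1e-12)


class TestHeterozygosity:
    def test_zero_at_center(self):
        for mode in ("classic", "introgression"):
            assert expected_heterozygosity(1.0, 0.0, THETA, 13 * THETA, mode) == 0.0

    def test_background_recovery(self):
        for mode in ("classic", "introgression"):
            h = expected_heterozygosity(1.0, 60.0, THETA, 13 * THETA, mode)
            assert h == pytest.approx(THETA, rel=1e-12)

    def test_shoulder_example(self):
        h = expected_heterozygosity(1.0, np.log(2), THETA, 13 * THETA, "introgression")
        assert h == pytest.approx(6.75 * THETA, rel=1e-12)

    def test_classic_limit_is_D_equals_theta(self):
        for s in np.linspace(0.01, 8, 40):
            hc = expected_heterozygosity(1.0, s, THETA, mode="classic")
            hi = expected_heterozygosity(1.0, s, THETA, THETA, "introgression")
            assert hi == pytest.approx(hc, rel=1e-12)


class TestVolcanoGeometry:
    def test_reference_shape(self):
        g = volcano_geometry(THETA, 13 * THETA)
        assert g.relative_height == pytest.approx(5.76, rel=1e-12)  # 4*36/25
        assert g.peak_height == pytest.approx(6.76 * THETA, rel=1e-12)
        assert 0 < g.valley_halfwidth_scaled < g.peak_position_scaled < g.flank_halfwidth_scaled

    def test_large_divergence_limits(self):
        g = volcano_geometry(THETA, 1e6 * THETA)
        assert g.peak_position_scaled == pytest.approx(np.log(2), rel=1e-5)
        assert g.valley_halfwidth_scaled == pytest.approx(0.0, abs=1e-5)
        assert g.flank_halfwidth_scaled == pytest.approx(
            np.log(20 / (10 - 3 * np.sqrt(10))), rel=1e-5
        )
        assert round(g.flank_halfwidth_scaled, 1) == 3.7

    def test_undefined_without_excess_divergence(self):
        with pytest.raises(ValueError):
            volcano_geometry(THETA, THETA)

    @pytest.mark.parametrize("ratio", [1.3, 2, 5, 13, 100])
    def test_peak_matches_numeric_argmax(self, ratio):
        D = ratio * THETA
        g = volcano_geometry(THETA, D)
        res = minimize_scalar(
            lambda s: -expected_heterozygosity(1.0, s, THETA, D, "introgression"),
            bounds=(1e-8, 30.0), method="bounded", options={"xatol": 1e-12},
        )
        assert res.x == pytest.approx(g.peak_position_scaled, rel=1e-6)
        assert -res.fun == pytest.approx(g.peak_height, rel=1e-10)

    @pytest.mark.parametrize("ratio", [1.2, 3, 13, 1e4])
    def test_flank_decay_identity(self, ratio):
        # H at the flank half-width equals theta + (H* - theta)/10 exactly
        D = ratio * THETA
        g = volcano_geometry(THETA, D)
        h = expected_heterozygosity(1.0, g.flank_halfwidth_scaled, THETA, D, "introgression")
        assert h == pytest.approx(THETA + (g.peak_height - THETA) / 10, rel=1e-12)

    def test_valley_edge_restores_background(self):
        g = volcano_geometry(THETA, 7 * THETA)
        h = expected_heterozygosity(1.0, g.valley_halfwidth_scaled, THETA, 7 * THETA, "introgression")
        assert h == pytest.approx(THETA, rel=1e-12)

    def test_bp_widths_require_alpha(self):
        g = volcano_geometry(THETA, 5 * THETA)
        with pytest.raises(ValueError):
            _ = g.flank_halfwidth_bp
        g2 = volcano_geometry(THETA, 5 * THETA, alpha=1e-4)
        assert g2.flank_halfwidth_bp == pytest.approx(g2.flank_halfwidth_scaled / 1e-4)


class TestClassicRecovery:
    def test_ninety_percent(self):
        assert classic_recovery_distance(0.9) == pytest.approx(0.5 * np.log(10), rel=1e-12)
        assert classic_recovery_distance(0.9) == pytest.approx(1.1513, rel=1e-4)

    def test_peak_distance_is_75_percent_recovery(self):
        # the volcano peak sits where the classic signal has decayed by 75%
        assert classic_recovery_distance(0.75) == pytest.approx(np.log(2), rel=1e-12)

    def test_limits_and_errors(self):
        assert classic_recovery_distance(1e-12) == pytest.approx(0.0, abs=1e-10)
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                classic_recovery_distance(bad)

    def test_selection_bound(self):
        # 5 kb half-width floor with r = 1e-8, N_e = 1e4 implies 2 N s >= 2.7
        bound = selection_bound_from_halfwidth(5_000, r=1e-8, N=1e4)
        assert round(bound, 1) == 2.7


class TestTransformedSpectrum:
    def setup_method(self):
        self.bg = neutral_spectrum(6, THETA, 0.0125)
        self.Do = 0.0125

    def test_center_concentrates_on_fixed_class(self):
        t = transformed_spectrum(self.bg, SweepParameters(1e-4, 5 * THETA), 0.0)
        np.testing.assert_allclose(t.weights[1:6], 0.0, atol=1e-15)
        assert t.weights[6] == pytest.approx(self.Do, rel=1e-12)

    def test_far_field_restores_polymorphic_background(self):
        t = transformed_spectrum(self.bg, SweepParameters(1.0, 5 * THETA), 60.0)
        np.testing.assert_allclose(t.weights[1:6], self.bg.weights[1:6], rtol=1e-12)
        # class n tends to D_o, not S_n: the model neglects within-recipient
        # coalescent time on the fixed-difference branch
        assert t.weights[6] == pytest.approx(self.Do, rel=1e-12)

    def test_pairwise_identity_with_heterozygosity(self):
        # the n = 2 transformed polymorphic class IS the closed-form volcano
        bg2 = neutral_spectrum(2, THETA, 0.014)
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            alpha = 10 ** rng.uniform(-6, -3)
            d = 10 ** rng.uniform(0, 5)
            D = THETA * rng.uniform(1.0, 13.0)
            t = transformed_spectrum(bg2, SweepParameters(alpha, D), d)
            h = expected_heterozygosity(alpha, d, THETA, D, "introgression")
            assert abs(t.weights[1] - h) <= 1e-12 * h

    def test_divergence_bound_enforced(self):
        with pytest.raises(ValueError):
            transformed_spectrum(self.bg, SweepParameters(1e-4, 3 * self.Do), 100.0)
        unpol = neutral_spectrum(6, THETA, 0.0125, fixed_diffs_polarized=False)
        with pytest.raises(ValueError):
            transformed_spectrum(unpol, SweepParameters(1e-4, 1.5 * self.Do), 100.0)


class TestConditionalSweep:
    def setup_method(self):
        self.bg = neutral_spectrum(5, THETA, 0.0125)

    def test_far_field_equals_background_polymorphic(self):
        t = transformed_spectrum(self.bg, SweepParameters(1.0, 5 * THETA), 55.0)
        got = conditional_sweep(t, include_fixed=False).probabilities
        want = conditional_background(self.bg, include_fixed=False).probabilities
        np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_center_is_pure_fixed_difference(self):
        t = transformed_spectrum(self.bg, SweepParameters(1e-4, 5 * THETA), 0.0)
        got = conditional_sweep(t, include_fixed=True).probabilities
        np.testing.assert_allclose(got, [0, 0, 0, 0, 1.0], atol=1e-15)

    def test_center_polymorphic_only_is_undefined(self):
        t = transformed_spectrum(self.bg, SweepParameters(1e-4, 5 * THETA), 0.0)
        with pytest.raises(ValueError):
            conditional_sweep(t, include_fixed=False)

    def test_mutation_rate_cancels(self):
        # scaling background weights together with D and D_o leaves q' unchanged
        params = SweepParameters(2e-4, 5 * THETA)
        t1 = transformed_spectrum(self.bg, params, 3_000.0)
        scaled_bg = self.bg.scaled(7.0)
        t2 = transformed_spectrum(
            scaled_bg, SweepParameters(2e-4, 7.0 * 5 * THETA), 3_000.0
        )
        q1 = conditional_sweep(t1, True).probabilities
        q2 = conditional_sweep(t2, True).probabilities
        np.testing.assert_allclose(q1, q2, rtol=1e-12)
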