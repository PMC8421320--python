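"""Unit and property tests for the tracer-kinetic core."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from dualflow import (
    AifModelParams,
    GdKineticParams,
    SampledCurve,
    WaterKineticParams,
    expconv,
    gamma_variate_aif,
    gd_1tcm_forward,
    renkin_crone_extraction,
    renkin_crone_invert,
    renkin_crone_k1,
    water_1tcm_forward,
)
from dualflow.kinetics import (
    KineticsError,
    NoSolutionError,
    extraction_correction_amplification,
)


class TestRenkinCrone:
    def test_reference_value(self):
        # F = 1 with the calibrated Gd-DOTA PS: K1 = 1 - exp(-2.6)
        assert renkin_crone_k1(1.0, 2.6) == pytest.approx(1 - np.exp(-2.6),
                                                          abs=1e-12)
        assert renkin_crone_k1(1.0, 2.6) == pytest.approx(0.92573, abs=1e-5)

    def test_zero_extraction_and_zero_flow(self):
        assert renkin_crone_k1(5.0, 0.0) == 0.0
        assert renkin_crone_k1(0.0, 2.6) == 0.0

    def test_high_flow_limit_is_ps(self):
        assert renkin_crone_k1(1e6, 2.6) == pytest.approx(2.6, abs=1e-4)

    def test_negative_inputs_rejected(self):
        with pytest.raises(KineticsError):
            renkin_crone_k1(-1.0, 2.6)
        with pytest.raises(KineticsError):
            renkin_crone_k1(1.0, -0.1)

    @settings(derandomize=True, max_examples=200)
    @given(F=st.floats(0.05, 10.0), PS=st.floats(0.1, 8.0))
    def test_k1_below_min_f_ps_and_monotone(self, F, PS):
        # beyond PS/F ~ 30 extraction saturates to 1 in double precision
        assume(PS / F < 30)
        k1 = renkin_crone_k1(F, PS)
        assert 0 < k1 < min(F, PS)
        # strictly increasing in both arguments
        assert renkin_crone_k1(F * 1.01, PS) > k1
        assert renkin_crone_k1(F, PS * 1.01) > k1
        # extraction in (0,1) and decreasing with flow
        e = renkin_crone_extraction(F, PS)
        assert 0 < e < 1
        assert renkin_crone_extraction(F * 1.1, PS) < e

    @settings(derandomize=True, max_examples=100)
    @given(F=st.floats(0.05, 8.0), PS=st.floats(0.2, 6.0))
    def test_invert_round_trip(self, F, PS):
        k1 = renkin_crone_k1(F, PS)
        F_back = renkin_crone_invert(k1, PS)
        assert abs(renkin_crone_k1(F_back, PS) - k1) < 1e-10
        assert F_back == pytest.approx(F, rel=1e-8)

    def test_invert_examples_and_errors(self):
        assert renkin_crone_invert(0.92573, 2.6) == pytest.approx(1.0, abs=1e-5)
        assert renkin_crone_invert(0.0, 2.6) == 0.0
        with pytest.raises(NoSolutionError):
            renkin_crone_invert(2.6, 2.6)
        with pytest.raises(KineticsError):
            renkin_crone_invert(-0.1, 2.6)

    def test_amplification_grows_near_asymptote(self):
        # dF/dK1 modest at low flow, explosive as K1 -> PS
        low = extraction_correction_amplification(0.1, 2.6)
        assert low == pytest.approx(1.0, abs=0.01)
        F_high = renkin_crone_invert(2.59, 2.6)
        assert extraction_correction_amplification(F_high, 2.6) > 50


class TestExpconv:
    def test_step_input_closed_form(self):
        t = np.linspace(0.0, 50.0, 101)
        c = 3.0
        k = 0.07
        out = expconv(SampledCurve(t, np.full_like(t, c)), k)
        expected = c * (1 - np.exp(-k * t)) / k
        np.testing.assert_allclose(out.values, expected, atol=1e-10)

    def test_zero_input_and_zero_rate(self):
        t = np.linspace(0.0, 10.0, 21)
        zero = expconv(SampledCurve(t, np.zeros_like(t)), 0.3)
        assert np.all(zero.values == 0)
        # rate 0: running time-integral (here of a ramp)
        ramp = expconv(SampledCurve(t, t), 0.0)
        np.testing.assert_allclose(ramp.values, t ** 2 / 2, atol=1e-9)

    def test_against_dense_grid_convolution_oracle(self):
        params = AifModelParams(t0=5.0, alpha=3.0, beta=4.0, amplitude=10.0)
        t = np.arange(0.0, 120.0, 1.0)  # 1 Hz sampling
        curve = gamma_variate_aif(params, t)
        k = 0.04
        # oracle: trapezoidal convolution on a 0.01 s grid
        tf = np.arange(0.0, 120.0, 0.01)
        fine = np.interp(tf, t, curve.values)
        kernel = np.exp(-k * tf)
        conv = np.convolve(fine, kernel)[: tf.size] * 0.01
        conv -= 0.5 * 0.01 * (fine * kernel[0] + fine[0] * kernel)  # trapezoid ends
        oracle = np.interp(t, tf, conv)
        out = expconv(curve, k)
        scale = np.max(np.abs(oracle))
        np.testing.assert_allclose(out.values / scale, oracle / scale,
                                   atol=1e-5)

    def test_negative_rate_rejected(self):
        t = np.linspace(0, 5, 11)
        with pytest.raises(KineticsError):
            expconv(SampledCurve(t, t), -0.1)


class TestGammaVariateAif:
    params = AifModelParams(t0=10.0, alpha=4.0, beta=3.0, amplitude=100.0)

    def test_zero_before_arrival(self):
        curve = gamma_variate_aif(self.params, np.array([0.0, 5.0, 10.0]))
        assert np.all(curve.values == 0)

    def test_peak_location_and_value(self):
        t = np.linspace(0, 80, 80001)
        curve = gamma_variate_aif(self.params, t)
        i = curve.values.argmax()
        assert t[i] == pytest.approx(10 + 4 * 3, abs=0.01)
        assert curve.values[i] == pytest.approx(100.0, rel=1e-6)

    def test_amplitude_linearity_and_nonnegativity(self):
        t = np.linspace(0, 60, 301)
        one = gamma_variate_aif(self.params, t)
        p2 = AifModelParams(t0=10.0, alpha=4.0, beta=3.0, amplitude=200.0,
                            recirc_fraction=0.2)
        one_rc = gamma_variate_aif(
            AifModelParams(t0=10.0, alpha=4.0, beta=3.0, amplitude=100.0,
                           recirc_fraction=0.2), t)
        two = gamma_variate_aif(p2, t)
        np.testing.assert_allclose(two.values, 2 * one_rc.values, rtol=1e-12)
        assert np.all(one.values >= 0)

    def test_recirculation_adds_late_tail(self):
        t = np.linspace(0, 120, 601)
        base = gamma_variate_aif(self.params, t)
        rc = gamma_variate_aif(
            AifModelParams(t0=10.0, alpha=4.0, beta=3.0, amplitude=100.0,
                           recirc_fraction=0.3, recirc_tau=30.0), t)
        assert rc.values[-1] > base.values[-1]

    def test_non_increasing_times_rejected(self):
        with pytest.raises(KineticsError):
            gamma_variate_aif(self.params, np.array([0.0, 2.0, 1.0]))


@pytest.fixture(scope="module")
def fine_aif():
    t = np.linspace(0.0, 300.0, 601)
    return gamma_variate_aif(
        AifModelParams(t0=10.0, alpha=4.0, beta=3.0, amplitude=100.0,
                       recirc_fraction=0.15, recirc_tau=40.0), t)


class TestWaterForward:
    def test_zero_flow_reduces_to_spillover(self, fine_aif):
        params = WaterKineticParams(F=0.0, PTF=0.7, Va=0.1)
        out = water_1tcm_forward(params, fine_aif)
        np.testing.assert_allclose(out.values, 0.1 * fine_aif.values,
                                   atol=1e-14)

    def test_constant_input_closed_form(self):
        t = np.linspace(0.0, 600.0, 1201)
        c = 50.0
        aif = SampledCurve(t, np.full_like(t, c), "kBq/mL")
        params = WaterKineticParams(F=1.2, PTF=0.65, Va=0.0, p=0.91)
        out = water_1tcm_forward(params, aif)
        k2 = 1.2 / 0.91 / 60.0
        expected = 0.65 * 0.91 * c * (1 - np.exp(-k2 * t))
        np.testing.assert_allclose(out.values, expected, rtol=1e-9, atol=1e-9)

    def test_linearity_in_ptf(self, fine_aif):
        lo = water_1tcm_forward(WaterKineticParams(F=1.0, PTF=0.35, Va=0.0),
                                fine_aif)
        hi = water_1tcm_forward(WaterKineticParams(F=1.0, PTF=0.7, Va=0.0),
                                fine_aif)
        np.testing.assert_allclose(hi.values, 2 * lo.values, rtol=1e-12)

    def test_unit_discipline_minutes_vs_seconds(self, fine_aif):
        """Re-expressing the time axis in minutes with rates in 1/min leaves
        the prediction unchanged."""
        params = WaterKineticParams(F=1.5, PTF=0.7, Va=0.2)
        out_s = water_1tcm_forward(params, fine_aif)
        t_min = fine_aif.times / 60.0
        aif_min = SampledCurve(t_min, fine_aif.values, "kBq/mL")
        # manual model in minute units: k1 = F, k2 = F/p per minute
        k1, k2 = 1.5, 1.5 / 0.91
        tissue = k1 * expconv(aif_min, k2).values
        manual = 0.7 * tissue + 0.2 * aif_min.values
        np.testing.assert_allclose(out_s.values, manual, rtol=1e-12,
                                   atol=1e-12)


class TestGdForward:
    def test_zero_k1_reduces_to_blood_pool(self, fine_aif):
        out = gd_1tcm_forward(GdKineticParams(K1=0.0, vb=0.05), fine_aif,
                              mode="plain")
        np.testing.assert_allclose(out.values, 0.05 * fine_aif.values,
                                   atol=1e-14)

    def test_constant_input_closed_form_plain(self):
        t = np.linspace(0.0, 300.0, 601)
        c = 4.0
        aif = SampledCurve(t, np.full_like(t, c), "mmol/L")
        out = gd_1tcm_forward(GdKineticParams(K1=0.9, Ve=0.35, vb=0.0), aif,
                              mode="plain")
        k2 = 0.9 / 0.35 / 60.0
        expected = 0.35 * c * (1 - np.exp(-k2 * t))
        np.testing.assert_allclose(out.values, expected, rtol=1e-9, atol=1e-9)

    def test_ps_embedded_high_flow_limit_is_plain_with_k1_ps(self, fine_aif):
        ps = 2.6
        hi = gd_1tcm_forward(GdKineticParams(F=1e6, PS=ps), fine_aif,
                             mode="ps_embedded")
        plain = gd_1tcm_forward(GdKineticParams(K1=ps, Ve=0.35, vb=0.08),
                                fine_aif, mode="plain")
        np.testing.assert_allclose(hi.values, plain.values, rtol=1e-4,
                                   atol=1e-4)

    def test_ps_embedded_encodes_flow_beyond_k1(self, fine_aif):
        """Two (F, PS) pairs with identical K1 give different curves: the
        capillary-transit delivery phase separates flow from PS."""
        k1 = renkin_crone_k1(1.0, 2.6)
        ps_for_f2 = -2.0 * np.log1p(-k1 / 2.0)  # PS giving same K1 at F = 2
        a = gd_1tcm_forward(GdKineticParams(F=1.0, PS=2.6), fine_aif,
                            mode="ps_embedded")
        b = gd_1tcm_forward(GdKineticParams(F=2.0, PS=ps_for_f2), fine_aif,
                            mode="ps_embedded")
        assert np.max(np.abs(a.values - b.values)) > 1e-3 * a.values.max()

    def test_missing_parameters_raise(self, fine_aif):
        with pytest.raises(KineticsError):
            gd_1tcm_forward(GdKineticParams(K1=1.0), fine_aif,
                            mode="ps_embedded")
        with pytest.raises(KineticsError):
            GdKineticParams(Ve=0.35, vb=0.05)  # neither K1 nor (F, PS)

    def test_inconsistent_k1_rejected(self):
        with pytest.raises(KineticsError):
            GdKineticParams(F=1.0, PS=2.6, K1=0.5)
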