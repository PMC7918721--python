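"""Forward lineshape model: closed-form limits, normalization contracts
and superposition linearity."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from eprnano import (
    DomainParams,
    MagneticTensors,
    SpectrometerSettings,
    ValidationError,
    cone_angle_from_order,
    line_width,
    partial_average,
    resonance_field,
    simulate_component,
    simulate_spectrum,
)
from eprnano.spin_model import EffectiveTensors


class TestPartialAverage:
    def test_rigid_limit_recovers_principal_values(self, tensors):
        eff = partial_average(tensors, S=1.0)
        assert eff.A_par == pytest.approx(3.36, abs=1e-12)
        assert eff.A_perp == pytest.approx(0.605, abs=1e-12)
        assert eff.g_par == pytest.approx(2.0027, abs=1e-12)

    def test_isotropic_limit_is_a_iso(self, tensors):
        eff = partial_average(tensors, S=0.0)
        a_iso = (0.63 + 0.58 + 3.36) / 3.0
        assert eff.A_par == pytest.approx(a_iso, abs=1e-12)
        assert eff.A_perp == pytest.approx(a_iso, abs=1e-12)

    def test_polarity_factor_scales_isotropic_average(self, tensors):
        eff = partial_average(tensors, S=0.0, pA=1.05)
        assert eff.A_par == pytest.approx(1.5995, abs=1e-4)
        assert eff.A_perp == pytest.approx(1.5995, abs=1e-4)

    @given(s=st.floats(0.0, 1.0), pa=st.floats(0.9, 1.1))
    @hyp_settings(max_examples=50, deadline=None, derandomize=True)
    def test_trace_conservation(self, s, pa):
        t = MagneticTensors()
        eff = partial_average(t, S=s, pA=pa, pg=1.0005)
        assert (eff.A_par + 2 * eff.A_perp) / 3 == pytest.approx(
            pa * t.a_iso, abs=1e-12)
        assert (eff.g_par + 2 * eff.g_perp) / 3 == pytest.approx(
            1.0005 * t.g_iso, abs=1e-12)

    def test_monotone_in_order_parameter(self, tensors):
        grid = np.linspace(0, 1, 21)
        a_par = [partial_average(tensors, s).A_par for s in grid]
        a_perp = [partial_average(tensors, s).A_perp for s in grid]
        assert np.all(np.diff(a_par) >= 0)
        assert np.all(np.diff(a_perp) <= 0)

    def test_out_of_range_rejected(self, tensors):
        with pytest.raises(ValidationError):
            partial_average(tensors, S=1.2)
        with pytest.raises(ValidationError):
            partial_average(tensors, S=0.5, pA=-1.0)

    def test_tensor_geometry_validated(self):
        with pytest.raises(ValidationError):
            MagneticTensors(A_zz=0.5)  # not the largest value
        with pytest.raises(ValidationError):
            MagneticTensors(g_xx=1.9)


class TestConeAngle:
    @pytest.mark.parametrize("s,theta_deg", [
        (1.0, 0.0), (0.0, 90.0), (0.37, 60.33)])
    def test_known_angles(self, s, theta_deg):
        assert cone_angle_from_order(s) == pytest.approx(theta_deg, abs=0.01)

    def test_monotone_decreasing(self):
        grid = np.linspace(0, 1, 50)
        angles = [cone_angle_from_order(s) for s in grid]
        assert np.all(np.diff(angles) < 0)

    def test_roundtrip_defining_equation(self):
        for s in (0.1, 0.37, 0.8):
            c = np.cos(cone_angle_from_order(s, degrees=False))
            assert 0.5 * c * (1 + c) == pytest.approx(s, abs=1e-12)


class TestResonanceField:
    def test_central_field_at_x_band(self):
        eff = EffectiveTensors(1.0, 1.0, 2.0060, 2.0060)
        assert resonance_field(eff, 0.0, 0, 9.59) == pytest.approx(
            341.567, abs=2e-3)

    def test_outer_lines_symmetric(self, tensors):
        eff = partial_average(tensors, S=0.5)
        for theta in (0.0, 0.7, np.pi / 2):
            hi = resonance_field(eff, theta, -1)
            lo = resonance_field(eff, theta, +1)
            mid = resonance_field(eff, theta, 0)
            a_eff = np.sqrt(eff.A_par**2 * np.cos(theta)**2 +
                            eff.A_perp**2 * np.sin(theta)**2)
            assert hi - lo == pytest.approx(2 * a_eff, abs=1e-10)
            assert (hi + lo) / 2 == pytest.approx(mid, abs=1e-10)

    def test_rigid_parallel_offset_is_a_zz(self, tensors):
        eff = partial_average(tensors, S=1.0)
        offset = resonance_field(eff, 0.0, 0) - resonance_field(eff, 0.0, 1)
        assert offset == pytest.approx(3.36, abs=1e-10)


class TestLineWidth:
    def test_no_motional_term_when_fully_ordered(self, tensors):
        d = DomainParams(S=1.0, tau_c=3.0, W=0.07)
        for theta in (0.0, 0.5, 1.2):
            for mi in (-1, 0, 1):
                assert line_width(d, tensors, theta, mi) == 0.07

    def test_linear_in_tau_c(self, tensors):
        d1 = DomainParams(S=0.37, tau_c=1.0, W=0.1)
        d2 = DomainParams(S=0.37, tau_c=2.0, W=0.1)
        w1 = line_width(d1, tensors, np.pi / 4, -1)
        w2 = line_width(d2, tensors, np.pi / 4, -1)
        assert w2 - 0.1 == pytest.approx(2 * (w1 - 0.1), rel=1e-12)

    def test_central_line_narrower_than_outer(self, tensors):
        d = DomainParams(S=0.37, tau_c=1.0, W=0.1)
        w0 = line_width(d, tensors, np.pi / 4, 0)
        assert w0 < line_width(d, tensors, np.pi / 4, -1)
        assert w0 < line_width(d, tensors, np.pi / 4, +1)


class TestSimulateComponent:
    def test_absorption_normalized_to_unit_area(self, tensors, settings,
                                                random_domains):
        for dom in random_domains(3):
            spec = simulate_component(dom, tensors, settings, derivative=False)
            assert np.trapezoid(spec.intensity, spec.field) == pytest.approx(
                1.0, abs=1e-6)

    def test_derivative_integrates_to_zero(self, tensors, settings,
                                           random_domains):
        for dom in random_domains(3):
            spec = simulate_component(dom, tensors, settings)
            assert abs(np.trapezoid(spec.intensity, spec.field)) < 1e-6

    def test_double_integral_of_derivative_is_unity(self, tensors, settings):
        from scipy.integrate import cumulative_trapezoid
        dom = DomainParams(S=0.37, tau_c=0.9, W=0.1)
        spec = simulate_component(dom, tensors, settings)
        absorption = cumulative_trapezoid(spec.intensity, spec.field,
                                          initial=0.0)
        assert np.trapezoid(absorption, spec.field) == pytest.approx(
            1.0, abs=1e-5)

    def test_isotropic_fast_limit_is_triplet(self, tensors, settings):
        dom = DomainParams(S=0.0, tau_c=0.01, W=0.08)
        spec = simulate_component(dom, tensors, settings, derivative=False)
        # three absorption maxima spaced by a_iso
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(spec.intensity,
                              height=0.2 * spec.intensity.max())
        assert len(peaks) == 3
        positions = spec.field[peaks]
        spacings = np.diff(positions)
        assert spacings == pytest.approx(
            [tensors.a_iso, tensors.a_iso], abs=0.02)
        heights = spec.intensity[peaks]
        assert heights.max() / heights.min() < 1.1

    def test_width_floor_tau_to_zero(self, tensors, settings):
        dom_fast = DomainParams(S=0.37, tau_c=1e-9, W=0.1)
        dom_ref = DomainParams(S=0.37, tau_c=1e-12, W=0.1)
        s1 = simulate_component(dom_fast, tensors, settings)
        s2 = simulate_component(dom_ref, tensors, settings)
        assert np.max(np.abs(s1.intensity - s2.intensity)) < 1e-4 * np.max(
            np.abs(s2.intensity))

    def test_pseudo_modulation_matches_derivative_for_small_amplitude(
            self, tensors):
        small = SpectrometerSettings(modulation_amplitude=0.02)
        dom = DomainParams(S=0.37, tau_c=0.9, W=0.12)
        ana = simulate_component(dom, tensors, small)
        mod = simulate_component(dom, tensors, small, pseudo_modulation=True)
        scale = 0.5 * small.modulation_amplitude
        peak = np.max(np.abs(ana.intensity))
        assert np.max(np.abs(mod.intensity / scale - ana.intensity)) < 0.02 * peak


class TestSimulateSpectrum:
    def test_single_domain_equals_component(self, tensors, settings):
        dom = DomainParams(S=0.5, tau_c=1.0, W=0.1, d=1.0)
        a = simulate_spectrum([dom], tensors, settings)
        b = simulate_component(dom, tensors, settings)
        np.testing.assert_allclose(a.intensity, b.intensity, atol=1e-14)

    def test_two_identical_halves_equal_single(self, tensors, settings):
        kw = dict(S=0.5, tau_c=1.0, W=0.1)
        two = simulate_spectrum([DomainParams(d=0.5, **kw),
                                 DomainParams(d=0.5, **kw)],
                                tensors, settings)
        one = simulate_spectrum([DomainParams(d=1.0, **kw)], tensors, settings)
        np.testing.assert_allclose(two.intensity, one.intensity, atol=1e-12)

    def test_linear_in_proportions(self, tensors, settings, three_domains):
        full = simulate_spectrum(three_domains, tensors, settings)
        acc = np.zeros_like(full.intensity)
        for dom in three_domains:
            acc += dom.d * simulate_component(dom, tensors, settings).intensity
        np.testing.assert_allclose(full.intensity, acc, atol=1e-12)

    def test_proportions_must_sum_to_one(self, tensors, settings):
        doms = [DomainParams(S=0.5, tau_c=1.0, W=0.1, d=0.6),
                DomainParams(S=0.2, tau_c=0.5, W=0.1, d=0.6)]
        with pytest.raises(ValidationError):
            simulate_spectrum(doms, tensors, settings)

    def test_empty_domain_list_rejected(self, tensors, settings):
        with pytest.raises(ValidationError):
            simulate_spectrum([], tensors, settings)
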