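"""Hertz fitting chain: baseline, contact detection, indentation, fit."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hippomech.errors import (
    DomainError,
    InsufficientBaselineError,
    NoContactError,
    ParameterError,
)
from hippomech.forcecurve import (
    ForceCurve,
    IndentationCurve,
    analyze_curve,
    baseline_correct,
    detect_contact_point,
    fit_hertz,
    hertz_force,
    to_indentation,
)
from hippomech.synthgen import CurveGenParams, simulate_force_curve


def closed_form_hertz_nn(e_pa, nu, r_um, delta_um):
    """Independent hand evaluation: F[nN] = (4/3)(E/(1-ν²))√R δ^1.5 · 1e-3."""
    return (4.0 / 3.0) * e_pa / (1.0 - nu**2) * np.sqrt(r_um) * delta_um**1.5 * 1e-3


class TestHertzForce:
    def test_reference_point(self):
        # 1 kPa sphere of 12.5 μm at 1 μm indentation, incompressible tissue
        got = hertz_force(1000.0, 0.5, 12.5, 1.0)
        assert got == pytest.approx(6.285, abs=5e-4)
        assert got == pytest.approx(closed_form_hertz_nn(1000.0, 0.5, 12.5, 1.0))

    def test_zero_indentation_zero_force(self):
        assert hertz_force(500.0, 0.5, 12.5, 0.0) == 0.0

    @given(
        e=st.floats(10.0, 5000.0),
        delta=st.floats(0.01, 10.0),
    )
    def test_linearity_in_modulus(self, e, delta):
        f1 = hertz_force(e, 0.5, 12.5, delta)
        f2 = hertz_force(2 * e, 0.5, 12.5, delta)
        assert f2 == pytest.approx(2 * f1, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            hertz_force(-5.0, 0.5, 12.5, 1.0)
        with pytest.raises(DomainError):
            hertz_force(100.0, 0.5, 12.5, -0.1)


class TestBaseline:
    def test_perfect_line_zeroed(self):
        z = np.linspace(0, 10, 60)
        curve = ForceCurve(z, 0.02 * z + 0.3, spring_constant=0.07)
        out = baseline_correct(curve)
        assert np.allclose(out.deflections, 0.0, atol=1e-12)

    def test_generator_roundtrip_tilted_baseline(self, noiseless_curve_params):
        curve = simulate_force_curve(noiseless_curve_params(baseline_slope=0.01))
        out = baseline_correct(curve)
        pre = out.heights < 20.0 - 0.5
        assert np.max(np.abs(out.deflections[pre])) < 1e-9

    def test_idempotent_on_baseline_window(self, noiseless_curve_params):
        curve = simulate_force_curve(noiseless_curve_params(baseline_slope=0.02))
        once = baseline_correct(curve)
        twice = baseline_correct(once)
        assert np.allclose(once.deflections, twice.deflections, atol=1e-12)

    def test_too_small_window(self):
        z = np.linspace(0, 1, 25)
        curve = ForceCurve(z, z * 0.0, spring_constant=0.07)
        with pytest.raises(InsufficientBaselineError):
            baseline_correct(curve, fraction=0.1)


class TestContactPoint:
    def test_roundtrip_within_one_sample(self, noiseless_curve_params):
        params = noiseless_curve_params(elastic_modulus=200.0)
        curve = simulate_force_curve(params)
        z_c = detect_contact_point(curve)
        assert abs(z_c - 20.0) <= params.sample_spacing

    def test_all_zero_raises_no_contact(self):
        z = np.linspace(0, 10, 100)
        curve = ForceCurve(z, np.zeros_like(z), spring_constant=0.07)
        with pytest.raises(NoContactError):
            detect_contact_point(curve)

    def test_translation_equivariance(self, noiseless_curve_params):
        curve = simulate_force_curve(noiseless_curve_params())
        shifted = ForceCurve(
            curve.heights + 3.0, curve.deflections, spring_constant=0.07
        )
        assert detect_contact_point(shifted) == pytest.approx(
            detect_contact_point(curve) + 3.0, abs=1e-12
        )


class TestToIndentation:
    def test_contact_origin(self, noiseless_curve_params):
        curve = simulate_force_curve(noiseless_curve_params())
        ind = to_indentation(curve, 20.0)
        assert ind.indentations[0] == pytest.approx(0.0, abs=1e-9)
        assert ind.forces[0] == pytest.approx(0.0, abs=1e-9)

    def test_setpoint_deflection_force(self):
        # d = F/k: the 15 nN setpoint corresponds to 0.2143 μm at 0.07 N/m
        z = np.linspace(0, 1, 50)
        d = np.linspace(0, 0.2143, 50)
        curve = ForceCurve(z, d, spring_constant=0.07)
        ind = to_indentation(curve, 0.0)
        assert ind.forces[-1] == pytest.approx(15.0, abs=2e-3)

    def test_monotonic_indentation(self, noiseless_curve_params):
        curve = simulate_force_curve(noiseless_curve_params())
        ind = to_indentation(curve, 20.0)
        assert np.all(np.diff(ind.indentations) >= -1e-12)

    def test_contact_point_out_of_range(self, noiseless_curve_params):
        curve = simulate_force_curve(noiseless_curve_params())
        with pytest.raises(DomainError):
            to_indentation(curve, curve.heights.max() + 5.0)


class TestFitHertz:
    @pytest.mark.parametrize("e_true", [50.0, 100.0, 200.0, 400.0, 800.0])
    def test_noiseless_oracle_equivalence(self, e_true, noiseless_curve_params):
        curve = simulate_force_curve(noiseless_curve_params(elastic_modulus=e_true))
        res = analyze_curve(curve)
        assert res.quality_flag == "ok"
        assert abs(res.elastic_modulus - e_true) / e_true < 1e-6
        assert abs(res.contact_point - 20.0) < 1e-5

    def test_depth_capped_at_seven_microns(self, noiseless_curve_params):
        # soft tissue: the ramp reaches ~13 μm but only ≤7 μm is fitted
        curve = simulate_force_curve(noiseless_curve_params(elastic_modulus=50.0))
        res = analyze_curve(curve)
        assert res.fit_max_indentation <= 7.0 + 1e-9
        ind = to_indentation(baseline_correct(curve), 20.0)
        n_within = int(((ind.indentations > 0) & (ind.indentations <= 7.0)).sum())
        assert abs(res.n_points_fitted - n_within) <= 2

    def test_contact_radius_below_bead_radius(self, noiseless_curve_params):
        curve = simulate_force_curve(noiseless_curve_params(elastic_modulus=50.0))
        res = analyze_curve(curve)
        assert res.contact_radius == pytest.approx(
            np.sqrt(12.5 * res.fit_max_indentation), rel=1e-9
        )
        assert res.contact_radius < 12.5
        assert np.sqrt(12.5 * 7.0) == pytest.approx(9.354, abs=1e-3)

    def test_scale_consistency(self):
        delta = np.linspace(0.0, 5.0, 80)
        f = closed_form_hertz_nn(300.0, 0.5, 12.5, delta)
        for c in (1.0, 2.5):
            ind = IndentationCurve(delta, c * f, contact_point=0.0)
            res = fit_hertz(ind)
            assert res.elastic_modulus == pytest.approx(c * 300.0, rel=1e-9)

    def test_translation_invariance_of_modulus(self, noiseless_curve_params):
        curve = simulate_force_curve(noiseless_curve_params(elastic_modulus=250.0))
        shifted = ForceCurve(
            curve.heights + 11.0, curve.deflections, spring_constant=0.07
        )
        e1 = analyze_curve(curve).elastic_modulus
        e2 = analyze_curve(shifted).elastic_modulus
        assert e2 == pytest.approx(e1, rel=1e-9)

    def test_noisy_curves_unbiased(self, noiseless_curve_params):
        fitted = []
        for seed in range(500):
            params = noiseless_curve_params(
                elastic_modulus=400.0, noise_sd=0.05, seed=seed
            )
            res = analyze_curve(simulate_force_curve(params))
            if res.quality_flag == "ok":
                fitted.append(res.elastic_modulus)
        assert len(fitted) > 450
        assert np.mean(fitted) == pytest.approx(400.0, rel=0.02)

    def test_no_contact_flag_via_analyze(self):
        z = np.linspace(0, 10, 200)
        curve = ForceCurve(z, np.zeros_like(z), spring_constant=0.07)
        res = analyze_curve(curve)
        assert res.quality_flag == "no_contact"
        assert np.isnan(res.elastic_modulus)
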