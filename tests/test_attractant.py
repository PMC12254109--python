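"""Production-diffusion field, receptor binding and bias readout."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.special import expi

from woundwalk.attractant import (
    AttractantParams,
    complex_concentration,
    concentration_from_distances,
    field_concentration,
    point_source_concentration,
    predicted_bias,
    radial_gradient,
    sample_field,
)
from woundwalk.tracks import WoundGeometry


def quadrature_concentration(r, t, q, D, tau):
    """Independent oracle: adaptive quadrature of the defining integral."""
    if t == 0:
        return 0.0
    val, _ = integrate.quad(
        lambda tp: q / (4 * math.pi * D * (t - tp)) * math.exp(-r * r / (4 * D * (t - tp))),
        0.0,
        min(tau, t),
        limit=200,
    )
    return val


class TestPointSource:
    def test_zero_before_production(self):
        assert point_source_concentration(50.0, 0.0, 1.0, 200.0, 18.0) == 0.0

    @pytest.mark.parametrize(
        "r,t", [(50.0, 10.0), (50.0, 25.0), (10.0, 1.0), (200.0, 18.0), (120.0, 24.0)]
    )
    def test_ei_form_matches_quadrature(self, r, t):
        q, D, tau = 1.0, 200.0, 18.0
        assert point_source_concentration(r, t, q, D, tau) == pytest.approx(
            quadrature_concentration(r, t, q, D, tau), rel=1e-6
        )

    def test_continuous_at_production_stop(self):
        q, D, tau = 1.0, 200.0, 18.0
        before = point_source_concentration(60.0, tau, q, D, tau)
        after = point_source_concentration(60.0, tau + 1e-6, q, D, tau)
        assert after == pytest.approx(before, rel=1e-4)

    def test_decreasing_in_r_increasing_in_t(self):
        q, D, tau = 1.0, 200.0, 18.0
        rs = np.linspace(10.0, 300.0, 40)
        a = point_source_concentration(rs, 10.0, q, D, tau)
        assert np.all(np.diff(a) < 0)
        ts = np.linspace(0.5, tau, 30)
        at = np.array([point_source_concentration(80.0, t, q, D, tau) for t in ts])
        assert np.all(np.diff(at) > 0)

    def test_singular_origin_rejected(self):
        with pytest.raises(ValueError):
            point_source_concentration(0.0, 10.0, 1.0, 200.0, 18.0)

    @pytest.mark.parametrize("t", [5.0, 18.0, 25.0])
    def test_mass_conservation(self, t):
        # integral of A over the plane equals everything emitted, q*min(t,tau)
        q, D, tau = 3.0, 200.0, 18.0
        r_max = 10.0 * math.sqrt(4 * D * t)
        total, _ = integrate.quad(
            lambda r: 2 * math.pi * r * point_source_concentration(r, t, q, D, tau),
            1e-6,
            r_max,
            limit=400,
        )
        assert total == pytest.approx(q * min(t, tau), rel=0.01)


class TestFieldSuperposition:
    def test_ring_finite_at_center(self, wound, params):
        a = field_concentration((0.0, 0.0), 10.0, wound, params)
        assert np.isfinite(a) and a > 0

    def test_total_rate_independent_of_discretisation(self, params):
        # q is per wound: refining the ring leaves the far field unchanged
        w36 = WoundGeometry(center=(0.0, 0.0), radius=40.0, n_sources=36)
        w72 = WoundGeometry(center=(0.0, 0.0), radius=40.0, n_sources=72)
        pts = np.array([[50.0, 0.0], [100.0, 60.0], [0.0, -200.0]])
        a36 = field_concentration(pts, 10.0, w36, params)
        a72 = field_concentration(pts, 10.0, w72, params)
        np.testing.assert_allclose(a36, a72, rtol=5e-3)

    def test_two_wounds_midline_symmetric(self, params):
        wa = WoundGeometry(center=(-150.0, 0.0), radius=40.0)
        wb = WoundGeometry(center=(150.0, 0.0), radius=40.0)
        for y in (0.0, 50.0, -120.0):
            for x in (30.0, 100.0):
                left = field_concentration((-x, y), 12.0, [wa, wb], params)
                right = field_concentration((x, y), 12.0, [wa, wb], params)
                assert left == pytest.approx(right, rel=1e-9)

    def test_semicircle_asymmetric(self, params):
        half = WoundGeometry(center=(0.0, 0.0), radius=40.0, source_arc=((0.0, math.pi),))
        for t in (5.0, 15.0, 22.0):
            for r in (60.0, 120.0):
                top = field_concentration((0.0, r), t, half, params)
                bottom = field_concentration((0.0, -r), t, half, params)
                assert top > bottom

    def test_inactive_wound_contributes_nothing(self, params):
        silent = WoundGeometry(center=(0.0, 0.0), radius=40.0, active=False)
        a = field_concentration((100.0, 0.0), 10.0, silent, params)
        assert a == 0.0

    def test_on_source_rejected(self, wound, params):
        src = wound.source_positions()[0]
        with pytest.raises(ValueError):
            field_concentration(src, 10.0, wound, params)


class TestComplex:
    def test_no_ligand_no_complex(self):
        assert complex_concentration(0.0, 100.0, 50.0) == 0.0

    def test_saturates_at_receptor_count(self):
        R0 = 100.0
        c = complex_concentration(1e9 * R0, R0, 50.0)
        assert c == pytest.approx(R0, rel=1e-3)

    def test_quadratic_identity(self):
        A, R0, kd = 5.0, 100.0, 50.0
        c = complex_concentration(A, R0, kd)
        assert abs((R0 - c) * (A - c) - kd * c) < 1e-10

    def test_bounds_and_monotonicity(self):
        R0, kd = 300.0, 70.0
        a = np.linspace(0.0, 2000.0, 200)
        c = complex_concentration(a, R0, kd)
        assert np.all(c >= 0) and np.all(c <= np.minimum(R0, a) + 1e-12)
        assert np.all(np.diff(c) >= 0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            complex_concentration(-1.0, 10.0, 10.0)


class TestPredictedBias:
    def test_no_sensing_gives_baseline(self, wound, params):
        flat = AttractantParams(q=params.q, D=params.D, tau=params.tau, m=0.0,
                                R0=params.R0, kd=params.kd, b0=0.07)
        assert predicted_bias((100.0, 0.0), 10.0, wound, flat) == pytest.approx(0.07)

    def test_decreasing_field_biases_above_baseline(self, wound, params):
        for r in (70.0, 120.0, 200.0):
            b = predicted_bias((r, 0.0), 15.0, wound, params)
            assert b >= params.b0

    def test_baseline_at_infinity(self, wound, params):
        far = predicted_bias((5000.0, 0.0), 10.0, wound, params)
        assert far == pytest.approx(params.b0, abs=1e-9)

    def test_inactive_wound_gives_baseline_everywhere(self, params):
        silent = WoundGeometry(center=(0.0, 0.0), radius=40.0, active=False)
        assert predicted_bias((90.0, 40.0), 12.0, silent, params) == params.b0


class TestRadialGradient:
    def test_matches_analytic_single_source_derivative(self):
        # with u = r^2/4Dt, d/dr Ei(-u) = 2 exp(-u) / r, so for t < tau
        # dA/dr = -(q / 2 pi D r) exp(-r^2 / 4 D t)
        q, D, tau, t = 1.0, 200.0, 18.0, 10.0
        w = WoundGeometry(center=(0.0, 0.0), radius=40.0, n_sources=1, source_arc=((-1e-6, 1e-6),))
        # single source sits at (40, 0); measure along +x so distance from the
        # source is x - 40
        params = AttractantParams(q=q, D=D, tau=tau, m=1.0, R0=1.0, kd=1.0, b0=0.0)
        prof = radial_gradient(w, params, t, azimuth_range=(-1e-9, 1e-9), r_min=80.0,
                               r_max=160.0, dr=0.5, n_azimuth=2)
        r_eval = prof["r_um"].to_numpy()[1:-1]  # interior central differences
        d = r_eval - 40.0
        analytic = -(q / (2 * math.pi * D)) * np.exp(-d * d / (4 * D * t)) / d
        np.testing.assert_allclose(prof["grad_mean"].to_numpy()[1:-1], analytic, rtol=1e-4)

    def test_full_ring_symmetric_profiles(self, wound, params):
        up = radial_gradient(wound, params, 10.0, (math.pi / 4, 3 * math.pi / 4), r_max=200.0)
        down = radial_gradient(wound, params, 10.0, (-3 * math.pi / 4, -math.pi / 4), r_max=200.0)
        np.testing.assert_allclose(up["grad_mean"], down["grad_mean"], rtol=1e-6, atol=1e-12)

    def test_semicircle_steeper_on_source_side(self, params):
        half = WoundGeometry(center=(0.0, 0.0), radius=40.0, source_arc=((0.0, math.pi),))
        src = radial_gradient(half, params, 10.0, (math.pi / 4, 3 * math.pi / 4), r_max=200.0)
        bare = radial_gradient(half, params, 10.0, (-3 * math.pi / 4, -math.pi / 4), r_max=200.0)
        # gradients point inward (negative); source side is steeper in magnitude
        assert np.all(np.abs(src["grad_mean"]) >= np.abs(bare["grad_mean"]) - 1e-15)
        assert np.abs(src["grad_mean"]).max() > 2 * np.abs(bare["grad_mean"]).max()

    def test_empty_azimuth_range_rejected(self, wound, params):
        with pytest.raises(ValueError):
            radial_gradient(wound, params, 10.0, (1.0, 1.0), r_max=100.0)


def test_sample_field_long_format(wound, params):
    fld = sample_field(wound, params, [1.0, 10.0], (-60.0, 60.0, -60.0, 60.0), spacing=30.0)
    assert set(fld.table.columns) == {"x_um", "y_um", "t_min", "A", "C", "bias"}
    assert np.all(fld.table["A"] >= 0)
    assert fld.table["t_min"].nunique() == 2
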