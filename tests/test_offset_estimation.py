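"""Asymmetry computation, inversion round trips and decoupling validity."""

import numpy as np
import pytest

from pbsqa.geometry import DetectorId, SpotModel
from pbsqa.offset_estimation import (
    OffsetOutOfRangeError,
    ShiftMeasurementSet,
    asymmetry_model,
    compute_asymmetry,
    coupled_asymmetries,
    estimate_daily_offset,
    invert_asymmetry,
    solve_coupled_offsets,
)
from pbsqa.signal_model import signal_fraction

DELTA = 1.5


def _forward_set(dx, dy, spot, aperture, d0_scale=1000.0, delta=DELTA):
    """Noise-free five-position measurement set from the signal model."""
    def s(x, y):
        return d0_scale * signal_fraction(float(np.hypot(x, y)), spot, aperture)
    return ShiftMeasurementSet(
        detector_id=aperture.detector_id,
        d0=s(dx, dy),
        d_plus_x=s(dx + delta, dy), d_minus_x=s(dx - delta, dy),
        d_plus_y=s(dx, dy + delta), d_minus_y=s(dx, dy - delta),
        delta=delta,
    )


def test_symmetric_set_has_zero_asymmetry():
    m = ShiftMeasurementSet(DetectorId.T2, 100.0, 80.0, 80.0, 70.0, 70.0)
    a = compute_asymmetry(m)
    assert a.ax == 0.0 and a.ay == 0.0


def test_asymmetry_matches_forward_model(diode_spot, diode_aperture):
    """For a generated set at (0.5, 0), ax equals (S(2)-S(1))/S(0.5)."""
    m = _forward_set(0.5, 0.0, diode_spot, diode_aperture)
    a = compute_asymmetry(m)
    s = lambda r: signal_fraction(r, diode_spot, diode_aperture)
    assert a.ax == pytest.approx((s(2.0) - s(1.0)) / s(0.5), rel=1e-9)
    assert a.ay == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("dx", [0.3, 1.0, 1.8, 2.5])
def test_asymmetry_is_odd(dx, diode_spot, diode_aperture, cax_spot, cax_aperture):
    for spot, ap in [(diode_spot, diode_aperture), (cax_spot, cax_aperture)]:
        a_pos = compute_asymmetry(_forward_set(dx, 0.0, spot, ap)).ax
        a_neg = compute_asymmetry(_forward_set(-dx, 0.0, spot, ap)).ax
        assert a_neg == pytest.approx(-a_pos, rel=1e-9)
        assert asymmetry_model(dx, spot, ap) == pytest.approx(
            -asymmetry_model(-dx, spot, ap), rel=1e-9
        )


def test_asymmetry_model_zero_at_origin(diode_spot, diode_aperture):
    assert asymmetry_model(0.0, diode_spot, diode_aperture) == pytest.approx(0.0, abs=1e-12)


def test_asymmetry_model_monotone_decreasing(diode_spot, diode_aperture, cax_spot, cax_aperture):
    grid = np.linspace(-3, 3, 121)
    for spot, ap in [(diode_spot, diode_aperture), (cax_spot, cax_aperture)]:
        vals = asymmetry_model(grid, spot, ap)
        assert np.all(np.diff(vals) < 0)


def test_asymmetry_model_near_point_detector_closed_form():
    """For a tiny aperture the asymmetry reduces to the Gaussian-profile form."""
    sigma = 2.2
    spot = SpotModel(sigma)
    from pbsqa.geometry import DetectorAperture, DetectorRole
    ap = DetectorAperture(DetectorId.T2, sigma / 50, DetectorRole.POSITIONING_DIODE)
    g = lambda r: np.exp(-r**2 / (2 * sigma**2))
    dx = 1.5
    expected = (g(dx + DELTA) - g(dx - DELTA)) / g(dx)
    assert asymmetry_model(dx, spot, ap) == pytest.approx(expected, rel=1e-3)


@pytest.mark.parametrize("dx", [-2.5, -1.0, -0.3, 0.7, 1.5, 2.9])
def test_inversion_round_trip(dx, diode_spot, diode_aperture, cax_spot, cax_aperture):
    for spot, ap in [(diode_spot, diode_aperture), (cax_spot, cax_aperture)]:
        a = asymmetry_model(dx, spot, ap)
        assert invert_asymmetry(a, spot, ap) == pytest.approx(dx, abs=1e-3)


def test_inversion_of_zero(diode_spot, diode_aperture):
    assert invert_asymmetry(0.0, diode_spot, diode_aperture) == 0.0


def test_out_of_range_asymmetry_rejected(diode_spot, diode_aperture):
    a_max = asymmetry_model(-3.0, diode_spot, diode_aperture)
    with pytest.raises(OffsetOutOfRangeError):
        invert_asymmetry(a_max * 1.5, diode_spot, diode_aperture)
    with pytest.raises(OffsetOutOfRangeError):
        invert_asymmetry(-a_max * 1.5, diode_spot, diode_aperture)


def test_daily_offset_recovery_noise_free(diode_spot, diode_aperture):
    m = _forward_set(0.36, 0.01, diode_spot, diode_aperture)
    off = estimate_daily_offset(m, diode_spot, diode_aperture)
    assert off.dx == pytest.approx(0.36, abs=0.01)
    assert off.dy == pytest.approx(0.01, abs=0.01)
    assert off.radial == pytest.approx(np.hypot(0.36, 0.01), abs=0.01)

    centred = _forward_set(0.0, 0.0, diode_spot, diode_aperture)
    off0 = estimate_daily_offset(centred, diode_spot, diode_aperture)
    assert off0.radial == pytest.approx(0.0, abs=1e-6)


def test_recovery_bias_under_noise(diode_spot, diode_aperture):
    """0.5% multiplicative signal noise leaves the mean recovered offset
    within 0.05 mm of truth."""
    rng = np.random.default_rng(42)
    true_dx, true_dy = 0.5, 0.3
    n = 1000
    base = _forward_set(true_dx, true_dy, diode_spot, diode_aperture)
    rec = np.empty((n, 2))
    for i in range(n):
        f = 1.0 + 0.005 * rng.standard_normal(5)
        m = ShiftMeasurementSet(
            base.detector_id, base.d0 * f[0],
            base.d_plus_x * f[1], base.d_minus_x * f[2],
            base.d_plus_y * f[3], base.d_minus_y * f[4],
        )
        off = estimate_daily_offset(m, diode_spot, diode_aperture)
        rec[i] = off.dx, off.dy
    bias = rec.mean(axis=0) - (true_dx, true_dy)
    assert np.all(np.abs(bias) < 0.05)


def test_decoupled_inversion_matches_coupled_oracle(cax_spot, cax_aperture):
    """With a 3 mm transverse offset the decoupled inversion stays within
    0.05 mm of the truth for the central chamber."""
    for true_dx in np.linspace(-2.5, 2.5, 11):
        ax = coupled_asymmetries(true_dx, 3.0, cax_spot, cax_aperture).ax
        rec = invert_asymmetry(ax, cax_spot, cax_aperture)
        assert abs(rec - true_dx) < 0.05


def test_coupled_solver_recovers_2d_offset(diode_spot, diode_aperture):
    true = (0.8, -1.2)
    a = coupled_asymmetries(*true, diode_spot, diode_aperture)
    sol = solve_coupled_offsets(a.ax, a.ay, diode_spot, diode_aperture)
    assert sol.dx == pytest.approx(true[0], abs=1e-4)
    assert sol.dy == pytest.approx(true[1], abs=1e-4)


def test_sigma_mismatch_inversion_error(diode_spot, diode_aperture, cax_spot, cax_aperture):
    """Inverting the same measured asymmetry with a +/-10% wrong sigma
    displaces the estimate at 1.5 mm by about 0.22 mm (diode) and
    0.10 mm (chamber)."""
    from pbsqa.geometry import DetectorAperture, DetectorRole

    def max_err(nominal_sigma, ap):
        a = asymmetry_model(1.5, SpotModel(nominal_sigma), ap)
        errs = []
        for f in (0.9, 1.1):
            rec = invert_asymmetry(a, SpotModel(nominal_sigma * f), ap)
            errs.append(abs(rec - 1.5))
        return max(errs)

    assert max_err(2.2, diode_aperture) == pytest.approx(0.22, abs=0.03)
    assert max_err(4.8, cax_aperture) == pytest.approx(0.10, abs=0.05)


def test_measurement_set_validation():
    with pytest.raises(ValueError):
        ShiftMeasurementSet(DetectorId.T2, 0.0, 1, 1, 1, 1)
    with pytest.raises(ValueError):
        ShiftMeasurementSet(DetectorId.T2, 1, 1, 1, 1, 1, delta=0.0)
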