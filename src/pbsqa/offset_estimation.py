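"""Couch-shift signal asymmetries and their inversion to 2D spot offsets.

Because the spot never lands exactly on a detector, the daily offset is
estimated by irradiating the same pattern at five couch positions: the
aligned position and +/-delta shifts in the left-right (x) and sup-inf (y)
directions (delta defaults to 1.5 mm).  The normalized differences

    Ax = (D(+delta LR) - D(-delta LR)) / D0
    Ay = (D(+delta SI) - D(-delta SI)) / D0

are odd, strictly monotone functions of the respective offset component,
so each can be inverted by bracketed root finding.  The production path
uses the decoupled approximation Ax(dx) = (S(dx+delta,0) - S(dx-delta,0))
/ S(dx,0), valid for |dx|, |dy| < 3 mm; the fully coupled 2D system is
implemented here as well and serves as a cross-check oracle in the tests.

Sign convention: offsets are spot position minus detector position in the
room frame, and a +delta couch shift moves the detector so that it samples
S(dx + delta).  Under this convention the asymmetry is a decreasing
function of the offset.  Any self-consistent convention reproduces the
same magnitudes; the synthetic generator enforces this one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .geometry import DetectorAperture, DetectorId, SpotModel
from .signal_model import signal_2d, signal_fraction

#: Offsets beyond this magnitude (mm) are outside the validated inversion
#: domain and indicate a gross misalignment that must be investigated, not
#: estimated.
MAX_OFFSET_MM = 3.0

DEFAULT_SHIFT_MM = 1.5


class OffsetOutOfRangeError(ValueError):
    """Measured asymmetry not attainable by any offset within +/-3 mm."""


@dataclass(frozen=True)
class ShiftMeasurementSet:
    """One detector's five couch-position signals for one day."""

    detector_id: DetectorId
    d0: float
    d_plus_x: float
    d_minus_x: float
    d_plus_y: float
    d_minus_y: float
    delta: float = DEFAULT_SHIFT_MM

    def __post_init__(self) -> None:
        signals = (self.d0, self.d_plus_x, self.d_minus_x, self.d_plus_y, self.d_minus_y)
        if any(not (s > 0) for s in signals):
            raise ValueError(f"all five signals must be positive, got {signals}")
        if not (self.delta > 0):
            raise ValueError("couch shift delta must be positive")


@dataclass(frozen=True)
class AsymmetryPair:
    ax: float
    ay: float


@dataclass(frozen=True)
class DailyOffset:
    """Estimated spot-detector offset for one detector on one day (mm)."""

    dx: float
    dy: float

    @property
    def radial(self) -> float:
        return math.hypot(self.dx, self.dy)


def compute_asymmetry(m: ShiftMeasurementSet) -> AsymmetryPair:
    """Signal asymmetries of a five-position measurement set."""
    return AsymmetryPair(
        ax=(m.d_plus_x - m.d_minus_x) / m.d0,
        ay=(m.d_plus_y - m.d_minus_y) / m.d0,
    )


def asymmetry_model(
    dx: float | np.ndarray,
    spot: SpotModel,
    aperture: DetectorAperture,
    delta: float = DEFAULT_SHIFT_MM,
):
    """Decoupled forward model A(dx); odd and strictly decreasing in dx."""
    dx = np.asarray(dx, dtype=float)
    s = signal_fraction(np.stack([np.abs(dx + delta), np.abs(dx - delta), np.abs(dx)]).ravel(),
                        spot, aperture).reshape(3, *dx.shape)
    out = (s[0] - s[1]) / s[2]
    return float(out) if out.ndim == 0 else out


def coupled_asymmetries(
    dx: float,
    dy: float,
    spot: SpotModel,
    aperture: DetectorAperture,
    delta: float = DEFAULT_SHIFT_MM,
) -> AsymmetryPair:
    """Fully coupled forward model (Ax, Ay) at a 2D offset."""
    s0 = signal_2d(dx, dy, spot, aperture)
    ax = (signal_2d(dx + delta, dy, spot, aperture)
          - signal_2d(dx - delta, dy, spot, aperture)) / s0
    ay = (signal_2d(dx, dy + delta, spot, aperture)
          - signal_2d(dx, dy - delta, spot, aperture)) / s0
    return AsymmetryPair(ax, ay)


@lru_cache(maxsize=64)
def _attainable_range(sigma, diameter, detector_id, role, delta, max_offset):
    spot = SpotModel(sigma)
    aperture = DetectorAperture(detector_id, diameter, role)
    return (asymmetry_model(max_offset, spot, aperture, delta),
            asymmetry_model(-max_offset, spot, aperture, delta))


def invert_asymmetry(
    a: float,
    spot: SpotModel,
    aperture: DetectorAperture,
    delta: float = DEFAULT_SHIFT_MM,
    *,
    max_offset: float = MAX_OFFSET_MM,
    xtol: float = 1e-4,
) -> float:
    """Unique offset dx in [-3, 3] mm with asymmetry_model(dx) == a.

    Raises
    ------
    OffsetOutOfRangeError
        If ``a`` lies outside the range attained on the bracket; such a
        value signals a misalignment beyond the validity domain and is
        reported rather than extrapolated.
    """
    # decreasing convention: maximum at -max_offset, minimum at +max_offset
    a_lo, a_hi = _attainable_range(spot.sigma, aperture.diameter,
                                   aperture.detector_id, aperture.role,
                                   delta, max_offset)
    if not (a_lo <= a <= a_hi):
        raise OffsetOutOfRangeError(
            f"asymmetry {a:.4f} outside attainable range [{a_lo:.4f}, {a_hi:.4f}] "
            f"for offsets within +/-{max_offset} mm"
        )
    if a == 0.0:
        return 0.0
    return brentq(
        lambda x: asymmetry_model(x, spot, aperture, delta) - a,
        -max_offset, max_offset, xtol=xtol,
    )


def solve_coupled_offsets(
    ax: float,
    ay: float,
    spot: SpotModel,
    aperture: DetectorAperture,
    delta: float = DEFAULT_SHIFT_MM,
    *,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> DailyOffset:
    """Solve the coupled 2-equation system for (dx, dy).

    Alternating 1D inversions with the other coordinate held fixed; the
    cross-coupling is weak for offsets below 3 mm, so this fixed-point
    iteration converges in a few sweeps.  Used as the oracle against which
    the decoupled production path is validated.
    """
    dx, dy = 0.0, 0.0
    for _ in range(max_iter):
        def fx(x: float) -> float:
            s0 = signal_2d(x, dy, spot, aperture)
            return (signal_2d(x + delta, dy, spot, aperture)
                    - signal_2d(x - delta, dy, spot, aperture)) / s0 - ax

        def fy(y: float) -> float:
            s0 = signal_2d(dx, y, spot, aperture)
            return (signal_2d(dx, y + delta, spot, aperture)
                    - signal_2d(dx, y - delta, spot, aperture)) / s0 - ay

        dx_new = brentq(fx, -MAX_OFFSET_MM - 0.5, MAX_OFFSET_MM + 0.5, xtol=tol / 10)
        dy_new = brentq(fy, -MAX_OFFSET_MM - 0.5, MAX_OFFSET_MM + 0.5, xtol=tol / 10)
        shift = max(abs(dx_new - dx), abs(dy_new - dy))
        dx, dy = dx_new, dy_new
        if shift < tol:
            break
    return DailyOffset(dx, dy)


def estimate_daily_offset(
    m: ShiftMeasurementSet,
    spot: SpotModel,
    aperture: DetectorAperture,
) -> DailyOffset:
    """Per-day 2D offset from a five-position measurement set."""
    a = compute_asymmetry(m)
    dx = invert_asymmetry(a.ax, spot, aperture, m.delta)
    dy = invert_asymmetry(a.ay, spot, aperture, m.delta)
    return DailyOffset(dx, dy)
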