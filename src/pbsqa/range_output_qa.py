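"""Range and output constancy QA from chamber signal ratios.

Two SOBPs are delivered so that one chamber of each pair (det-TL, det-BR)
sits on the distal falloff while its partner (det-BL, det-TR) sits on the
flat plateau.  The distal/plateau signal ratio is then a steep, monotone
function of residual range, and the plateau chambers' absolute signals
monitor output.

Tolerances are empirical: during commissioning the ratio is measured with
0, 1, 2 and 4 mm of plastic water added on top of the permanent 1 mm slab.
The ratio at 1 mm is the daily reference, and the ratios at 0 and 2 mm
become the upper and lower bounds, realizing a +/-1 mm range-constancy
tolerance without any analytic depth-dose model.  Output tolerance is a
+/-3% band around the campaign-mean plateau signal (daily-QA output
constancy recommendation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .geometry import DetectorId

#: Ratios outside this band lose sensitivity to range changes and are
#: flagged (not rejected).
SENSITIVE_RATIO_BAND = (0.2, 0.8)

DEFAULT_REFERENCE_WET_MM = 1.0
DEFAULT_OUTPUT_TOLERANCE_PCT = 3.0


class RangeVerdict(str, Enum):
    PASS = "pass"
    FAIL_HIGH = "fail_high"  # ratio above upper bound: range long / WET deficit
    FAIL_LOW = "fail_low"    # ratio below lower bound: range short / WET excess


class OutputVerdict(str, Enum):
    PASS = "pass"
    FAIL = "fail"


class CalibrationCurveError(ValueError):
    """Range-calibration sweep unusable (non-monotone or incomplete)."""


@dataclass(frozen=True)
class RangeCalibrationCurve:
    """Measured distal/plateau signal ratios vs added plastic-water WET."""

    block_label: str  # left_sobp | right_sobp
    config_label: str
    points: tuple[tuple[float, float], ...]  # (added WET mm, ratio), sorted
    reference_wet: float = DEFAULT_REFERENCE_WET_MM

    def __post_init__(self) -> None:
        wets = [p[0] for p in self.points]
        ratios = [p[1] for p in self.points]
        if len(self.points) < 3:
            raise CalibrationCurveError("need at least 3 calibration points")
        if sorted(wets) != wets or len(set(wets)) != len(wets):
            raise CalibrationCurveError("WET points must be strictly increasing")
        if any(r2 >= r1 for r1, r2 in zip(ratios, ratios[1:])):
            raise CalibrationCurveError(
                "ratios must decrease strictly with added WET; a flat or "
                "inverted curve cannot define a range tolerance"
            )
        lo, hi = SENSITIVE_RATIO_BAND
        if min(ratios) < lo or max(ratios) > hi:
            warnings.warn(
                f"{self.block_label}/{self.config_label}: calibration ratios "
                f"extend outside the sensitive band [{lo}, {hi}]",
                stacklevel=2,
            )

    def ratio_at(self, wet: float) -> float:
        """Monotone piecewise-linear interpolation; no extrapolation."""
        wets = np.array([p[0] for p in self.points])
        ratios = np.array([p[1] for p in self.points])
        if not (wets[0] <= wet <= wets[-1]):
            raise CalibrationCurveError(
                f"WET {wet} mm outside calibrated range [{wets[0]}, {wets[-1]}] mm"
            )
        return float(np.interp(wet, wets, ratios))


@dataclass(frozen=True)
class RangeTolerance:
    """Reference ratio and bounds realizing a +/-1 mm range tolerance."""

    reference_ratio: float
    upper_ratio: float  # ratio with 0 mm added WET
    lower_ratio: float  # ratio with 2 mm added WET

    def __post_init__(self) -> None:
        if not (self.lower_ratio < self.reference_ratio < self.upper_ratio):
            raise ValueError(
                "tolerance band must bracket the reference ratio: "
                f"{self.lower_ratio} < {self.reference_ratio} < {self.upper_ratio}"
            )


@dataclass(frozen=True)
class OutputBaseline:
    """Campaign-mean plateau-chamber signal with a +/- percent tolerance."""

    detector_id: DetectorId
    config_label: str
    mean_signal: float
    tolerance_percent: float = DEFAULT_OUTPUT_TOLERANCE_PCT

    def __post_init__(self) -> None:
        if not (self.mean_signal > 0):
            raise ValueError("baseline mean signal must be positive")
        if not (self.tolerance_percent > 0):
            raise ValueError("tolerance percent must be positive")


@dataclass(frozen=True)
class OutputCheck:
    verdict: OutputVerdict
    deviation_percent: float


def compute_ratio(signal_distal: float, signal_plateau: float) -> float:
    """Distal-edge over plateau chamber signal ratio."""
    if not (signal_plateau > 0):
        raise ValueError(f"plateau signal must be positive, got {signal_plateau}")
    ratio = signal_distal / signal_plateau
    lo, hi = SENSITIVE_RATIO_BAND
    if not (lo <= ratio <= hi):
        warnings.warn(
            f"signal ratio {ratio:.3f} outside the sensitive band [{lo}, {hi}]",
            stacklevel=2,
        )
    return ratio


def derive_range_tolerance(
    curve: RangeCalibrationCurve,
    *,
    band_mm: float = 1.0,
) -> RangeTolerance:
    """Tolerance band from the plastic-water sweep.

    The reference is the ratio at the permanent reference WET (1 mm added);
    the upper/lower bounds are the ratios at reference -/+ ``band_mm``
    (i.e. 0 and 2 mm for the default +/-1 mm range tolerance).
    """
    ref = curve.ratio_at(curve.reference_wet)
    upper = curve.ratio_at(curve.reference_wet - band_mm)
    lower = curve.ratio_at(curve.reference_wet + band_mm)
    return RangeTolerance(reference_ratio=ref, upper_ratio=upper, lower_ratio=lower)


def check_range(daily_ratio: float, tol: RangeTolerance) -> RangeVerdict:
    """Verdict on a daily distal/plateau ratio."""
    if daily_ratio > tol.upper_ratio:
        return RangeVerdict.FAIL_HIGH
    if daily_ratio < tol.lower_ratio:
        return RangeVerdict.FAIL_LOW
    return RangeVerdict.PASS


def check_output(daily_signal: float, baseline: OutputBaseline) -> OutputCheck:
    """Percent deviation of a plateau signal from its campaign baseline."""
    dev = 100.0 * (daily_signal - baseline.mean_signal) / baseline.mean_signal
    verdict = (OutputVerdict.PASS if abs(dev) <= baseline.tolerance_percent
               else OutputVerdict.FAIL)
    return OutputCheck(verdict=verdict, deviation_percent=dev)


def output_baseline_from_campaign(
    detector_id: DetectorId,
    config_label: str,
    signals: Sequence[float],
    tolerance_percent: float = DEFAULT_OUTPUT_TOLERANCE_PCT,
) -> OutputBaseline:
    """Baseline from a campaign of daily plateau signals (>= 2 days)."""
    if len(signals) < 2:
        raise ValueError("need at least 2 campaign days for a baseline")
    return OutputBaseline(
        detector_id=detector_id,
        config_label=config_label,
        mean_signal=float(np.mean(signals)),
        tolerance_percent=tolerance_percent,
    )
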