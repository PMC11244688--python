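"""Synthetic calibration campaigns, daily exports and range sweeps.

No public measurement dataset exists for this device, so every consumer of
measured data in the package is exercised against synthetic data drawn
from the same statistical model the QA framework assumes:

* per-day setup offsets (dx, dy) are bivariate normal with mean
  (mu_x, mu_y) and a common per-axis spread sigma_setup, so the radial
  offset is Rice-distributed by construction;
* detector signals follow the aperture-integrated Gaussian signal model
  evaluated at the day's offset (and at the four shifted couch positions
  for calibration campaigns), with multiplicative noise of configurable
  coefficient of variation (default 0.5%, consistent with the observed
  day-to-day variability of the central chamber);
* distal/plateau range ratios follow a complementary-error-function
  falloff in added water-equivalent thickness.  This functional form is
  the generator's own invention - in the clinic the curve is measured, not
  modelled - and nothing downstream depends on its shape, only on its
  monotonicity.

Every generator is deterministic under a fixed seed and returns a
ground-truth record next to the data so recovery tests never peek at the
estimation chain.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc

from .geometry import (
    OUTPUT_CHAMBERS,
    RANGE_PAIRS,
    DetectorGeometry,
    DetectorId,
    DetectorRole,
)
from .range_output_qa import RangeCalibrationCurve
from .signal_model import signal_fraction

DEFAULT_NOISE_CV = 0.005
DEFAULT_CAMPAIGN_DAYS = 20

#: Nominal perfectly-centred signals (device counts) used by the generator.
#: The plateau-chamber values follow typical published 20-day averages of
#: this device class; diode and CAX counts are round nominal scales.
NOMINAL_SIGNALS = {
    "config1": {
        DetectorId.BL: 502.0, DetectorId.TR: 561.0,
        DetectorId.TL: 502.0 * 0.62, DetectorId.BR: 561.0 * 0.55,
        DetectorId.CAX: 1000.0,
        DetectorId.T2: 1000.0, DetectorId.L2: 1000.0,
        DetectorId.R2: 1000.0, DetectorId.B2: 1000.0,
    },
    "config2": {
        DetectorId.BL: 523.3, DetectorId.TR: 585.2,
        DetectorId.TL: 523.3 * 0.62, DetectorId.BR: 585.2 * 0.55,
        DetectorId.CAX: 1000.0,
        DetectorId.T2: 1000.0, DetectorId.L2: 1000.0,
        DetectorId.R2: 1000.0, DetectorId.B2: 1000.0,
    },
}


@dataclass(frozen=True)
class SetupErrorModel:
    """Ground truth for the daily setup-error distribution (mm)."""

    mu_x: float = 0.5
    mu_y: float = 0.2
    sigma_setup: float = 0.25
    sigma_setup_y: float | None = None  # optional unequal-axis mode
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_setup < 0:
            raise ValueError("sigma_setup must be non-negative")

    @property
    def nu_true(self) -> float:
        return float(np.hypot(self.mu_x, self.mu_y))

    def draw_offsets(self, n_days: int, rng: np.random.Generator) -> np.ndarray:
        sy = self.sigma_setup if self.sigma_setup_y is None else self.sigma_setup_y
        dx = rng.normal(self.mu_x, self.sigma_setup, n_days)
        dy = rng.normal(self.mu_y, sy, n_days)
        return np.column_stack([dx, dy])


@dataclass(frozen=True)
class FalloffModel:
    """Distal-falloff model for the range-ratio sweep.

    ratio(w) = ratio0 * erfc((w - midpoint)/width) / erfc(-midpoint/width),
    strictly decreasing in added WET w; defaults keep the four standard
    sweep points inside the sensitive [0.2, 0.8] ratio band.
    """

    ratio0: float = 0.79
    falloff_width: float = 3.0
    midpoint: float = 2.5

    def __post_init__(self) -> None:
        if not (self.falloff_width > 0):
            raise ValueError("falloff width must be positive")
        if not (0 < self.ratio0 < 1):
            raise ValueError("ratio0 must be in (0, 1)")

    def ratio(self, wet_mm: float | np.ndarray) -> np.ndarray | float:
        w = np.asarray(wet_mm, dtype=float)
        val = self.ratio0 * erfc((w - self.midpoint) / self.falloff_width) \
            / erfc(-self.midpoint / self.falloff_width)
        return float(val) if val.ndim == 0 else val


_POSITION_SHIFTS = {
    # couch shift +delta samples S(offset + delta) under the package's
    # sign convention (spot minus detector, room frame)
    "center": (0.0, 0.0),
    "+x": (1.0, 0.0),
    "-x": (-1.0, 0.0),
    "+y": (0.0, 1.0),
    "-y": (0.0, -1.0),
}


def _config_for_day(day_index: int, start: dt.date) -> str:
    """Config 1 on Mon/Wed/Fri, config 2 otherwise (weekend days skipped
    by the caller's date arithmetic are not modelled; the alternation only
    matters as metadata)."""
    weekday = (start + dt.timedelta(days=day_index)).weekday()
    return "config1" if weekday in (0, 2, 4) else "config2"


def generate_campaign(
    model: SetupErrorModel,
    n_days: int = DEFAULT_CAMPAIGN_DAYS,
    noise_cv: float = DEFAULT_NOISE_CV,
    detectors: Sequence[DetectorId] | None = None,
    geometry: DetectorGeometry | None = None,
    delta: float = 1.5,
    start_date: dt.date = dt.date(2023, 3, 1),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an N-day five-couch-position calibration campaign.

    Returns ``(signals, truth)``: the calibration-CSV-dialect signal table
    (date, detector_id, position_label, corrected_signal, config) and the
    ground-truth per-day offsets.  One offset draw per day is shared by
    all detectors (the whole device is displaced by the setup error).
    """
    if n_days < 1:
        raise ValueError("campaign needs at least one day")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    geometry = geometry or DetectorGeometry.default()
    if detectors is None:
        detectors = [s.detector_id for s in geometry.detectors.values()
                     if s.role in (DetectorRole.POSITIONING_DIODE,
                                   DetectorRole.CENTERING_CHAMBER)]
    rng = np.random.default_rng(model.seed)
    offsets = model.draw_offsets(n_days, rng)
    sig_rows, truth_rows = [], []
    for i in range(n_days):
        date = (start_date + dt.timedelta(days=i)).isoformat()
        config = _config_for_day(i, start_date)
        dx, dy = offsets[i]
        truth_rows.append({"date": date, "dx_mm": dx, "dy_mm": dy,
                           "radial_mm": float(np.hypot(dx, dy)), "config": config})
        for det in detectors:
            spec = geometry[det]
            d0_nominal = NOMINAL_SIGNALS[config][det]
            for label, (sx, sy) in _POSITION_SHIFTS.items():
                r = np.hypot(dx + sx * delta, dy + sy * delta)
                s = signal_fraction(float(r), spec.spot, spec.aperture)
                noise = 1.0 + noise_cv * rng.standard_normal() if noise_cv else 1.0
                sig_rows.append({
                    "date": date,
                    "detector_id": det.value,
                    "position_label": label,
                    "corrected_signal": d0_nominal * s * noise,
                    "config": config,
                })
    return pd.DataFrame(sig_rows), pd.DataFrame(truth_rows)


def ratio_curve(
    f: FalloffModel,
    wets: Sequence[float] = (0.0, 1.0, 2.0, 4.0),
    block_label: str = "left_sobp",
    config_label: str = "config1",
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> RangeCalibrationCurve:
    """Synthetic plastic-water sweep as a range calibration curve."""
    if min(wets) < 0 or max(wets) > 5.0:
        raise ValueError("sweep WETs must lie within [0, 5] mm")
    ratios = np.asarray(f.ratio(np.asarray(wets, dtype=float)))
    if noise_cv:
        if rng is None:
            rng = np.random.default_rng(0)
        ratios = ratios * (1.0 + noise_cv * rng.standard_normal(len(ratios)))
    points = tuple(zip([float(w) for w in wets], [float(r) for r in ratios]))
    return RangeCalibrationCurve(
        block_label=block_label, config_label=config_label, points=points
    )


def generate_daily_exports(
    model: SetupErrorModel,
    n_days: int,
    noise_cv: float = DEFAULT_NOISE_CV,
    drift_percent_per_month: float = 0.0,
    wet_error_mm: float = 0.0,
    diode_displacement: tuple[DetectorId, float] | None = None,
    falloff: FalloffModel | None = None,
    geometry: DetectorGeometry | None = None,
    start_date: dt.date = dt.date(2023, 4, 1),
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate daily-QA raw exports (counts, T, P) with optional faults.

    Fault injection knobs: ``drift_percent_per_month`` applies a linear
    output drift to every chamber; ``wet_error_mm`` shifts the effective
    WET of both SOBP blocks (range fault); ``diode_displacement`` adds an
    extra fixed offset (mm) to one positioning diode.

    Returns ``(exports, truth)`` where exports follow the daily-export CSV
    dialect and truth records the per-day offsets and fault state.
    """
    geometry = geometry or DetectorGeometry.default()
    falloff = falloff or FalloffModel()
    rng = np.random.default_rng(model.seed if seed is None else seed)
    offsets = model.draw_offsets(n_days, rng)
    background = 50.0
    rows, truth_rows = [], []
    for i in range(n_days):
        date = start_date + dt.timedelta(days=i)
        config = _config_for_day(i, start_date)
        dx, dy = offsets[i]
        temp = float(np.clip(rng.normal(22.0, 1.0), *((15.0, 30.0))))
        pres = float(np.clip(rng.normal(101.0, 0.4), *((95.0, 105.0))))
        drift = 1.0 + (drift_percent_per_month / 100.0) * (i / 30.0)
        ktp = ((273.15 + temp) / (273.15 + 20.0)) * (101.325 / pres)
        nominal = NOMINAL_SIGNALS[config]
        truth_rows.append({"date": date.isoformat(), "config": config,
                           "dx_mm": dx, "dy_mm": dy, "drift_factor": drift,
                           "wet_error_mm": wet_error_mm})

        signals: dict[DetectorId, float] = {}
        # positioning diodes and centering chamber: spot model at the offset
        for spec in geometry.detectors.values():
            det = spec.detector_id
            if spec.role is DetectorRole.RANGE_OUTPUT_CHAMBER:
                continue
            ddx, ddy = dx, dy
            if diode_displacement is not None and det == diode_displacement[0]:
                ddx = dx + diode_displacement[1]
            s = signal_fraction(float(np.hypot(ddx, ddy)), spec.spot, spec.aperture)
            noise = 1.0 + noise_cv * rng.standard_normal() if noise_cv else 1.0
            signals[det] = nominal[det] * s * noise * drift
        # plateau chambers: output level only
        for det in OUTPUT_CHAMBERS:
            noise = 1.0 + noise_cv * rng.standard_normal() if noise_cv else 1.0
            signals[det] = nominal[det] * noise * drift
        # distal chambers: plateau partner times the falloff ratio at the
        # (possibly faulted) effective WET
        for block, (distal, plateau) in RANGE_PAIRS.items():
            eff_wet = 1.0 + wet_error_mm
            noise = 1.0 + noise_cv * rng.standard_normal() if noise_cv else 1.0
            signals[distal] = signals[plateau] * falloff.ratio(eff_wet) * noise

        for det, sig in signals.items():
            is_diode = geometry[det].role is DetectorRole.POSITIONING_DIODE
            raw = sig if is_diode else sig / ktp  # exports carry uncorrected counts
            rows.append({
                "date": date.isoformat(),
                "gantry": "G1",
                "config": config,
                "detector_id": det.value,
                "raw_counts": raw + background,
                "background_counts": background,
                "irradiation_time_s": 60.0,
                "temperature_c": temp,
                "pressure_kpa": pres,
            })
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
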