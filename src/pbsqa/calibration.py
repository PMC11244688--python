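"""Rice-distribution calibration of systematic spot-detector offsets.

Daily setup errors displace the whole QA device, so the per-day 2D offset
between a spot and its detector fluctuates around a systematic mean.  If
the per-axis offsets are bivariate normal with a common spread sigma_xy,
the radial offset Delta follows a Rice distribution with noncentrality nu
(the magnitude of the systematic offset).  An N-day calibration campaign
of five-couch-position measurements yields per-day (dx_i, dy_i); from
these the campaign estimates

    nu       = mean of the per-day radial offsets,
    sigma_xy = max(std(dx_i), std(dy_i))   (conservative: the larger
               spread inflates the mean and hence the threshold),

and the mean radial offset as the Rice mean

    mean = sigma_xy * sqrt(pi/2) * L_{1/2}(-nu^2 / (2 sigma_xy^2)),

with L_{1/2} the generalized Laguerre function of order 1/2.  The absolute
signal threshold for a positioning tolerance ``tol`` is then

    th = D0_bar * S(tol) / S(mean),

where D0_bar is the campaign-mean aligned signal (kept separately per plan
configuration, because the central spot energies differ) and S the
aperture-integrated signal model.  1-sigma bounds on the mean (Rice mean
+/- Rice standard deviation, floored at zero) propagate to an advisory
threshold band.

The campaign estimation is exposed both as plain functions and as a
model/results pair: ``SpotPositionCalibration`` holds the campaign data,
``fit()`` returns ``SpotPositionCalibrationResults`` with the per-detector
estimates, their 1-sigma bounds, thresholds and a ``summary()`` table.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import i0e, i1e

from .geometry import DetectorAperture, DetectorGeometry, DetectorId, SpotModel
from .offset_estimation import (
    DailyOffset,
    ShiftMeasurementSet,
    estimate_daily_offset,
)
from .signal_model import signal_fraction

DEFAULT_TOLERANCE_MM = 1.5
DEFAULT_CONFIGS = ("config1", "config2")


class DegenerateCampaignError(ValueError):
    """Campaign with zero spread: the Rice model is undefined."""


@dataclass(frozen=True)
class CampaignOffsets:
    """Per-day estimated offsets of one detector over a campaign."""

    detector_id: DetectorId
    dx: tuple[float, ...]
    dy: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.dx) != len(self.dy):
            raise ValueError("dx and dy must have equal length")
        if len(self.dx) == 0:
            raise ValueError("campaign must contain at least one day")

    @property
    def n_days(self) -> int:
        return len(self.dx)

    @property
    def radial(self) -> np.ndarray:
        return np.hypot(np.asarray(self.dx), np.asarray(self.dy))


@dataclass(frozen=True)
class RiceCalibration:
    """Fitted Rice parameters and derived mean offset for one detector."""

    nu: float
    sigma_xy: float
    delta_bar: float
    delta_bar_lo: float
    delta_bar_hi: float
    s_at_delta_bar: float
    s_lo: float  # S at delta_bar_hi (larger offset -> smaller signal)
    s_hi: float  # S at delta_bar_lo


@dataclass(frozen=True)
class ThresholdSet:
    """Absolute signal threshold for one detector and one configuration."""

    detector_id: DetectorId
    config_label: str
    d0_bar: float
    tolerance_mm: float
    threshold: float
    threshold_lo: float
    threshold_hi: float

    def __post_init__(self) -> None:
        # threshold == d0_bar only at the degenerate point delta_bar == tolerance
        if not (0 < self.threshold <= self.d0_bar):
            raise ValueError(
                f"threshold {self.threshold} must lie in (0, D0_bar={self.d0_bar}]"
            )


def estimate_nu(c: CampaignOffsets) -> float:
    """Noncentrality estimate: mean of the per-day radial offsets (mm)."""
    return float(np.mean(c.radial))


def estimate_sigma_xy(c: CampaignOffsets) -> float:
    """Common spread estimate: larger of the two per-axis sample
    standard deviations (n-1 denominator)."""
    if c.n_days < 2:
        raise ValueError("need at least 2 days to estimate a spread")
    return float(max(np.std(c.dx, ddof=1), np.std(c.dy, ddof=1)))


def rice_mean(nu: float, sigma: float) -> float:
    """Mean of the Rice distribution, sigma*sqrt(pi/2)*L_{1/2}(-nu^2/2sigma^2).

    Evaluated via exponentially scaled Bessel functions:
    L_{1/2}(-x) = exp(-x/2) * ((1+x) I0(x/2) + x I1(x/2)) with
    x = nu^2 / (2 sigma^2), which is stable for any nu/sigma.
    """
    if not (sigma > 0):
        raise ValueError("sigma must be positive")
    if nu < 0:
        raise ValueError("nu must be non-negative")
    x = nu * nu / (2.0 * sigma * sigma)
    return sigma * math.sqrt(math.pi / 2.0) * ((1.0 + x) * i0e(x / 2.0) + x * i1e(x / 2.0))


def rice_std(nu: float, sigma: float) -> float:
    """Standard deviation of the Rice distribution,
    sqrt(nu^2 + 2 sigma^2 - mean^2)."""
    m = rice_mean(nu, sigma)
    return math.sqrt(max(nu * nu + 2.0 * sigma * sigma - m * m, 0.0))


def rice_sigma_bounds(nu: float, sigma: float) -> tuple[float, float]:
    """1-sigma bounds on the mean radial offset: mean -/+ Rice standard
    deviation, the lower bound floored at zero."""
    m = rice_mean(nu, sigma)
    s = rice_std(nu, sigma)
    return max(m - s, 0.0), m + s


def fit_rice(
    c: CampaignOffsets,
    spot: SpotModel,
    aperture: DetectorAperture,
) -> RiceCalibration:
    """Campaign offsets -> Rice parameters, mean offset and signal factors."""
    nu = estimate_nu(c)
    sigma_xy = estimate_sigma_xy(c)
    if sigma_xy < 1e-9:  # identical days up to rounding: no spread information
        raise DegenerateCampaignError(
            f"{c.detector_id.value}: per-axis spread is zero; the Rice model "
            "is undefined for a degenerate campaign"
        )
    delta_bar = rice_mean(nu, sigma_xy)
    lo, hi = rice_sigma_bounds(nu, sigma_xy)
    s_bar, s_at_hi, s_at_lo = signal_fraction(
        np.array([delta_bar, hi, lo]), spot, aperture
    )
    return RiceCalibration(
        nu=nu, sigma_xy=sigma_xy, delta_bar=delta_bar,
        delta_bar_lo=lo, delta_bar_hi=hi,
        s_at_delta_bar=float(s_bar), s_lo=float(s_at_hi), s_hi=float(s_at_lo),
    )


def compute_threshold(
    d0_bar: float,
    tolerance_mm: float,
    cal: RiceCalibration,
    spot: SpotModel,
    aperture: DetectorAperture,
    *,
    detector_id: DetectorId | None = None,
    config_label: str = "config1",
) -> ThresholdSet:
    """Absolute signal threshold th = D0_bar * S(tol) / S(delta_bar).

    The 1-sigma band uses S at the bounds of the mean offset: a larger
    mean offset depresses the baseline signal more, so dividing by the
    smaller S(delta_bar_hi) yields the upper (more conservative) threshold.
    """
    if not (d0_bar > 0):
        raise ValueError("D0_bar must be positive")
    if not (tolerance_mm > 0):
        raise ValueError("tolerance must be positive")
    s_tol = signal_fraction(tolerance_mm, spot, aperture)
    th = d0_bar * s_tol / cal.s_at_delta_bar
    th_hi = d0_bar * s_tol / cal.s_lo
    th_lo = d0_bar * s_tol / cal.s_hi
    return ThresholdSet(
        detector_id=detector_id if detector_id is not None else aperture.detector_id,
        config_label=config_label,
        d0_bar=d0_bar,
        tolerance_mm=tolerance_mm,
        threshold=float(th),
        threshold_lo=float(th_lo),
        threshold_hi=float(th_hi),
    )


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------


class SpotPositionCalibration:
    """Calibration model for the spot positioning and centering thresholds.

    Built either directly from per-day offsets (columns ``date``,
    ``detector_id``, ``dx_mm``, ``dy_mm``) or, via :meth:`from_signals`,
    from the raw five-couch-position signal table, in which case the
    asymmetry inversion chain runs first and the per-configuration mean
    aligned signals D0_bar are compiled alongside.
    """

    def __init__(
        self,
        offsets: pd.DataFrame,
        geometry: DetectorGeometry | None = None,
        d0_bar: Mapping[DetectorId, Mapping[str, float]] | None = None,
        tolerance_mm: float = DEFAULT_TOLERANCE_MM,
    ) -> None:
        required = {"date", "detector_id", "dx_mm", "dy_mm"}
        missing = required - set(offsets.columns)
        if missing:
            raise ValueError(f"offsets frame missing columns {sorted(missing)}")
        self.offsets = offsets.copy()
        self.geometry = geometry or DetectorGeometry.default()
        self.d0_bar = {DetectorId(k): dict(v) for k, v in (d0_bar or {}).items()}
        self.tolerance_mm = tolerance_mm

    @classmethod
    def from_signals(
        cls,
        signals: pd.DataFrame,
        geometry: DetectorGeometry | None = None,
        delta: float = 1.5,
        tolerance_mm: float = DEFAULT_TOLERANCE_MM,
    ) -> "SpotPositionCalibration":
        """Build the model from a five-position calibration signal table.

        Expected columns: ``date``, ``detector_id``, ``position_label``
        (one of center, +x, -x, +y, -y), ``corrected_signal`` and
        optionally ``config`` (defaults to config1); exactly five labelled
        rows per detector per day.
        """
        geometry = geometry or DetectorGeometry.default()
        df = signals.copy()
        if "config" not in df.columns:
            df["config"] = "config1"
        rows = []
        d0_acc: dict[DetectorId, dict[str, list[float]]] = {}
        for (date, det), grp in df.groupby(["date", "detector_id"], sort=True):
            labels = dict(zip(grp["position_label"], grp["corrected_signal"]))
            expected = {"center", "+x", "-x", "+y", "-y"}
            if set(labels) != expected or len(grp) != 5:
                raise ValueError(
                    f"{date}/{det}: expected exactly one row per position "
                    f"label {sorted(expected)}, got {sorted(grp['position_label'])}"
                )
            det_id = DetectorId(det)
            spec = geometry[det_id]
            m = ShiftMeasurementSet(
                detector_id=det_id,
                d0=labels["center"],
                d_plus_x=labels["+x"], d_minus_x=labels["-x"],
                d_plus_y=labels["+y"], d_minus_y=labels["-y"],
                delta=delta,
            )
            off = estimate_daily_offset(m, spec.spot, spec.aperture)
            rows.append({"date": date, "detector_id": det_id.value,
                         "dx_mm": off.dx, "dy_mm": off.dy})
            cfg = str(grp["config"].iloc[0])
            d0_acc.setdefault(det_id, {}).setdefault(cfg, []).append(labels["center"])
        d0_bar = {
            det: {cfg: float(np.mean(vals)) for cfg, vals in cfgs.items()}
            for det, cfgs in d0_acc.items()
        }
        return cls(pd.DataFrame(rows), geometry, d0_bar, tolerance_mm)

    def campaign(self, detector_id: DetectorId) -> CampaignOffsets:
        sub = self.offsets[self.offsets["detector_id"] == detector_id.value]
        if sub.empty:
            raise KeyError(f"no offsets for detector {detector_id.value}")
        return CampaignOffsets(
            detector_id=detector_id,
            dx=tuple(sub["dx_mm"]),
            dy=tuple(sub["dy_mm"]),
        )

    def fit(self) -> "SpotPositionCalibrationResults":
        cals: dict[DetectorId, RiceCalibration] = {}
        n_days: dict[DetectorId, int] = {}
        for det in sorted(self.offsets["detector_id"].unique()):
            det_id = DetectorId(det)
            spec = self.geometry[det_id]
            c = self.campaign(det_id)
            cals[det_id] = fit_rice(c, spec.spot, spec.aperture)
            n_days[det_id] = c.n_days
        return SpotPositionCalibrationResults(self, cals, n_days)


@dataclass
class SpotPositionCalibrationResults:
    """Fitted campaign: per-detector Rice parameters and thresholds."""

    model: SpotPositionCalibration
    calibrations: Mapping[DetectorId, RiceCalibration]
    n_days: Mapping[DetectorId, int]

    @property
    def params(self) -> pd.DataFrame:
        rows = []
        for det, cal in self.calibrations.items():
            rows.append({
                "detector_id": det.value,
                "n_days": self.n_days[det],
                "nu_mm": cal.nu,
                "sigma_xy_mm": cal.sigma_xy,
                "delta_bar_mm": cal.delta_bar,
                "delta_bar_lo_mm": cal.delta_bar_lo,
                "delta_bar_hi_mm": cal.delta_bar_hi,
                "drop_at_delta_bar_pct": 100.0 * (1.0 - cal.s_at_delta_bar),
            })
        return pd.DataFrame(rows).set_index("detector_id")

    def thresholds(
        self,
        tolerance_mm: float | None = None,
        d0_bar: Mapping[DetectorId, Mapping[str, float]] | None = None,
    ) -> dict[DetectorId, dict[str, ThresholdSet]]:
        """Per-detector, per-configuration absolute signal thresholds."""
        tol = tolerance_mm if tolerance_mm is not None else self.model.tolerance_mm
        d0 = {DetectorId(k): dict(v) for k, v in (d0_bar or self.model.d0_bar).items()}
        if not d0:
            raise ValueError("no D0_bar values available; pass d0_bar explicitly")
        out: dict[DetectorId, dict[str, ThresholdSet]] = {}
        for det, cal in self.calibrations.items():
            if det not in d0:
                continue
            spec = self.model.geometry[det]
            out[det] = {
                cfg: compute_threshold(
                    val, tol, cal, spec.spot, spec.aperture,
                    detector_id=det, config_label=cfg,
                )
                for cfg, val in d0[det].items()
            }
        return out

    def summary(self) -> str:
        """Human-readable calibration summary table."""
        lines = ["Spot position calibration (Rice model)",
                 "=" * 72]
        df = self.params
        lines.append(
            f"{'det':>5} {'days':>5} {'nu/mm':>7} {'sxy/mm':>7} "
            f"{'mean/mm':>8} {'1s-lo':>6} {'1s-hi':>6} {'drop%':>7}"
        )
        for det, row in df.iterrows():
            lines.append(
                f"{det:>5} {int(row['n_days']):>5d} {row['nu_mm']:>7.3f} "
                f"{row['sigma_xy_mm']:>7.3f} {row['delta_bar_mm']:>8.3f} "
                f"{row['delta_bar_lo_mm']:>6.3f} {row['delta_bar_hi_mm']:>6.3f} "
                f"{row['drop_at_delta_bar_pct']:>7.2f}"
            )
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def to_json(self, path: str | Path, tolerance_mm: float | None = None) -> None:
        """Write the calibration result file (detectors, thresholds, metadata)."""
        thresholds = self.thresholds(tolerance_mm) if self.model.d0_bar else {}
        payload = {
            "schema": "pbsqa-calibration/1",
            "tolerance_mm": tolerance_mm or self.model.tolerance_mm,
            "detectors": {
                det.value: {
                    **asdict(cal),
                    "n_days": self.n_days[det],
                    "d0_bar": self.model.d0_bar.get(det, {}),
                    "thresholds": {
                        cfg: asdict(ts) | {"detector_id": det.value}
                        for cfg, ts in thresholds.get(det, {}).items()
                    },
                }
                for det, cal in self.calibrations.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def load_calibration(
    path: str | Path,
) -> dict[DetectorId, tuple[RiceCalibration, dict[str, float]]]:
    """Read per-detector Rice calibrations and D0_bar values back from a
    calibration result file."""
    raw = json.loads(Path(path).read_text())
    if raw.get("schema") != "pbsqa-calibration/1":
        raise ValueError(f"unrecognized calibration file schema: {raw.get('schema')}")
    out = {}
    fields = {f for f in RiceCalibration.__dataclass_fields__}
    for det, entry in raw["detectors"].items():
        cal = RiceCalibration(**{k: entry[k] for k in fields})
        out[DetectorId(det)] = (cal, dict(entry.get("d0_bar", {})))
    return out


def load_thresholds(path: str | Path) -> dict[DetectorId, dict[str, ThresholdSet]]:
    """Read per-detector thresholds back from a calibration result file."""
    raw = json.loads(Path(path).read_text())
    if raw.get("schema") != "pbsqa-calibration/1":
        raise ValueError(f"unrecognized calibration file schema: {raw.get('schema')}")
    out: dict[DetectorId, dict[str, ThresholdSet]] = {}
    for det, entry in raw["detectors"].items():
        det_id = DetectorId(det)
        out[det_id] = {}
        for cfg, ts in entry.get("thresholds", {}).items():
            out[det_id][cfg] = ThresholdSet(
                detector_id=det_id,
                config_label=cfg,
                d0_bar=ts["d0_bar"],
                tolerance_mm=ts["tolerance_mm"],
                threshold=ts["threshold"],
                threshold_lo=ts["threshold_lo"],
                threshold_hi=ts["threshold_hi"],
            )
    return out
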