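"""Daily-QA evaluation engine: corrections, verdicts and trends.

Consumes the documented daily-export CSV dialect (net counts with
environmental metadata), applies the temperature-pressure correction for
vented ionization chambers, evaluates the four QA items (output constancy,
range constancy, spot positioning, spot centering) against calibrated
thresholds, and maintains an append-only trend store with summary
statistics (coefficient of variation, min-max deviations).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import ThresholdSet
from .geometry import (
    OUTPUT_CHAMBERS,
    RANGE_PAIRS,
    DetectorGeometry,
    DetectorId,
    DetectorRole,
)
from .range_output_qa import (
    OutputBaseline,
    OutputCheck,
    RangeTolerance,
    RangeVerdict,
    check_output,
    check_range,
    compute_ratio,
)

REF_TEMPERATURE_C = 20.0
REF_PRESSURE_KPA = 101.325

#: Physical plausibility limits for the environmental sensors.
TEMPERATURE_RANGE_C = (10.0, 40.0)
PRESSURE_RANGE_KPA = (80.0, 110.0)


class RecordValidationError(ValueError):
    """Raw export record outside physical plausibility limits."""


class IncompleteDayError(ValueError):
    """A required detector is missing from the day's export."""


class DuplicateDayError(ValueError):
    """The (date, gantry, config) key already exists in the trend store."""


@dataclass(frozen=True)
class RawExportRecord:
    """One detector's raw export row for one day."""

    date: dt.date
    detector_id: DetectorId
    raw_counts: float
    background_counts: float
    irradiation_time_s: float
    temperature_c: float
    pressure_kpa: float

    def __post_init__(self) -> None:
        if self.raw_counts < self.background_counts:
            raise RecordValidationError(
                f"{self.detector_id.value}: raw counts {self.raw_counts} below "
                f"background {self.background_counts}"
            )
        if not (self.irradiation_time_s > 0):
            raise RecordValidationError("irradiation time must be positive")
        t_lo, t_hi = TEMPERATURE_RANGE_C
        p_lo, p_hi = PRESSURE_RANGE_KPA
        if not (t_lo <= self.temperature_c <= t_hi):
            raise RecordValidationError(
                f"temperature {self.temperature_c} degC outside [{t_lo}, {t_hi}]"
            )
        if not (p_lo <= self.pressure_kpa <= p_hi):
            raise RecordValidationError(
                f"pressure {self.pressure_kpa} kPa outside [{p_lo}, {p_hi}]"
            )


def k_tp(temperature_c: float, pressure_kpa: float,
         ref_temp: float = REF_TEMPERATURE_C,
         ref_pressure: float = REF_PRESSURE_KPA) -> float:
    """Temperature-pressure correction factor for a vented ion chamber."""
    return ((273.15 + temperature_c) / (273.15 + ref_temp)) * (ref_pressure / pressure_kpa)


def correct_signal(
    r: RawExportRecord,
    geometry: DetectorGeometry | None = None,
    ref_temp: float = REF_TEMPERATURE_C,
    ref_pressure: float = REF_PRESSURE_KPA,
) -> float:
    """Net counts with the k_TP air-density correction.

    Vented ionization chambers are corrected by
    k_TP = ((273.15+T)/(273.15+T_ref)) * (P_ref/P); solid-state diodes are
    insensitive to air density and get k_TP = 1.  A record with net counts
    of zero is a no-beam measurement and returns 0.0.
    """
    geometry = geometry or DetectorGeometry.default()
    net = r.raw_counts - r.background_counts
    role = geometry[r.detector_id].role
    if role is DetectorRole.POSITIONING_DIODE:
        return net
    return net * k_tp(r.temperature_c, r.pressure_kpa, ref_temp, ref_pressure)


@dataclass(frozen=True)
class PositionCheck:
    detector_id: DetectorId
    signal: float
    threshold: float
    threshold_hi: float
    passed: bool
    within_one_sigma: bool  # advisory: signal also clears the upper band


@dataclass(frozen=True)
class RangeCheck:
    block_label: str
    ratio: float
    reference_ratio: float
    verdict: RangeVerdict


@dataclass(frozen=True)
class DailyQARecord:
    """All verdicts for one day, one gantry, one configuration."""

    date: dt.date
    gantry: str
    config_label: str
    signals: Mapping[DetectorId, float]
    positioning: Mapping[DetectorId, PositionCheck]
    centering: PositionCheck
    range_checks: Mapping[str, RangeCheck]
    output_checks: Mapping[DetectorId, OutputCheck]

    @property
    def overall_pass(self) -> bool:
        return (
            all(c.passed for c in self.positioning.values())
            and self.centering.passed
            and all(c.verdict is RangeVerdict.PASS for c in self.range_checks.values())
            and all(c.verdict.value == "pass" for c in self.output_checks.values())
        )


def _position_check(det: DetectorId, signal: float, ts: ThresholdSet) -> PositionCheck:
    return PositionCheck(
        detector_id=det,
        signal=signal,
        threshold=ts.threshold,
        threshold_hi=ts.threshold_hi,
        passed=signal >= ts.threshold,
        within_one_sigma=signal >= ts.threshold_hi,
    )


def evaluate_day(
    date: dt.date,
    gantry: str,
    config_label: str,
    signals: Mapping[DetectorId, float],
    thresholds: Mapping[DetectorId, Mapping[str, ThresholdSet]],
    range_tolerances: Mapping[str, RangeTolerance],
    output_baselines: Mapping[DetectorId, OutputBaseline],
) -> DailyQARecord:
    """Evaluate one day's corrected signals against all calibrated limits.

    Positioning and centering pass when the signal meets the mean-based
    threshold; clearing the 1-sigma upper band as well is annotated but
    never blocking (the clinical decision rests on the mean threshold).
    """
    required = set(DetectorId)
    missing = sorted(d.value for d in required - set(signals))
    if missing:
        raise IncompleteDayError(f"{date} {gantry}/{config_label}: missing detectors {missing}")

    positioning = {}
    for det in (DetectorId.T2, DetectorId.L2, DetectorId.R2, DetectorId.B2):
        ts = thresholds[det][config_label]
        positioning[det] = _position_check(det, signals[det], ts)
    centering = _position_check(
        DetectorId.CAX, signals[DetectorId.CAX],
        thresholds[DetectorId.CAX][config_label],
    )

    range_checks = {}
    for block, (distal, plateau) in RANGE_PAIRS.items():
        ratio = compute_ratio(signals[distal], signals[plateau])
        tol = range_tolerances[block]
        range_checks[block] = RangeCheck(
            block_label=block,
            ratio=ratio,
            reference_ratio=tol.reference_ratio,
            verdict=check_range(ratio, tol),
        )

    output_checks = {
        det: check_output(signals[det], output_baselines[det])
        for det in OUTPUT_CHAMBERS
    }

    return DailyQARecord(
        date=date,
        gantry=gantry,
        config_label=config_label,
        signals=dict(signals),
        positioning=positioning,
        centering=centering,
        range_checks=range_checks,
        output_checks=output_checks,
    )


@dataclass(frozen=True)
class TrendSummary:
    detector_id: DetectorId
    config_label: str
    n_days: int
    cov_percent: float
    min_dev_percent: float
    max_dev_percent: float


def summarize_trend(records: Sequence[DailyQARecord]) -> list[TrendSummary]:
    """Per-(detector, config) signal stability over a series of days.

    COV is 100*std/mean (sample standard deviation); min/max deviations
    are percent excursions of the extreme signals from the mean.
    """
    frames = []
    for rec in records:
        for det, sig in rec.signals.items():
            frames.append((det.value, rec.config_label, sig))
    df = pd.DataFrame(frames, columns=["detector_id", "config", "signal"])
    out = []
    for (det, cfg), grp in df.groupby(["detector_id", "config"], sort=True):
        if len(grp) < 2:
            continue
        vals = grp["signal"].to_numpy()
        mean = vals.mean()
        out.append(TrendSummary(
            detector_id=DetectorId(det),
            config_label=cfg,
            n_days=len(vals),
            cov_percent=100.0 * vals.std(ddof=1) / mean,
            min_dev_percent=100.0 * (vals.min() - mean) / mean,
            max_dev_percent=100.0 * (vals.max() - mean) / mean,
        ))
    return out


# ---------------------------------------------------------------------------
# trend store
# ---------------------------------------------------------------------------

TREND_COLUMNS = [
    "date", "gantry", "config", "detector_id", "check", "signal",
    "threshold", "threshold_hi", "ratio", "reference_ratio",
    "deviation_percent", "verdict",
]


def record_to_rows(rec: DailyQARecord) -> pd.DataFrame:
    """Flatten one day's record into trend-store rows (one per check)."""
    rows = []
    base = {"date": rec.date.isoformat(), "gantry": rec.gantry, "config": rec.config_label}
    for det, chk in rec.positioning.items():
        rows.append(base | {
            "detector_id": det.value, "check": "positioning",
            "signal": chk.signal, "threshold": chk.threshold,
            "threshold_hi": chk.threshold_hi, "ratio": "", "reference_ratio": "",
            "deviation_percent": "",
            "verdict": "pass" if chk.passed else "fail",
        })
    chk = rec.centering
    rows.append(base | {
        "detector_id": chk.detector_id.value, "check": "centering",
        "signal": chk.signal, "threshold": chk.threshold,
        "threshold_hi": chk.threshold_hi, "ratio": "", "reference_ratio": "",
        "deviation_percent": "", "verdict": "pass" if chk.passed else "fail",
    })
    for block, rchk in rec.range_checks.items():
        rows.append(base | {
            "detector_id": block, "check": "range", "signal": "",
            "threshold": "", "threshold_hi": "",
            "ratio": rchk.ratio, "reference_ratio": rchk.reference_ratio,
            "deviation_percent": "", "verdict": rchk.verdict.value,
        })
    for det, ochk in rec.output_checks.items():
        rows.append(base | {
            "detector_id": det.value, "check": "output",
            "signal": rec.signals[det], "threshold": "", "threshold_hi": "",
            "ratio": "", "reference_ratio": "",
            "deviation_percent": ochk.deviation_percent,
            "verdict": ochk.verdict.value,
        })
    return pd.DataFrame(rows, columns=TREND_COLUMNS)


class TrendStore:
    """Append-only per-gantry CSV database of daily QA results."""

    def __init__(self, path: str | Path) -> None:
        self.path = Path(path)

    def read(self) -> pd.DataFrame:
        if not self.path.exists():
            return pd.DataFrame(columns=TREND_COLUMNS)
        return pd.read_csv(self.path, dtype=str).fillna("")

    def append(self, rec: DailyQARecord) -> None:
        existing = self.read()
        key = (rec.date.isoformat(), rec.gantry, rec.config_label)
        if not existing.empty:
            dup = (
                (existing["date"] == key[0])
                & (existing["gantry"] == key[1])
                & (existing["config"] == key[2])
            )
            if dup.any():
                raise DuplicateDayError(
                    f"day {key[0]} for {key[1]}/{key[2]} already stored"
                )
        rows = record_to_rows(rec)
        header = not self.path.exists()
        rows.to_csv(self.path, mode="a", header=header, index=False)

    def summarize(self) -> pd.DataFrame:
        """COV and min/max percent deviations per (detector, config, check)."""
        df = self.read()
        if df.empty:
            return pd.DataFrame()
        sig = df[df["check"].isin(["positioning", "centering", "output"])].copy()
        sig["signal"] = sig["signal"].astype(float)
        out = []
        for (det, cfg, check), grp in sig.groupby(["detector_id", "config", "check"]):
            vals = grp["signal"].to_numpy()
            if len(vals) < 2:
                continue
            mean = vals.mean()
            out.append({
                "detector_id": det, "config": cfg, "check": check,
                "n_days": len(vals),
                "cov_percent": 100.0 * vals.std(ddof=1) / mean,
                "min_dev_percent": 100.0 * (vals.min() - mean) / mean,
                "max_dev_percent": 100.0 * (vals.max() - mean) / mean,
            })
        return pd.DataFrame(out)


def plot_trend(store: TrendStore, out_path: str | Path) -> None:
    """Signal-vs-date trend plot per detector with threshold lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = store.read()
    pos = df[df["check"].isin(["positioning", "centering"])].copy()
    if pos.empty:
        raise ValueError("trend store holds no positioning/centering rows")
    pos["signal"] = pos["signal"].astype(float)
    pos["threshold"] = pos["threshold"].astype(float)
    dets = sorted(pos["detector_id"].unique())
    fig, axes = plt.subplots(len(dets), 1, figsize=(8, 2.2 * len(dets)), sharex=True)
    axes = np.atleast_1d(axes)
    for ax, det in zip(axes, dets):
        sub = pos[pos["detector_id"] == det]
        for cfg, grp in sub.groupby("config"):
            ax.plot(pd.to_datetime(grp["date"]), grp["signal"], "o", ms=3, label=cfg)
            ax.axhline(grp["threshold"].iloc[-1], ls="-", lw=0.8, color="k")
        ax.set_ylabel(det)
        ax.legend(fontsize=7)
    axes[-1].set_xlabel("date")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
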