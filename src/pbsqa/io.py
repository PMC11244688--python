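"""Documented CSV dialects for calibration, daily-export and range data.

The vendor's proprietary export format has no public specification, so
the package defines open CSV dialects carrying the same fields.  Each
file starts with a versioned comment header (``# pbsqa <kind> v1``); the
readers validate columns strictly and the writers always emit the header.

Dialects
--------
calibration-signals
    date, detector_id, position_label (center|+x|-x|+y|-y),
    corrected_signal, config - exactly five labelled rows per detector
    per day.
daily-export
    date, gantry, config, detector_id, raw_counts, background_counts,
    irradiation_time_s, temperature_c, pressure_kpa.
range-calibration
    gantry, config, block_label, added_wet_mm, ratio.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import pandas as pd

from .geometry import DetectorId
from .qa_engine import RawExportRecord
from .range_output_qa import RangeCalibrationCurve

_HEADERS = {
    "calibration-signals": "# pbsqa calibration-signals v1",
    "daily-export": "# pbsqa daily-export v1",
    "range-calibration": "# pbsqa range-calibration v1",
}

_COLUMNS = {
    "calibration-signals": ["date", "detector_id", "position_label",
                            "corrected_signal", "config"],
    "daily-export": ["date", "gantry", "config", "detector_id", "raw_counts",
                     "background_counts", "irradiation_time_s",
                     "temperature_c", "pressure_kpa"],
    "range-calibration": ["gantry", "config", "block_label", "added_wet_mm",
                          "ratio"],
}

POSITION_LABELS = {"center", "+x", "-x", "+y", "-y"}


def _write(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    cols = _COLUMNS[kind]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{kind}: missing columns {sorted(missing)}")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_HEADERS[kind] + "\n")
        df[cols].to_csv(fh, index=False)


def _read(path: str | Path, kind: str) -> pd.DataFrame:
    path = Path(path)
    first = path.open().readline().strip()
    if first != _HEADERS[kind]:
        raise ValueError(
            f"{path}: expected header '{_HEADERS[kind]}', found '{first}'"
        )
    df = pd.read_csv(path, comment="#")
    missing = set(_COLUMNS[kind]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_calibration_signals(df: pd.DataFrame, path: str | Path) -> None:
    _write(df, path, "calibration-signals")


def read_calibration_signals(path: str | Path) -> pd.DataFrame:
    """Read and validate a five-position calibration signal table."""
    df = _read(path, "calibration-signals")
    bad = set(df["position_label"]) - POSITION_LABELS
    if bad:
        raise ValueError(f"unknown position labels {sorted(bad)}")
    counts = df.groupby(["date", "detector_id"])["position_label"].agg(
        lambda s: (len(s), len(set(s)))
    )
    offenders = [k for k, (n, uniq) in counts.items() if n != 5 or uniq != 5]
    if offenders:
        raise ValueError(
            f"each detector-day needs exactly the five position labels; "
            f"offending keys: {offenders[:5]}"
        )
    return df


def write_daily_exports(df: pd.DataFrame, path: str | Path) -> None:
    _write(df, path, "daily-export")


def read_daily_exports(path: str | Path) -> pd.DataFrame:
    return _read(path, "daily-export")


def export_records(df: pd.DataFrame) -> list[RawExportRecord]:
    """Daily-export rows as validated records (raises on implausible T/P)."""
    return [
        RawExportRecord(
            date=dt.date.fromisoformat(str(row["date"])),
            detector_id=DetectorId(row["detector_id"]),
            raw_counts=float(row["raw_counts"]),
            background_counts=float(row["background_counts"]),
            irradiation_time_s=float(row["irradiation_time_s"]),
            temperature_c=float(row["temperature_c"]),
            pressure_kpa=float(row["pressure_kpa"]),
        )
        for _, row in df.iterrows()
    ]


def write_range_calibration(curves: list[RangeCalibrationCurve],
                            gantry: str, path: str | Path) -> None:
    rows = [
        {"gantry": gantry, "config": c.config_label, "block_label": c.block_label,
         "added_wet_mm": w, "ratio": r}
        for c in curves for w, r in c.points
    ]
    _write(pd.DataFrame(rows), path, "range-calibration")


def read_range_calibration(path: str | Path) -> dict[tuple[str, str, str], RangeCalibrationCurve]:
    """Curves keyed by (gantry, config, block_label)."""
    df = _read(path, "range-calibration")
    out = {}
    for (gantry, cfg, block), grp in df.groupby(["gantry", "config", "block_label"]):
        grp = grp.sort_values("added_wet_mm")
        out[(gantry, cfg, block)] = RangeCalibrationCurve(
            block_label=block,
            config_label=cfg,
            points=tuple(zip(grp["added_wet_mm"].astype(float),
                             grp["ratio"].astype(float))),
        )
    return out
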