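"""Readers and writers for the package's plain-text formats.

Schemas (all CSV with a header row):

* cohort:       subject_id, sex, <feature columns...>, event (0/1/true/false)
* RR series:    beat_time_s, rr_ms
* ECG:          time_s, mv  (sampling rate inferred from the time column)
* features:     subject_id, vlf, lf, hf, tp, ln_lf, ln_hf, lf_hf, sdnn, rmssd
* predictions:  subject_id, stratum, prediction, event

Validation errors name the offending row and field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .literature import MLRD
from .signals import ECGRecord, HRVFeatures, RRSeries

_TRUE = {"1", "true", "yes", "t"}
_FALSE = {"0", "false", "no", "f"}


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Cohort table with a validated boolean event column."""
    df = pd.read_csv(path)
    _require_columns(df, ("subject_id", "event"), path)
    events = []
    for i, raw in enumerate(df["event"]):
        token = str(raw).strip().lower()
        if token in _TRUE:
            events.append(True)
        elif token in _FALSE:
            events.append(False)
        else:
            raise SchemaError(
                f"{path}: row {i + 2}: event value {raw!r} is not boolean"
            )
    df["event"] = events
    if "sex" not in df.columns:
        df["sex"] = "unknown"
    return df


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    out = cohort.copy()
    out["event"] = out["event"].astype(bool).astype(int)
    out.to_csv(path, index=False)


def read_rr_csv(path: str | Path, start_clock_s: float = 8 * 3600.0) -> RRSeries:
    df = pd.read_csv(path)
    _require_columns(df, ("beat_time_s", "rr_ms"), path)
    times_s = df["beat_time_s"].to_numpy(dtype=float)
    rr_ms = df["rr_ms"].to_numpy(dtype=float)
    valid = (
        df["valid"].to_numpy(dtype=bool)
        if "valid" in df.columns
        else np.ones(rr_ms.size, dtype=bool)
    )
    # beat_time_s marks the closing beat of each interval
    beats_ms = np.concatenate(
        [[times_s[0] * 1000.0 - rr_ms[0]], times_s * 1000.0]
    )
    return RRSeries(beats_ms, rr_ms, valid, start_clock_s=start_clock_s)


def write_rr_csv(rr: RRSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "beat_time_s": rr.beat_times_ms[1:] / 1000.0,
            "rr_ms": rr.intervals_ms,
            "valid": rr.valid.astype(int),
        }
    ).to_csv(path, index=False)


def read_ecg_csv(path: str | Path, start_clock_s: float = 8 * 3600.0) -> ECGRecord:
    df = pd.read_csv(path)
    _require_columns(df, ("time_s", "mv"), path)
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise SchemaError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.max(dt) - np.min(dt) > 1e-6 + 1e-4 * np.median(dt):
        raise SchemaError(f"{path}: time column is not uniformly sampled")
    fs = 1.0 / float(np.median(dt))
    return ECGRecord(df["mv"].to_numpy(dtype=float), fs=fs, start_clock_s=start_clock_s)


def write_ecg_csv(ecg: ECGRecord, path: str | Path) -> None:
    t = np.arange(ecg.samples.size) / ecg.fs
    pd.DataFrame({"time_s": t, "mv": ecg.samples}).to_csv(path, index=False)


def write_features_csv(features: dict[str, HRVFeatures], path: str | Path) -> None:
    rows = [{"subject_id": sid, **f.as_dict()} for sid, f in features.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("subject_id",), path)
    return df


def write_mlrd_json(mlrd: MLRD, path: str | Path) -> None:
    Path(path).write_text(json.dumps(mlrd.to_dict(), indent=2))


def read_mlrd_json(path: str | Path) -> MLRD:
    return MLRD.from_dict(json.loads(Path(path).read_text()))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str))
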