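"""Reading streams and task logs, second-level task annotation, and the
HR-confidence quality filter.

Every second of a stream is assigned the task whose half-open interval
[start, end) contains it; seconds covered by no task (EVA prep, transit
home, ...) are dropped before analysis.  The chest strap reports a 0–100%
HR-confidence rating of the whole system, so the quality filter removes the
entire record — heart rate, respiration rate and HRV together — whenever
confidence falls below the threshold (default 50%).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import TASK_CODES
from .errors import DataError, FormatError
from .synthetic_data import LOG_COLUMNS, MANIFEST_COLUMNS, STREAM_COLUMNS

logger = logging.getLogger(__name__)

LABELED_COLUMNS = [
    "participant",
    "deployment",
    "eva",
    "time_s",
    "task_code",
    "hr_bpm",
    "rr_brpm",
    "hrv_ms",
    "hr_confidence",
]


def _check_header(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


def read_stream(path: str | Path) -> pd.DataFrame:
    """Parse one 1 Hz stream CSV.

    Empty HRV fields become NaN.  Raises :class:`FormatError` on a bad
    header and :class:`DataError` if time is not strictly increasing
    (duplicated seconds are rejected; gaps are allowed).
    """
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(df, STREAM_COLUMNS, path)
    df = df[STREAM_COLUMNS].copy()
    df["time_s"] = df["time_s"].astype(np.int64)
    for col in ("hr_bpm", "rr_brpm", "hrv_ms", "hr_confidence"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    t = df["time_s"].to_numpy()
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        row = int(bad[0]) + 1
        raise DataError(
            f"{path}: non-monotone time_s at row {row} (time {t[row]} after {t[row - 1]})"
        )
    return df


def read_task_log(path: str | Path) -> pd.DataFrame:
    """Parse a task-log CSV of transition rows (``time_s, participant,
    task_code, note``)."""
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    _check_header(df, LOG_COLUMNS[:3], path)
    df = df.copy()
    df["time_s"] = df["time_s"].astype(np.int64)
    unknown = set(df["task_code"]) - set(TASK_CODES)
    if unknown:
        raise DataError(f"{path}: unknown task code(s) {sorted(unknown)}")
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: transition times must be strictly increasing")
    return df


def intervals_from_transitions(
    transitions: pd.DataFrame, end_s: float | None = None
) -> pd.DataFrame:
    """Turn transition rows into half-open [start, end) intervals; the last
    interval extends to ``end_s`` (default: unbounded)."""
    starts = transitions["time_s"].to_numpy(dtype=float)
    ends = np.append(starts[1:], np.inf if end_s is None else float(end_s))
    return pd.DataFrame(
        {"start_s": starts, "end_s": ends, "task_code": transitions["task_code"].to_numpy()}
    )


def annotate(stream: pd.DataFrame, intervals: pd.DataFrame) -> pd.DataFrame:
    """Label each record with the task whose [start, end) contains its
    time; uncovered records get a missing label.  Pure in (time_s, log).

    Raises :class:`DataError` if intervals overlap.
    """
    if len(intervals) == 0:
        out = stream.copy()
        out["task_code"] = pd.Series([pd.NA] * len(out), index=out.index, dtype="object")
        return out
    iv = intervals.sort_values("start_s", kind="stable").reset_index(drop=True)
    starts = iv["start_s"].to_numpy(dtype=float)
    ends = iv["end_s"].to_numpy(dtype=float)
    bad = np.nonzero(starts[1:] < ends[:-1])[0]
    if bad.size:
        i = int(bad[0])
        raise DataError(
            "overlapping task intervals: "
            f"[{starts[i]}, {ends[i]}) {iv['task_code'][i]} and "
            f"[{starts[i + 1]}, {ends[i + 1]}) {iv['task_code'][i + 1]}"
        )
    out = stream.copy()
    t = out["time_s"].to_numpy(dtype=float)
    idx = np.searchsorted(starts, t, side="right") - 1
    idx_clipped = np.clip(idx, 0, len(iv) - 1)
    covered = (idx >= 0) & (t < ends[idx_clipped])
    labels = np.where(covered, iv["task_code"].to_numpy()[idx_clipped], None)
    out["task_code"] = pd.Series(labels, index=out.index, dtype="object")
    return out


def drop_untasked(labeled: pd.DataFrame) -> pd.DataFrame:
    """Keep only records carrying a task label, order preserved."""
    out = labeled[labeled["task_code"].notna()].copy()
    if out.empty and not labeled.empty:
        logger.warning("all %d records were outside task intervals", len(labeled))
    return out


def filter_confidence(labeled: pd.DataFrame, threshold_pct: float = 50.0) -> pd.DataFrame:
    """Drop whole records whose HR confidence is strictly below the
    threshold; the boundary value is kept.  Applies to HR, RR and HRV
    jointly, as the confidence rates the whole system."""
    if not (0.0 <= threshold_pct <= 100.0):
        raise ValueError(f"threshold_pct must lie in [0, 100], got {threshold_pct}")
    return labeled[labeled["hr_confidence"] >= threshold_pct].copy()


def ingest_manifest(
    manifest_path: str | Path, hr_confidence_min: float = 50.0
) -> pd.DataFrame:
    """Run the full ingest over every stream a manifest lists.

    Reads each (stream, task-log) pair, applies the optional per-file
    ``clock_offset_s`` to log times, annotates, drops untasked seconds and
    applies the confidence filter.  Returns one tidy labeled frame with
    columns ``participant, deployment, eva, time_s, task_code, hr_bpm,
    rr_brpm, hrv_ms, hr_confidence``.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    _check_header(manifest, MANIFEST_COLUMNS[:5], manifest_path)
    if "clock_offset_s" not in manifest.columns:
        manifest["clock_offset_s"] = 0
    root = manifest_path.parent
    frames = []
    for row in manifest.itertuples(index=False):
        stream = read_stream(root / row.stream_path)
        log = read_task_log(root / row.log_path)
        log = log.assign(time_s=log["time_s"] + int(row.clock_offset_s))
        labeled = annotate(stream, intervals_from_transitions(log))
        labeled = drop_untasked(labeled)
        labeled = filter_confidence(labeled, hr_confidence_min)
        labeled.insert(0, "eva", row.eva)
        labeled.insert(0, "deployment", row.deployment)
        labeled.insert(0, "participant", row.participant)
        frames.append(labeled)
    if not frames:
        return pd.DataFrame(columns=LABELED_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out[LABELED_COLUMNS]
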