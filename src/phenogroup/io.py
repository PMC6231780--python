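"""CSV dialects for traces, weekly scores, feature tables and results.

Traces: ``participant_id,timestamp,latitude,longitude,accuracy_m`` with
ISO-8601 timestamps carrying a UTC offset.  Scores:
``participant_id,week_start,qids`` where ``week_start`` is an ISO Monday
date and scores lie in [0, 27].  Feature tables mirror the weekly feature
vector columns.  Malformed rows are dropped and counted, never fatal.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .utils import FEATURE_NAMES

logger = logging.getLogger("phenogroup")

TRACE_HEADER = ["participant_id", "timestamp", "latitude", "longitude", "accuracy_m"]
SCORE_HEADER = ["participant_id", "week_start", "qids"]

__all__ = [
    "read_traces",
    "write_traces",
    "read_scores",
    "write_scores",
    "read_features",
    "write_features",
    "join_features_scores",
]


class FormatError(ValueError):
    """A required column is missing from an input CSV."""


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


def read_traces(path) -> dict:
    """Parse a trace CSV into per-participant time-sorted frames.

    Rows with unparsable timestamps, out-of-range coordinates or negative
    accuracy are rejected and logged.
    """
    df = pd.read_csv(path)
    if df.empty and not df.columns.size:
        return {}
    _require_columns(df, TRACE_HEADER, path)
    n_raw = len(df)
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    for col in ("latitude", "longitude", "accuracy_m"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = (
        df["timestamp"].notna()
        & df["latitude"].between(-90, 90)
        & df["longitude"].between(-180, 180)
        & (df["accuracy_m"] >= 0)
    )
    rejected = int(n_raw - ok.sum())
    if rejected:
        logger.warning("%s: rejected %d malformed trace row(s)", path, rejected)
    df = df[ok]
    out = {}
    for pid, sub in df.groupby("participant_id"):
        out[str(pid)] = (
            sub[["timestamp", "latitude", "longitude", "accuracy_m"]]
            .sort_values("timestamp", kind="mergesort")
            .reset_index(drop=True)
        )
    return out


def write_traces(traces: dict, path) -> None:
    frames = []
    for pid, df in traces.items():
        f = df.copy()
        f.insert(0, "participant_id", pid)
        f["timestamp"] = pd.to_datetime(f["timestamp"]).map(lambda t: t.isoformat())
        frames.append(f)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRACE_HEADER)
    out.to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    """Parse weekly scores; out-of-range values and non-Monday dates are
    rejected with a log entry."""
    df = pd.read_csv(path)
    _require_columns(df, SCORE_HEADER, path)
    n_raw = len(df)
    df["week_start"] = pd.to_datetime(df["week_start"], errors="coerce")
    df["qids"] = pd.to_numeric(df["qids"], errors="coerce")
    ok = df["week_start"].notna() & df["qids"].between(0, 27) & (df["week_start"].dt.dayofweek == 0)
    rejected = int(n_raw - ok.sum())
    if rejected:
        logger.warning("%s: rejected %d malformed score row(s)", path, rejected)
    df = df[ok].copy()
    df["week_start"] = df["week_start"].dt.date
    df["participant_id"] = df["participant_id"].astype(str)
    return df.reset_index(drop=True)


def write_scores(scores: pd.DataFrame, path) -> None:
    scores[SCORE_HEADER].to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["participant_id", "week_start", *FEATURE_NAMES], path)
    df["week_start"] = pd.to_datetime(df["week_start"]).dt.date
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def write_features(features: pd.DataFrame, path) -> None:
    cols = ["participant_id", "week_start", *FEATURE_NAMES]
    if "coverage" in features.columns:
        cols.append("coverage")
    features[cols].to_csv(path, index=False)


def join_features_scores(features: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Inner-join weekly features with scores on (participant, Monday).

    Weeks lacking either a feature vector or a score are dropped; rows with
    any missing feature value are also dropped so the regressions see
    complete vectors only.
    """
    merged = features.merge(scores, on=["participant_id", "week_start"], how="inner")
    merged = merged.dropna(subset=FEATURE_NAMES)
    return merged.sort_values(["participant_id", "week_start"]).reset_index(drop=True)
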