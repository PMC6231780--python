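"""Weekly behavioral features from raw GPS traces.

The pipeline is: accuracy filtering and de-duplication, stay-point
segmentation (stationary vs transitioning), greedy agglomerative clustering
of stay centroids into places, home identification from night-time dwell,
then per-calendar-week (Monday to Sunday, local time) computation of the 10
features: log location variance, number of places visited, entropy and
normalized entropy of dwell proportions, home stay %, transition time %,
total distance traveled, and three circadian-movement powers (raw
coordinates, per-week z-scored coordinates, and distance from home).

Traces are tables with columns ``timestamp`` (timezone-aware),
``latitude``, ``longitude``, ``accuracy_m``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .utils import FEATURE_NAMES, haversine_km

__all__ = [
    "GeoSample",
    "StationarySegment",
    "FeatureConfig",
    "HomeUndeterminableError",
    "preprocess_trace",
    "segment_stationary",
    "cluster_locations",
    "identify_home",
    "compute_entropy",
    "compute_diurnal_power",
    "compute_weekly_features",
    "extract_features",
]

TRACE_COLUMNS = ["timestamp", "latitude", "longitude", "accuracy_m"]

_LOG_VAR_EPS = 1e-12  # keeps location variance finite for constant traces


class GeoSample(NamedTuple):
    """One timestamped GPS fix."""

    timestamp: pd.Timestamp
    latitude: float
    longitude: float
    accuracy_m: float


class HomeUndeterminableError(ValueError):
    """Raised when no night-time stationary data exist to anchor 'home'."""


@dataclass
class StationarySegment:
    """A maximal stationary interval with its centroid and assigned place."""

    start: pd.Timestamp
    end: pd.Timestamp
    centroid: tuple
    cluster_id: int | None = None

    @property
    def dwell_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass(frozen=True)
class FeatureConfig:
    """Thresholds of the preprocessing and feature layer (all exposed)."""

    max_accuracy_m: float = 100.0
    speed_threshold_kmh: float = 1.0
    min_duration_min: float = 5.0
    cluster_distance_m: float = 200.0
    min_coverage: float = 0.5
    night_window: tuple = (0, 6)
    period_grid_h: tuple = tuple(np.round(np.arange(23.5, 24.51, 0.1), 2))


def _as_frame(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        return samples.reset_index(drop=True)
    return pd.DataFrame(samples, columns=TRACE_COLUMNS)


def preprocess_trace(samples, max_accuracy_m: float = 100.0) -> pd.DataFrame:
    """Sort by time, drop inaccurate fixes, resolve duplicate timestamps.

    Duplicate timestamps keep the most accurate fix; fixes with reported
    accuracy above ``max_accuracy_m`` are discarded.  An empty result is
    allowed.
    """
    df = _as_frame(samples)
    if df.empty:
        return df
    df = df[df["accuracy_m"] <= max_accuracy_m]
    df = df.sort_values(["timestamp", "accuracy_m"], kind="mergesort")
    df = df.drop_duplicates(subset="timestamp", keep="first")
    return df.reset_index(drop=True)


def segment_stationary(
    samples,
    speed_threshold_kmh: float = 1.0,
    min_duration_min: float = 5.0,
) -> tuple[list[StationarySegment], list[tuple]]:
    """Split a sorted trace into stationary segments and transition intervals.

    Consecutive fixes whose implied speed stays at or below the threshold
    belong to one candidate stay; candidates shorter than ``min_duration_min``
    are folded into the surrounding transition time, so every recorded
    instant is labeled exactly once.
    """
    df = _as_frame(samples)
    if df.empty:
        return [], []
    t_s = df["timestamp"].astype("int64").to_numpy() / 1e9
    if np.any(np.diff(t_s) < 0):
        raise ValueError("samples must be sorted by timestamp")
    lat = df["latitude"].to_numpy()
    lon = df["longitude"].to_numpy()

    n = len(df)
    if n == 1:
        return [], []
    dt_h = np.diff(t_s) / 3600.0
    dist = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        speed = np.where(dt_h > 0, dist / np.maximum(dt_h, 1e-12), np.inf)
    moving_gap = speed > speed_threshold_kmh

    segments: list[StationarySegment] = []
    run_start = 0
    for i in range(n - 1):
        if moving_gap[i]:
            _close_run(df, run_start, i, min_duration_min, segments)
            run_start = i + 1
    _close_run(df, run_start, n - 1, min_duration_min, segments)

    transitions: list[tuple] = []
    cursor = df["timestamp"].iloc[0]
    for seg in segments:
        if seg.start > cursor:
            transitions.append((cursor, seg.start))
        cursor = seg.end
    if df["timestamp"].iloc[-1] > cursor:
        transitions.append((cursor, df["timestamp"].iloc[-1]))
    return segments, transitions


def _close_run(df: pd.DataFrame, i0: int, i1: int, min_duration_min: float, out: list) -> None:
    if i1 <= i0:
        return
    start = df["timestamp"].iloc[i0]
    end = df["timestamp"].iloc[i1]
    if (end - start).total_seconds() >= min_duration_min * 60.0:
        lat = float(df["latitude"].iloc[i0 : i1 + 1].mean())
        lon = float(df["longitude"].iloc[i0 : i1 + 1].mean())
        out.append(StationarySegment(start, end, (lat, lon)))


def cluster_locations(
    segments: list[StationarySegment],
    distance_threshold_m: float = 200.0,
) -> dict:
    """Assign each segment to a place by greedy leader clustering.

    Segments are processed in descending dwell-time order; a segment joins
    the nearest existing leader within the great-circle threshold, else it
    founds a new cluster whose leader is its own centroid.  Final cluster ids
    are 0-based in descending total-dwell order; returns the dwell-weighted
    cluster centroids keyed by final id.
    """
    if not segments:
        return {}
    order = sorted(range(len(segments)), key=lambda i: (-segments[i].dwell_s, segments[i].start))
    leaders: list[tuple] = []
    raw_ids = {}
    for i in order:
        c = segments[i].centroid
        if leaders:
            d = np.array([haversine_km(c[0], c[1], L[0], L[1]) * 1000.0 for L in leaders])
            j = int(np.argmin(d))
            if d[j] <= distance_threshold_m:
                raw_ids[i] = j
                continue
        leaders.append(c)
        raw_ids[i] = len(leaders) - 1

    dwell: dict[int, float] = {}
    for i, g in raw_ids.items():
        dwell[g] = dwell.get(g, 0.0) + segments[i].dwell_s
    ranked = sorted(dwell, key=lambda g: (-dwell[g], g))
    remap = {g: r for r, g in enumerate(ranked)}
    for i, seg in enumerate(segments):
        seg.cluster_id = remap[raw_ids[i]]

    centroids: dict[int, tuple] = {}
    for g in set(remap.values()):
        members = [s for s in segments if s.cluster_id == g]
        w = np.array([s.dwell_s for s in members])
        w = w / w.sum() if w.sum() > 0 else np.full(len(members), 1.0 / len(members))
        centroids[g] = (
            float(sum(wi * s.centroid[0] for wi, s in zip(w, members))),
            float(sum(wi * s.centroid[1] for wi, s in zip(w, members))),
        )
    return centroids


def _night_overlap_s(seg: StationarySegment, night: tuple) -> float:
    """Seconds of a segment falling inside the daily night window (local)."""
    h0, h1 = night
    total = 0.0
    day = seg.start.normalize()
    while day <= seg.end:
        w0 = day + pd.Timedelta(hours=h0)
        w1 = day + pd.Timedelta(hours=h1)
        lo = max(seg.start, w0)
        hi = min(seg.end, w1)
        if hi > lo:
            total += (hi - lo).total_seconds()
        day += pd.Timedelta(days=1)
    return total


def identify_home(segments: list[StationarySegment], night_window: tuple = (0, 6)) -> int:
    """Home = the place with maximal dwell during the night window.

    Computed over the full trace (not per week) so distance-from-home is
    anchored to a single stable location; ties break to the lower cluster id.
    """
    if not segments or any(s.cluster_id is None for s in segments):
        raise ValueError("segments must be clustered first")
    dwell: dict[int, float] = {}
    for seg in segments:
        dwell[seg.cluster_id] = dwell.get(seg.cluster_id, 0.0) + _night_overlap_s(seg, night_window)
    if not dwell or max(dwell.values()) <= 0:
        raise HomeUndeterminableError("no stationary data in the night window")
    return min((g for g in dwell if dwell[g] == max(dwell.values())))


def compute_entropy(dwell_proportions) -> tuple[float, float]:
    """Shannon entropy (nats) of dwell proportions plus its normalized form.

    Normalization divides by log of the number of places; defined as 0 for a
    single place.
    """
    p = np.asarray(dwell_proportions, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("dwell proportions must be a simplex vector")
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log(nz)))
    n = p.size
    normalized = entropy / np.log(n) if n >= 2 else 0.0
    return entropy, float(normalized)


def compute_diurnal_power(times_h, values, period_grid_h=None) -> float:
    """Power of the best near-24 h sinusoid fitted by least squares.

    For each candidate period a sine/cosine pair plus intercept is fit to
    every coordinate dimension; the period minimizing the total residual is
    selected and its summed squared amplitude across dimensions returned.
    """
    t = np.asarray(times_h, dtype=float)
    V = np.asarray(values, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    if np.unique(t).size < 3:
        raise ValueError("need at least 3 distinct time points")
    periods = period_grid_h if period_grid_h is not None else FeatureConfig().period_grid_h
    best = (np.inf, 0.0)
    for T in periods:
        w = 2.0 * np.pi / T
        design = np.column_stack([np.ones_like(t), np.sin(w * t), np.cos(w * t)])
        coef, _, _, _ = np.linalg.lstsq(design, V, rcond=None)
        resid = V - design @ coef
        sse = float(np.sum(resid**2))
        power = float(np.sum(coef[1] ** 2 + coef[2] ** 2))
        if sse < best[0] - 1e-12:
            best = (sse, power)
    return best[1]


def _week_start(ts: pd.Timestamp) -> pd.Timestamp:
    return (ts - pd.Timedelta(days=int(ts.dayofweek))).normalize()


def compute_weekly_features(
    week_df: pd.DataFrame,
    segments: list[StationarySegment],
    cluster_centroids: dict,
    home_id: int | None,
    week_start: pd.Timestamp,
    config: FeatureConfig = FeatureConfig(),
) -> dict:
    """All 10 features for one Monday-to-Sunday week of samples.

    Percentages are of *recorded* time (first to last fix of the week), not
    calendar time; dwell proportions come from the week's clipped segment
    overlaps; the three circadian powers are computed on raw coordinates,
    per-week z-scored coordinates, and haversine distance from home.
    """
    lat = week_df["latitude"].to_numpy()
    lon = week_df["longitude"].to_numpy()
    ts = week_df["timestamp"]
    week_end = week_start + pd.Timedelta(days=7)

    recorded_s = (ts.iloc[-1] - ts.iloc[0]).total_seconds()
    dwell: dict[int, float] = {}
    for seg in segments:
        lo = max(seg.start, ts.iloc[0])
        hi = min(seg.end, ts.iloc[-1], week_end)
        if hi > lo:
            dwell[seg.cluster_id] = dwell.get(seg.cluster_id, 0.0) + (hi - lo).total_seconds()
    total_dwell = sum(dwell.values())
    transition_s = max(recorded_s - total_dwell, 0.0)

    out: dict = {"week_start": week_start.date()}
    out["location_variance"] = float(np.log(np.var(lat) + np.var(lon) + _LOG_VAR_EPS))
    out["n_clusters"] = int(len(dwell)) if dwell else 0
    if dwell:
        props = np.array(list(dwell.values())) / total_dwell
        ent, nent = compute_entropy(props)
    else:
        ent, nent = np.nan, np.nan
    out["entropy"] = ent
    out["normalized_entropy"] = nent
    if recorded_s > 0:
        out["home_stay"] = 100.0 * dwell.get(home_id, 0.0) / recorded_s if home_id is not None else np.nan
        out["transition_time"] = 100.0 * transition_s / recorded_s
    else:
        out["home_stay"] = np.nan
        out["transition_time"] = np.nan
    out["total_distance"] = float(np.sum(haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:]))) if len(lat) > 1 else 0.0

    hours = (ts - week_start).dt.total_seconds().to_numpy() / 3600.0
    coords = np.column_stack([lat, lon])
    try:
        out["diurnal_movement"] = compute_diurnal_power(hours, coords, config.period_grid_h)
        sd = coords.std(axis=0)
        z = (coords - coords.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        out["diurnal_movement_normalized"] = compute_diurnal_power(hours, z, config.period_grid_h)
        if home_id is not None and home_id in cluster_centroids:
            h = cluster_centroids[home_id]
            d_home = haversine_km(lat, lon, h[0], h[1])
            out["diurnal_movement_home_distance"] = compute_diurnal_power(hours, d_home, config.period_grid_h)
        else:
            out["diurnal_movement_home_distance"] = np.nan
    except ValueError:
        out["diurnal_movement"] = np.nan
        out["diurnal_movement_normalized"] = np.nan
        out["diurnal_movement_home_distance"] = np.nan

    hours_covered = ts.dt.floor("h").nunique()
    out["coverage"] = hours_covered / 168.0
    return out


def extract_features(trace, config: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """Full trace-to-weekly-features pipeline for one participant.

    Preprocesses the trace, segments it, clusters places, identifies home
    from night dwell (home-dependent features become missing if no night
    data exist), and returns one row per calendar week meeting the coverage
    minimum.
    """
    df = preprocess_trace(trace, config.max_accuracy_m)
    if df.empty:
        return pd.DataFrame(columns=["week_start", *FEATURE_NAMES, "coverage"])
    segments, _ = segment_stationary(df, config.speed_threshold_kmh, config.min_duration_min)
    centroids = cluster_locations(segments, config.cluster_distance_m)
    try:
        home_id = identify_home(segments, config.night_window) if segments else None
    except HomeUndeterminableError:
        home_id = None

    rows = []
    weeks = df["timestamp"].map(_week_start)
    for wk, wdf in df.groupby(weeks):
        if len(wdf) < 2:
            continue
        feats = compute_weekly_features(wdf.reset_index(drop=True), segments, centroids, home_id, wk, config)
        if feats["coverage"] >= config.min_coverage:
            rows.append(feats)
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out[["week_start", *FEATURE_NAMES, "coverage"]]
    return out
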