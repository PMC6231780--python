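"""Synthetic cohorts and GPS traces with known ground truth.

Two generators make the whole pipeline testable without any real study data:

* :func:`generate_grouped_cohort` draws weekly 10-feature vectors per
  participant and produces depression scores from a group-specific sparse
  linear model, returning the generating group labels alongside — the
  oracle for partition-recovery tests.
* :func:`generate_geolocation_trace` simulates raw GPS fixes following a
  daily anchor schedule (home/work/other) with constant-speed transitions
  and Gaussian position noise — the oracle for the feature-extraction layer.

Weeks are drawn independently per participant; real mobility data are
autocorrelated week to week, which these cohorts do not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .utils import FEATURE_NAMES, N_FEATURES, as_rng

__all__ = [
    "CohortConfig",
    "TraceConfig",
    "DEFAULT_FEATURE_DISTRIBUTIONS",
    "generate_grouped_cohort",
    "generate_geolocation_trace",
    "cohort_to_datasets",
    "two_group_orthogonal_config",
    "multi_group_config",
]

QIDS_MIN, QIDS_MAX = 0.0, 27.0

#: Per-feature (mean, sd, low, high) on the natural feature scale.  Means and
#: spreads are plausible for adults carrying a phone through a normal week;
#: truncation keeps every draw inside the feature's valid range.
DEFAULT_FEATURE_DISTRIBUTIONS: list[tuple[float, float, float, float]] = [
    (1.0, 2.5, -np.inf, np.inf),  # location_variance (log scale)
    (8.0, 4.0, 1.0, np.inf),      # n_clusters
    (1.2, 0.6, 0.0, np.inf),      # entropy (nats)
    (0.55, 0.2, 0.0, 1.0),        # normalized_entropy
    (65.0, 18.0, 0.0, 100.0),     # home_stay (%)
    (5.0, 3.0, 0.0, 100.0),       # transition_time (%)
    (60.0, 40.0, 0.0, np.inf),    # total_distance (km)
    (2.0, 1.2, 0.0, np.inf),      # diurnal_movement
    (1.0, 0.6, 0.0, np.inf),      # diurnal_movement_normalized
    (1.5, 0.9, 0.0, np.inf),      # diurnal_movement_home_distance
]

_WEEK0 = datetime(2024, 1, 1)  # a Monday


@dataclass(frozen=True)
class CohortConfig:
    """Generating model for a grouped cohort with known structure."""

    n_groups: int
    individuals_per_group: int | list
    weeks_per_individual: int | tuple
    group_coefficients: np.ndarray  # (n_groups, 10), sparse rows
    group_offsets: np.ndarray
    group_noise_sd: np.ndarray
    feature_distribution: list = field(default_factory=lambda: list(DEFAULT_FEATURE_DISTRIBUTIONS))
    round_scores: bool = False
    cohort_labels: list | None = None  # optional per-group diagnostic label
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "group_coefficients", np.asarray(self.group_coefficients, dtype=float))
        object.__setattr__(self, "group_offsets", np.asarray(self.group_offsets, dtype=float))
        object.__setattr__(self, "group_noise_sd", np.asarray(self.group_noise_sd, dtype=float))
        if self.n_groups < 1:
            raise ValueError("n_groups must be positive")
        per = self.individuals_per_group
        if isinstance(per, int):
            if per < 1:
                raise ValueError("individuals_per_group must be positive")
        elif any(int(v) < 1 for v in per):
            raise ValueError("individuals_per_group entries must be positive")
        if self.group_coefficients.shape != (self.n_groups, N_FEATURES):
            raise ValueError(f"group_coefficients must be (n_groups, {N_FEATURES})")
        if self.group_offsets.shape != (self.n_groups,):
            raise ValueError("group_offsets must have one entry per group")
        if np.any(self.group_noise_sd < 0):
            raise ValueError("group_noise_sd must be >= 0")
        wk = self.weeks_per_individual
        lo = wk if isinstance(wk, int) else wk[0]
        if lo < 6:
            raise ValueError("weeks_per_individual must be >= 6")

    def group_sizes(self) -> list[int]:
        per = self.individuals_per_group
        if isinstance(per, int):
            return [per] * self.n_groups
        if len(per) != self.n_groups:
            raise ValueError("individuals_per_group list length must equal n_groups")
        return [int(v) for v in per]


def _draw_features(dist, n_weeks: int, rng: np.random.Generator) -> np.ndarray:
    X = np.empty((n_weeks, len(dist)))
    for j, (mean, sd, lo, hi) in enumerate(dist):
        if sd <= 0:
            X[:, j] = mean
            continue
        a, b = (lo - mean) / sd, (hi - mean) / sd
        X[:, j] = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n_weeks, random_state=rng)
    # keep home_stay + transition_time a valid split of recorded time
    i_home, i_trans = FEATURE_NAMES.index("home_stay"), FEATURE_NAMES.index("transition_time")
    X[:, i_trans] = np.minimum(X[:, i_trans], 100.0 - X[:, i_home])
    return X


def generate_grouped_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate weekly observations for every participant.

    Returns ``(cohort, labels)``: a long-format table with one row per
    participant-week (features on their natural scales plus the ``qids``
    score) and a sidecar table mapping participants to their generating
    group.  Scores are ``beta_k . x + mu_k + Normal(0, sigma_k^2)`` clipped
    to [0, 27]; identical seeds reproduce identical cohorts.
    """
    rng = as_rng(config.seed)
    rows = []
    labels = []
    idx = 0
    for k, size in enumerate(config.group_sizes()):
        beta = config.group_coefficients[k]
        mu = config.group_offsets[k]
        sd = config.group_noise_sd[k]
        label = config.cohort_labels[k] if config.cohort_labels else None
        for _ in range(size):
            pid = f"P{idx:03d}"
            idx += 1
            wk = config.weeks_per_individual
            n_weeks = wk if isinstance(wk, int) else int(rng.integers(wk[0], wk[1] + 1))
            X = _draw_features(config.feature_distribution, n_weeks, rng)
            eps = rng.normal(0.0, sd, size=n_weeks) if sd > 0 else np.zeros(n_weeks)
            y = np.clip(X @ beta + mu + eps, QIDS_MIN, QIDS_MAX)
            if config.round_scores:
                y = np.round(y)
            for w in range(n_weeks):
                row = {"participant_id": pid, "week_start": (_WEEK0 + timedelta(weeks=w)).date()}
                row.update(dict(zip(FEATURE_NAMES, X[w])))
                row["qids"] = y[w]
                if label is not None:
                    row["cohort"] = label
                rows.append(row)
            labels.append({"participant_id": pid, "true_group": k})
    return pd.DataFrame(rows), pd.DataFrame(labels)


def cohort_to_datasets(cohort: pd.DataFrame):
    """Split a long-format cohort table into per-participant datasets."""
    from .dpmix import IndividualDataset

    out = []
    for pid, df in cohort.groupby("participant_id", sort=True):
        df = df.sort_values("week_start")
        label = df["cohort"].iloc[0] if "cohort" in df else None
        out.append(IndividualDataset(pid, df[FEATURE_NAMES].to_numpy(), df["qids"].to_numpy(), label))
    return out


def _effect_coefficients(loadings: dict[int, float]) -> np.ndarray:
    """Coefficients on the natural feature scale giving the requested
    per-feature effect SD in score points (effect / feature SD)."""
    beta = np.zeros(N_FEATURES)
    for j, effect_sd in loadings.items():
        beta[j] = effect_sd / DEFAULT_FEATURE_DISTRIBUTIONS[j][1]
    return beta


def two_group_orthogonal_config(
    n_per_group: int = 8,
    weeks: int = 20,
    noise_sd: float = 1.0,
    effect_sd: float = 2.0,
    seed: int = 0,
) -> CohortConfig:
    """Benchmark cohort: two groups loading on disjoint single features.

    Group 0 responds only through the number of locations visited, group 1
    only through total distance, each with a ``effect_sd``-score-point
    per-feature-SD effect against ``noise_sd`` observation noise — a
    well-separated recovery problem at the stated cohort size.
    """
    coeffs = np.vstack(
        [
            _effect_coefficients({FEATURE_NAMES.index("n_clusters"): effect_sd}),
            _effect_coefficients({FEATURE_NAMES.index("total_distance"): effect_sd}),
        ]
    )
    return CohortConfig(
        n_groups=2,
        individuals_per_group=n_per_group,
        weeks_per_individual=weeks,
        group_coefficients=coeffs,
        group_offsets=np.array([10.0, 14.0]),
        group_noise_sd=np.full(2, noise_sd),
        seed=seed,
    )


def multi_group_config(
    n_per_group: int = 8,
    weeks: int = 20,
    noise_sd: float = 1.0,
    effect_sd: float = 2.0,
    seed: int = 0,
) -> CohortConfig:
    """Three groups with antagonistic structure for model comparisons.

    Two groups load on the same feature with opposite signs (so a pooled
    population model averages them away) and a third loads on a disjoint
    feature; cohort labels mimic a control/bipolar/borderline split.
    """
    j1, j2 = FEATURE_NAMES.index("n_clusters"), FEATURE_NAMES.index("total_distance")
    coeffs = np.vstack(
        [
            _effect_coefficients({j1: effect_sd}),
            _effect_coefficients({j1: -effect_sd}),
            _effect_coefficients({j2: effect_sd}),
        ]
    )
    return CohortConfig(
        n_groups=3,
        individuals_per_group=n_per_group,
        weeks_per_individual=weeks,
        group_coefficients=coeffs,
        group_offsets=np.array([6.0, 14.0, 10.0]),
        group_noise_sd=np.full(3, noise_sd),
        cohort_labels=["healthy_control", "bipolar", "borderline"],
        seed=seed,
    )


@dataclass(frozen=True)
class TraceConfig:
    """Schedule-driven GPS trace generator configuration.

    ``daily_schedule`` is a list of ``((start_hour, end_hour), anchor_index)``
    windows covering [0, 24); the participant sits at the scheduled anchor
    and walks between anchors at constant speed when the schedule changes.
    ``depression_modulation`` in [0, 1] shrinks every away-from-home window
    by that fraction (time returned to home), emulating the tendency of more
    depressed individuals to visit fewer places and stay at home more.
    """

    anchor_locations: list
    daily_schedule: list
    gps_noise_sd_m: float = 10.0
    sampling_interval_s: float = 300.0
    n_days: int = 7
    depression_modulation: float = 0.0
    home_anchor: int = 0
    transit_speed_kmh: float = 5.0
    start: datetime = _WEEK0
    accuracy_m: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not self.daily_schedule:
            raise ValueError("daily_schedule must not be empty")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling_interval_s must be > 0")
        for lat, lon in self.anchor_locations:
            if not (-90 <= lat <= 90 and -180 <= lon <= 180):
                raise ValueError("anchors must be valid WGS84 coordinates")
        if not (0.0 <= self.depression_modulation <= 1.0):
            raise ValueError("depression_modulation must be in [0, 1]")


def _schedule_steps(config: TraceConfig) -> list[tuple[float, int]]:
    """Flatten the daily schedule into (start_second, anchor) change points."""
    m = config.depression_modulation
    steps: list[tuple[float, int]] = []
    for day in range(config.n_days):
        base = day * 86400.0
        for (h0, h1), anchor in sorted(config.daily_schedule):
            s, e = base + h0 * 3600.0, base + h1 * 3600.0
            if anchor != config.home_anchor and m > 0:
                cut = s + (e - s) * (1.0 - m)
                steps.append((s, anchor))
                steps.append((cut, config.home_anchor))
            else:
                steps.append((s, anchor))
    merged = [steps[0]]
    for t, a in steps[1:]:
        if a != merged[-1][1]:
            merged.append((t, a))
    return merged


def generate_geolocation_trace(config: TraceConfig) -> pd.DataFrame:
    """Simulate a GPS trace following the anchor schedule.

    Returns a frame with strictly increasing timezone-aware timestamps,
    latitude/longitude (anchor position, or linear interpolation along the
    constant-speed walk after a schedule change, plus isotropic Gaussian
    jitter of ``gps_noise_sd_m``) and a constant reported accuracy.
    """
    from .utils import haversine_km

    rng = as_rng(config.seed)
    anchors = np.asarray(config.anchor_locations, dtype=float)
    steps = _schedule_steps(config)
    total_s = config.n_days * 86400.0
    times = np.arange(0.0, total_s, config.sampling_interval_s)

    starts = np.array([t for t, _ in steps])
    lats = np.empty(times.size)
    lons = np.empty(times.size)
    for i, t in enumerate(times):
        k = int(np.searchsorted(starts, t, side="right")) - 1
        k = max(k, 0)
        cur = anchors[steps[k][1]]
        if k > 0:
            prev = anchors[steps[k - 1][1]]
            dist_km = float(haversine_km(prev[0], prev[1], cur[0], cur[1]))
            travel_s = dist_km / config.transit_speed_kmh * 3600.0
            dt = t - starts[k]
            if travel_s > 0 and dt < travel_s:
                frac = dt / travel_s
                cur = prev + frac * (cur - prev)
        lats[i], lons[i] = cur

    if config.gps_noise_sd_m > 0:
        lat_m = 111_195.0  # meters per degree latitude
        lats = lats + rng.normal(0, config.gps_noise_sd_m, times.size) / lat_m
        lons = lons + rng.normal(0, config.gps_noise_sd_m, times.size) / (
            lat_m * np.cos(np.radians(np.clip(lats, -89.9, 89.9)))
        )

    base = config.start.replace(tzinfo=timezone.utc) if config.start.tzinfo is None else config.start
    stamps = pd.to_datetime(base) + pd.to_timedelta(times, unit="s")
    return pd.DataFrame(
        {
            "timestamp": stamps,
            "latitude": lats,
            "longitude": lons,
            "accuracy_m": np.full(times.size, float(config.accuracy_m)),
        }
    )
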