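"""Shared helpers: seeding, distances, validation."""

from __future__ import annotations

import zlib

import numpy as np

EARTH_RADIUS_KM = 6371.0

#: Canonical order of the 10 weekly behavioral features.
FEATURE_NAMES = [
    "location_variance",
    "n_clusters",
    "entropy",
    "normalized_entropy",
    "home_stay",
    "transition_time",
    "total_distance",
    "diurnal_movement",
    "diurnal_movement_normalized",
    "diurnal_movement_home_distance",
]

N_FEATURES = len(FEATURE_NAMES)


def child_rng(seed: int, *keys) -> np.random.Generator:
    """Derive an independent random generator from a run seed and a key path.

    String keys are hashed with CRC-32 so that every (seed, key...) pair maps
    to a distinct, reproducible ``SeedSequence``.  Used so that a single run
    seed determines the randomness of every model variant and participant
    independently of execution order.
    """
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


def as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between WGS84 points (degrees), vectorized."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def check_array_2d(X, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if X.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite values")
    return X
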