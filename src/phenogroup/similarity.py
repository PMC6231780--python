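"""Feature-similarity baseline after Lane et al. / Abdullah et al.

Individuals are compared by where their *feature values* sit, ignoring the
feature-to-score relationship: random probe points are drawn in the
(z-scored) feature space and two individuals count as similar when they are
repeatedly among the participants nearest the same probe.  The resulting
similarity conditions a regression by weighting each training individual's
rows in the Bayesian Lasso likelihood — the regression analogue of the
original similarity-conditioned boosting classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .lasso import LassoPriors, fit as lasso_fit, per_iteration_mae
from .utils import as_rng, check_array_2d

__all__ = [
    "SimilarityMatrix",
    "participant_summaries",
    "random_projection_similarity",
    "similarity_weighted_fit",
    "RandomProjectionSimilarity",
]


@dataclass
class SimilarityMatrix:
    """Symmetric participant-by-participant co-nearest-probe frequencies."""

    values: pd.DataFrame
    n_projections: int
    seed: int | None = None

    def __getitem__(self, pair):
        i, j = pair
        return float(self.values.loc[i, j])


def participant_summaries(datasets) -> pd.DataFrame:
    """Mean weekly feature vector per participant (the distribution summary)."""
    rows = {d.participant_id: d.X.mean(axis=0) for d in datasets}
    return pd.DataFrame.from_dict(rows, orient="index")


def random_projection_similarity(
    feature_summaries: pd.DataFrame,
    n_projections: int = 1000,
    n_nearest: int | None = None,
    seed=None,
) -> SimilarityMatrix:
    """Co-nearest-probe similarity over random points in feature space.

    Features are z-scored across participants, probes drawn uniformly over
    their bounding box, and for each probe the ``n_nearest`` participants
    (default: a quarter of the cohort; distance ties included) are marked.
    similarity(i, j) is the fraction of probes marking *both* i and j among
    the probes marking *either* (0 when neither is ever marked), so
    participants with identical summaries — always marked together — have
    similarity 1; the diagonal is 1 by definition.
    """
    if len(feature_summaries) < 2:
        raise ValueError("need at least 2 participants")
    ids = list(feature_summaries.index)
    X = check_array_2d(feature_summaries.to_numpy(), "feature_summaries")
    n = len(ids)
    k = n_nearest if n_nearest is not None else max(1, n // 4)

    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    lo, hi = Z.min(axis=0), Z.max(axis=0)

    rng = as_rng(seed)
    both = np.zeros((n, n))
    marked_count = np.zeros(n)
    for _ in range(n_projections):
        probe = rng.uniform(lo, hi)
        d = np.linalg.norm(Z - probe, axis=1)
        thresh = np.partition(d, k - 1)[k - 1]
        marked = np.flatnonzero(d <= thresh + 1e-12)
        both[np.ix_(marked, marked)] += 1.0
        marked_count[marked] += 1.0
    either = marked_count[:, None] + marked_count[None, :] - both
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(either > 0, both / np.maximum(either, 1.0), 0.0)
    np.fill_diagonal(sim, 1.0)
    df = pd.DataFrame(sim, index=ids, columns=ids)
    return SimilarityMatrix(df, n_projections, seed if isinstance(seed, int) else None)


def similarity_weighted_fit(
    test_id,
    datasets,
    similarity: SimilarityMatrix,
    split,
    priors: LassoPriors | None = None,
    n_iter: int = 1000,
    seed=None,
) -> tuple[np.ndarray, float]:
    """Similarity-weighted Bayesian Lasso for one held-out participant.

    Training rows are the test participant's calibration weeks (weight 1)
    plus every other participant's weeks weighted by similarity to the test
    participant (weights enter as per-row precision multipliers).  Returns
    the per-iteration MAE on the test participant's evaluation weeks and its
    mean.
    """
    priors = priors or LassoPriors()
    data = {d.participant_id: d for d in datasets}
    test = data[test_id]
    X_parts = [test.X[split.calibration_indices]]
    y_parts = [test.y[split.calibration_indices]]
    w_parts = [np.ones(len(split.calibration_indices))]
    for pid in sorted(data):
        if pid == test_id:
            continue
        d = data[pid]
        X_parts.append(d.X)
        y_parts.append(d.y)
        w_parts.append(np.full(d.n_weeks, similarity[test_id, pid]))
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    w = np.concatenate(w_parts)
    if not np.any(w > 0):
        warnings.warn("all similarity weights are zero; falling back to uniform", RuntimeWarning)
        w = np.ones_like(w)

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    chain = lasso_fit((X - mean) / sd, y, priors, n_iter=n_iter, seed=seed, weights=w)
    X_eval = (test.X[split.evaluation_indices] - mean) / sd
    return per_iteration_mae(chain, X_eval, test.y[split.evaluation_indices])


class RandomProjectionSimilarity(BaseEstimator):
    """Estimator wrapper: fit on a participant-summary matrix, expose
    ``similarity_`` (DataFrame) computed by co-nearest-probe counting."""

    def __init__(self, n_projections: int = 1000, n_nearest: int | None = None, random_state=None):
        self.n_projections = n_projections
        self.n_nearest = n_nearest
        self.random_state = random_state

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        result = random_projection_similarity(
            X, n_projections=self.n_projections, n_nearest=self.n_nearest, seed=self.random_state
        )
        self.similarity_ = result.values
        return self
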