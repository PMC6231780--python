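"""Leave-one-participant-out comparison of six score-estimation models.

Every model predicts a held-out participant's weekly depression scores from
their behavioral features; models differ only in whose data trains the
regression:

* population — everyone else's weeks plus the test participant's
  calibration weeks;
* group-personalized (retrospective) — same-group peers only, given a
  partition from the DP mixture;
* group-personalized with calibration allocation — the group is chosen
  prospectively by which group model best predicts the calibration weeks;
* fully personalized, cross-validated — the participant's own data, 10
  random 80/20 splits;
* fully personalized, calibration only — just the calibration weeks;
* feature-similarity baseline — everyone's weeks, weighted by
  random-projection similarity of feature distributions.

Calibration weeks are the first half of a participant's weeks capped at 8;
they may enter training but never the evaluation MAE.  Performance is the
mean over Gibbs iterations of the per-iteration MAE, compared across models
with a one-tailed paired t test over participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dpmix import IndividualDataset, Partition, sample_prior_state
from .lasso import BayesianLasso, LassoChain, LassoPriors, per_iteration_mae
from .similarity import participant_summaries, random_projection_similarity, similarity_weighted_fit
from .utils import child_rng

__all__ = [
    "CalibrationSplit",
    "EvaluationResult",
    "calibration_split",
    "include_participants",
    "evaluate_population",
    "evaluate_group_personalized",
    "allocate_group",
    "evaluate_group_allocated",
    "evaluate_personalized_cv",
    "evaluate_personalized_calibration",
    "evaluate_clustering_baseline",
    "paired_one_tailed_t_test",
    "summarize_by_cohort",
]

MAX_CALIBRATION_WEEKS = 8
MIN_WEEKS = 6
CV_REPEATS = 10


@dataclass(frozen=True)
class CalibrationSplit:
    """Week indices used for calibration (training only) vs evaluation."""

    calibration_indices: np.ndarray
    evaluation_indices: np.ndarray


def calibration_split(n_weeks: int, max_calibration: int = MAX_CALIBRATION_WEEKS) -> CalibrationSplit:
    """First-half-up-to-8 rule: |calibration| = min(floor(n/2), 8).

    Calibration weeks are taken from the start of the series; everything
    after them is evaluated.
    """
    if n_weeks < 2:
        raise ValueError("need at least 2 weeks to split")
    n_cal = min(n_weeks // 2, max_calibration)
    return CalibrationSplit(np.arange(n_cal), np.arange(n_cal, n_weeks))


def include_participants(datasets, min_weeks: int = MIN_WEEKS):
    """Keep participants with at least ``min_weeks`` labeled weeks."""
    return [d for d in datasets if d.n_weeks >= min_weeks]


@dataclass
class EvaluationResult:
    """Per-participant and overall MAE under one named model variant."""

    model_name: str
    per_participant: pd.DataFrame  # participant_id, cohort, mean_mae, sd_mae

    @property
    def overall_mean(self) -> float:
        return float(self.per_participant["mean_mae"].mean())

    @property
    def overall_sd(self) -> float:
        return float(self.per_participant["mean_mae"].std(ddof=1))

    def mae_series(self) -> pd.Series:
        return self.per_participant.set_index("participant_id")["mean_mae"]


def _fit_and_score(X_train, y_train, test: IndividualDataset, split: CalibrationSplit, priors, n_iter, rng):
    model = BayesianLasso(
        lam=priors.lam,
        mu_mu=priors.mu_mu,
        sigma_mu_sq=priors.sigma_mu_sq,
        alpha_sigma_sq=priors.alpha_sigma_sq,
        gamma_sigma_sq=priors.gamma_sigma_sq,
        n_iter=n_iter,
        random_state=rng,
    )
    model.fit(X_train, y_train)
    return model.mae(test.X[split.evaluation_indices], test.y[split.evaluation_indices])


def _result(model_name: str, rows: list) -> EvaluationResult:
    return EvaluationResult(model_name, pd.DataFrame(rows))


def _row(d: IndividualDataset, maes: np.ndarray) -> dict:
    return {
        "participant_id": d.participant_id,
        "cohort": d.cohort_label,
        "mean_mae": float(np.mean(maes)),
        "sd_mae": float(np.std(maes, ddof=1)) if maes.size > 1 else 0.0,
    }


def evaluate_population(datasets, priors: LassoPriors | None = None, n_iter: int = 1000, seed=0) -> EvaluationResult:
    """One model for everyone: train on all other participants plus the test
    participant's calibration weeks."""
    priors = priors or LassoPriors()
    datasets = sorted(datasets, key=lambda d: d.participant_id)
    rows = []
    for test in datasets:
        split = calibration_split(test.n_weeks)
        X = np.vstack([test.X[split.calibration_indices]] + [d.X for d in datasets if d is not test])
        y = np.concatenate([test.y[split.calibration_indices]] + [d.y for d in datasets if d is not test])
        rng = child_rng(seed, "population", test.participant_id)
        maes, _ = _fit_and_score(X, y, test, split, priors, n_iter, rng)
        rows.append(_row(test, maes))
    return _result("population", rows)


def _labels_dict(partition) -> dict:
    if isinstance(partition, Partition):
        return dict(partition.assignment)
    return dict(partition)


def evaluate_group_personalized(
    datasets, partition, priors: LassoPriors | None = None, n_iter: int = 1000, seed=0
) -> EvaluationResult:
    """Train on same-group peers plus own calibration weeks.

    A participant alone in their group reduces to the fully personalized
    calibration-only model.
    """
    priors = priors or LassoPriors()
    labels = _labels_dict(partition)
    datasets = sorted(datasets, key=lambda d: d.participant_id)
    rows = []
    for test in datasets:
        split = calibration_split(test.n_weeks)
        peers = [d for d in datasets if d is not test and labels[d.participant_id] == labels[test.participant_id]]
        X = np.vstack([test.X[split.calibration_indices]] + [d.X for d in peers])
        y = np.concatenate([test.y[split.calibration_indices]] + [d.y for d in peers])
        # a singleton reduces *exactly* to the calibration-only personal model,
        # down to the random stream
        key = "group_personalized" if peers else "personalized_calibration"
        rng = child_rng(seed, key, test.participant_id)
        maes, _ = _fit_and_score(X, y, test, split, priors, n_iter, rng)
        rows.append(_row(test, maes))
    return _result("group_personalized", rows)


def _prior_only_mae(test, split, priors, n_iter, rng):
    """Score a group that has no remaining members with prior-draw states."""
    p = test.X.shape[1]
    chain = LassoChain([sample_prior_state(priors, p, rng) for _ in range(n_iter)])
    mean = test.X[split.calibration_indices].mean(axis=0)
    sd = test.X[split.calibration_indices].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xc = (test.X[split.calibration_indices] - mean) / sd
    return per_iteration_mae(chain, Xc, test.y[split.calibration_indices])


def allocate_group(
    test: IndividualDataset,
    partition,
    datasets,
    priors: LassoPriors | None = None,
    n_iter: int = 1000,
    seed=0,
) -> int:
    """Choose the group whose model best predicts the calibration weeks.

    For the test participant's own group, the model is trained on the
    remaining members (prior-only scoring if none remain); ties break to the
    smaller group id.
    """
    priors = priors or LassoPriors()
    labels = _labels_dict(partition)
    split = calibration_split(test.n_weeks)
    by_group: dict[int, list] = {}
    for d in sorted(datasets, key=lambda d: d.participant_id):
        if d.participant_id == test.participant_id:
            continue
        by_group.setdefault(labels[d.participant_id], []).append(d)
    group_ids = sorted(set(labels.values()))

    best = (np.inf, None)
    for g in group_ids:
        rng = child_rng(seed, "allocate", test.participant_id, g)
        members = by_group.get(g, [])
        if not members:
            _, mean_mae = _prior_only_mae(test, split, priors, n_iter, rng)
        else:
            X = np.vstack([d.X for d in members])
            y = np.concatenate([d.y for d in members])
            model = BayesianLasso(
                lam=priors.lam,
                mu_mu=priors.mu_mu,
                sigma_mu_sq=priors.sigma_mu_sq,
                alpha_sigma_sq=priors.alpha_sigma_sq,
                gamma_sigma_sq=priors.gamma_sigma_sq,
                n_iter=n_iter,
                random_state=rng,
            ).fit(X, y)
            _, mean_mae = model.mae(test.X[split.calibration_indices], test.y[split.calibration_indices])
        if mean_mae < best[0]:
            best = (mean_mae, g)
    return best[1]


def evaluate_group_allocated(
    datasets, partition, priors: LassoPriors | None = None, n_iter: int = 1000, seed=0
) -> EvaluationResult:
    """Prospective variant: allocate by calibration performance, then train
    on own calibration weeks plus the allocated group's members."""
    priors = priors or LassoPriors()
    labels = _labels_dict(partition)
    datasets = sorted(datasets, key=lambda d: d.participant_id)
    rows = []
    for test in datasets:
        split = calibration_split(test.n_weeks)
        g = allocate_group(test, labels, datasets, priors, n_iter=n_iter, seed=seed)
        peers = [d for d in datasets if d is not test and labels[d.participant_id] == g]
        X = np.vstack([test.X[split.calibration_indices]] + [d.X for d in peers])
        y = np.concatenate([test.y[split.calibration_indices]] + [d.y for d in peers])
        rng = child_rng(seed, "group_allocated", test.participant_id)
        maes, _ = _fit_and_score(X, y, test, split, priors, n_iter, rng)
        rows.append(_row(test, maes))
    return _result("group_allocated", rows)


def evaluate_personalized_cv(
    datasets, priors: LassoPriors | None = None, n_iter: int = 1000, seed=0, n_repeats: int = CV_REPEATS
) -> EvaluationResult:
    """Fully personalized upper bound: 10 random 80/20 splits of the
    participant's own weeks."""
    priors = priors or LassoPriors()
    rows = []
    for test in sorted(datasets, key=lambda d: d.participant_id):
        if test.n_weeks < 5:
            raise ValueError(f"{test.participant_id} has fewer than 5 weeks")
        rng = child_rng(seed, "personalized_cv", test.participant_id)
        all_maes = []
        for _ in range(n_repeats):
            perm = rng.permutation(test.n_weeks)
            n_train = max(int(round(0.8 * test.n_weeks)), 1)
            n_train = min(n_train, test.n_weeks - 1)
            tr, ev = perm[:n_train], perm[n_train:]
            model = BayesianLasso(
                lam=priors.lam,
                mu_mu=priors.mu_mu,
                sigma_mu_sq=priors.sigma_mu_sq,
                alpha_sigma_sq=priors.alpha_sigma_sq,
                gamma_sigma_sq=priors.gamma_sigma_sq,
                n_iter=n_iter,
                random_state=rng,
            ).fit(test.X[tr], test.y[tr])
            maes, _ = model.mae(test.X[ev], test.y[ev])
            all_maes.append(maes)
        rows.append(_row(test, np.concatenate(all_maes)))
    return _result("personalized_cv", rows)


def evaluate_personalized_calibration(
    datasets, priors: LassoPriors | None = None, n_iter: int = 1000, seed=0
) -> EvaluationResult:
    """Fully personalized model trained on the calibration weeks only."""
    priors = priors or LassoPriors()
    rows = []
    for test in sorted(datasets, key=lambda d: d.participant_id):
        split = calibration_split(test.n_weeks)
        rng = child_rng(seed, "personalized_calibration", test.participant_id)
        maes, _ = _fit_and_score(
            test.X[split.calibration_indices], test.y[split.calibration_indices], test, split, priors, n_iter, rng
        )
        rows.append(_row(test, maes))
    return _result("personalized_calibration", rows)


def evaluate_clustering_baseline(
    datasets, priors: LassoPriors | None = None, n_iter: int = 1000, seed=0, n_projections: int = 1000
) -> EvaluationResult:
    """Random-projection feature-similarity baseline (similarity computed on
    all data including the test participant, per its published protocol)."""
    priors = priors or LassoPriors()
    datasets = sorted(datasets, key=lambda d: d.participant_id)
    sim = random_projection_similarity(
        participant_summaries(datasets), n_projections=n_projections, seed=child_rng(seed, "similarity")
    )
    rows = []
    for test in datasets:
        split = calibration_split(test.n_weeks)
        rng = child_rng(seed, "clustering", test.participant_id)
        maes, _ = similarity_weighted_fit(
            test.participant_id, datasets, sim, split, priors, n_iter=n_iter, seed=rng
        )
        rows.append(_row(test, maes))
    return _result("clustering_baseline", rows)


def paired_one_tailed_t_test(mae_a, mae_b) -> tuple[float, float]:
    """Paired t test of H1: mean(mae_a - mae_b) > 0 (model b improves on a)."""
    a = np.asarray(mae_a, dtype=float)
    b = np.asarray(mae_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need equal-length samples of size >= 2")
    diff = a - b
    if np.allclose(np.std(diff, ddof=1), 0.0):
        warnings.warn("zero variance of paired differences", RuntimeWarning)
        return (np.inf if diff.mean() > 0 else -np.inf if diff.mean() < 0 else 0.0), (
            0.0 if diff.mean() > 0 else 1.0 if diff.mean() < 0 else 0.5
        )
    t, p = stats.ttest_rel(a, b, alternative="greater")
    return float(t), float(p)


def summarize_by_cohort(results) -> pd.DataFrame:
    """Mean (SD) of per-participant MAEs per diagnostic cohort and overall."""
    if isinstance(results, EvaluationResult):
        results = [results]
    rows = []
    for res in results:
        df = res.per_participant
        entry = {"model": res.model_name}
        if df["cohort"].notna().any():
            for label, sub in df.groupby("cohort"):
                entry[f"{label}_mean"] = float(sub["mean_mae"].mean())
                entry[f"{label}_sd"] = float(sub["mean_mae"].std(ddof=1)) if len(sub) > 1 else 0.0
        entry["overall_mean"] = res.overall_mean
        entry["overall_sd"] = res.overall_sd
        rows.append(entry)
    return pd.DataFrame(rows)
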