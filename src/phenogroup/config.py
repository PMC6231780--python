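"""Run configuration: every tunable constant of the pipeline in one place,
loadable from YAML with command-line overrides."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .features import FeatureConfig
from .lasso import LassoPriors


@dataclass
class RunConfig:
    """Defaults are the published operating point of the method:
    lambda=0.4, alpha=1e-4, 1000 Lasso iterations, 5000 DP sweeps,
    calibration capped at 8 weeks, >=6 labeled weeks for inclusion,
    10 cross-validation repeats."""

    seed: int = 0
    # regression / mixture
    lam: float = 0.4
    alpha: float = 1e-4
    mu_mu: float = 0.0
    sigma_mu_sq: float = 10.0
    alpha_sigma_sq: float = 1.0
    gamma_sigma_sq: float = 1.0
    n_iter_lasso: int = 1000
    n_iter_dp: int = 5000
    n_iter_grid: int = 500
    n_aux: int = 3
    # evaluation
    min_weeks: int = 6
    max_calibration_weeks: int = 8
    cv_repeats: int = 10
    n_projections: int = 1000
    # feature extraction
    max_accuracy_m: float = 100.0
    speed_threshold_kmh: float = 1.0
    min_duration_min: float = 5.0
    cluster_distance_m: float = 200.0
    min_coverage: float = 0.5

    def __post_init__(self):
        for name in ("n_iter_lasso", "n_iter_dp", "n_iter_grid", "n_aux", "min_weeks", "cv_repeats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def priors(self) -> LassoPriors:
        return LassoPriors(
            lam=self.lam,
            mu_mu=self.mu_mu,
            sigma_mu_sq=self.sigma_mu_sq,
            alpha_sigma_sq=self.alpha_sigma_sq,
            gamma_sigma_sq=self.gamma_sigma_sq,
        )

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            max_accuracy_m=self.max_accuracy_m,
            speed_threshold_kmh=self.speed_threshold_kmh,
            min_duration_min=self.min_duration_min,
            cluster_distance_m=self.cluster_distance_m,
            min_coverage=self.min_coverage,
        )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
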