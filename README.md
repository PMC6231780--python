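# phenogroup

Group-personalized regression of self-reported depression from
geolocation-derived behavioral features.

## The problem

Weekly mobility features extracted from a phone's GPS trace — home stay,
number of places visited, entropy of time across places, circadian movement
regularity, distance traveled — carry signal about depressive symptoms
(measured here as QIDS self-report scores, 0–27). A single population-level
regression linking features to scores assumes every individual responds to
illness the same way; in practice interindividual variability swamps the
shared signal. Fully personal models avoid that but need more labeled weeks
per person than is practical and generalize poorly.

`phenogroup` implements the middle ground: a **Dirichlet-process mixture of
Bayesian Lasso regressions** that automatically partitions individuals into
groups sharing the *same feature-to-score relationship* ("behavioral
phenotypes"), and fits one sparse linear model per group.

## The model

For individual *i* in group *k*, week *t*:

```
y_it | β_k, μ_k, σ_k²      ~  N(β_k · x_it + μ_k, σ_k²)
β_kj | τ_kj², σ_k²         ~  N(0, σ_k² τ_kj²)        (scale-mixture Laplace: λ|β|/σ penalty)
τ_kj²                      ~  Exp(λ²/2)
μ_k                        ~  N(μ_μ, σ_μ²)
σ_k²                       ~  InvGamma(α_σ², γ_σ²)
(z_1, …, z_n)              ~  CRP(α)                   (partition of individuals into groups)
```

Defaults are the optimized operating point: λ = 0.4, α = 10⁻⁴,
μ_μ = 0, σ_μ² = 10, α_σ² = γ_σ² = 1. Each Bayesian Lasso is sampled by
Gibbs (Park–Casella conditionals, 1000 sweeps); the partition is sampled by
Neal's Algorithm 8 with m = 3 auxiliary components (5000 sweeps), and the
reported partition is the maximum-joint-probability sample.

Around the core model the package provides:

* `phenogroup.features` — raw GPS trace → the 10 weekly features
  (stay-point segmentation, place clustering, night-dwell home detection,
  entropy, near-24 h sinusoid power), on Monday-to-Sunday calendar weeks;
* `phenogroup.synthetic` — cohort and GPS-trace generators with known
  ground truth;
* `phenogroup.evaluation` — the six-model leave-one-participant-out
  comparison (population, group-personalized retrospective and
  calibration-allocated, fully personalized ×2, feature-similarity
  baseline) with per-Gibbs-iteration MAE and paired one-tailed t tests;
* `phenogroup.similarity` — the random-projection feature-similarity
  baseline;
* a CLI: `phenogroup simulate | extract-features | fit-group-model |
  evaluate | report`.

## Worked example

Two synthetic groups of 8 individuals (20 weeks each, noise SD 1): one
group's scores depend only on the number of places visited, the other's
only on total distance.

```python
import numpy as np
import phenogroup as pg
from phenogroup import evaluation as ev
from sklearn.metrics import adjusted_rand_score

cfg = pg.two_group_orthogonal_config(seed=1)
cohort, labels = pg.generate_grouped_cohort(cfg)

model = pg.DPGroupLasso(n_iter=1000, random_state=0).fit(
    cohort[pg.FEATURE_NAMES].to_numpy(), cohort["qids"].to_numpy(),
    groups=cohort["participant_id"].to_numpy())
truth = labels.set_index("participant_id")["true_group"].loc[model.participants_]
print("groups found:", model.n_groups_)
print("adjusted Rand index vs truth:", adjusted_rand_score(truth, model.labels_))

datasets = pg.cohort_to_datasets(cohort)
pop = ev.evaluate_population(datasets, n_iter=300, seed=0)
grp = ev.evaluate_group_personalized(
    datasets, dict(zip(model.participants_, model.labels_)), n_iter=300, seed=0)
t, p = ev.paired_one_tailed_t_test(pop.mae_series(), grp.mae_series())
print(f"population MAE        : {pop.overall_mean:.2f} ({pop.overall_sd:.2f})")
print(f"group-personalized MAE: {grp.overall_mean:.2f} ({grp.overall_sd:.2f})")
print(f"paired one-tailed t={t:.2f}, p={p:.2g}")
```

Output:

```
groups found: 2
adjusted Rand index vs truth: 1.0
population MAE        : 1.83 (0.45)
group-personalized MAE: 0.87 (0.21)
paired one-tailed t=8.20, p=3.2e-07
```

The sampler recovers the generating two-group structure exactly (ARI 1.0),
and the group-personalized model halves the mean absolute error of the
pooled population model — the antagonistic group structure that the pooled
fit averages away is preserved within groups.

The same pipeline from the shell:

```bash
phenogroup simulate --seed 1 --out runs/sim
phenogroup evaluate --features runs/sim/features.csv --scores runs/sim/scores.csv \
    --cohorts runs/sim/cohorts.csv --out runs/eval --seed 1 --n-iter 300 --dp-iters 1000
phenogroup report --results runs/eval --out runs/report
```

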