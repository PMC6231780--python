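# Methods

## Model

The core model is a Dirichlet-process (DP) mixture over individuals whose
mixture components are Bayesian Lasso linear regressions. Each individual
*i* contributes a set of weekly observations (x_it, y_it): a 10-dimensional
behavioral feature vector and a depression score treated as continuous on
the 0–27 scale. Conditional on membership in group *k*, weeks are
independent Gaussians around the group's linear predictor
β_k·x + μ_k with variance σ_k². The coefficient prior is the
scale-mixture-of-normals representation of the Laplace distribution
(β_kj | τ_kj², σ_k² ~ N(0, σ_k²τ_kj²), τ_kj² ~ Exp(λ²/2)), i.e. the ℓ₁
penalty is conditional on the noise scale, which keeps the joint posterior
unimodal and yields closed-form full conditionals: μ and β Gaussian,
1/τ_j² inverse-Gaussian, σ² inverse-gamma. The sweep order is
μ → β → τ² → σ².

The partition prior is the Chinese restaurant process with concentration
α. Assignments are resampled with Neal's Algorithm 8: when individual *i*
is detached, m auxiliary component states are drawn from the prior (the
orphaned state of a dissolved singleton seeds the first auxiliary, per
Neal), and *i* rejoins group *k* with weight n_{-i,k}·L_i(θ_k) or starts a
new group with weight (α/m)·L_i(θ_aux). A full sweep over individuals
alternates with one Gibbs sweep of every occupied group's regression state
on its pooled member rows. The joint log probability — CRP partition mass
plus state priors plus member likelihoods — is recorded every sweep.

### Assumptions

* Linearity of the feature–score relationship within a group; weeks are
  conditionally independent given the group state (no temporal dynamics).
* An individual belongs to one group for their entire record.
* Scores are modeled as unbounded reals; predictions are **not** clipped to
  [0, 27] and MAE is computed on raw predictions.

## Parameters

| parameter | default | units / scale | rationale |
|---|---|---|---|
| λ (Lasso regularization) | 0.4 | dimensionless, on z-scored features | optimized operating point of the method |
| α (DP concentration) | 1e-4 | dimensionless | optimized operating point; small α favors few groups so the likelihood drives splitting |
| μ_μ, σ_μ² | 0, 10 | score points, points² | weakly informative offset prior |
| α_σ², γ_σ² | 1, 1 | shape, rate | weakly informative noise prior |
| Lasso sweeps | 1000 | iterations | enough for the per-iteration-MAE summary to stabilize; no burn-in is discarded because performance is averaged over *all* iterations (an optional burn-in flag defaults to 0) |
| DP sweeps | 5000 | iterations | full-length run for partition recovery |
| m (auxiliary components) | 3 | count | standard small value for Algorithm 8; exposed in config |
| calibration cap | 8 | weeks | first-half-up-to-8 rule: min(⌊n/2⌋, 8) earliest weeks |
| inclusion minimum | 6 | labeled weeks | participants with fewer are excluded |
| CV repeats | 10 | splits | random 80/20 subsampling for the fully personal upper bound |

Features are z-scored before any regression — per training set for the
standalone estimator (transform stored for prediction), cohort-wide before
the DP sampler — because the ℓ₁ penalty is scale-sensitive and the 10
features span log-variances, percentages and kilometers. For odd week
counts the "first half" of the calibration rule is ⌊n/2⌋ (the conservative
reading; both published worked examples are even).

## Numerical choices

* **Initialization**: β = 0, μ = mean(y), σ² = var(y) (1 if a single row),
  τ² = 1. The DP sampler starts from singleton groups, each state one Gibbs
  sweep from its own data; with α = 1e-4 merges happen within the first few
  sweeps.
* **Degenerate conditionals**: a singular β-conditional precision gets
  1e-10 diagonal jitter with a warning; |β_j|² is floored at 1e-12 inside
  the inverse-Gaussian mean; 1/τ² draws are floored away from zero.
* **Point-estimate partition**: the chain sample maximizing joint log
  probability (`method="map"`), matching the criterion the λ/α grid search
  optimizes; the final sample is selectable (`method="last"`). Per-group
  coefficient summaries come from a fresh 1000-sweep Lasso refit on pooled
  member rows, with per-feature Pearson correlations against the scores.
  Groups with fewer than 2 members are flagged "unassigned".
* **Sweep order** over participants is sorted by id; all randomness flows
  from one `numpy` Generator per run, and evaluation derives one
  independent stream per (model, participant) from the run seed via
  `SeedSequence` so results are order-independent and reproducible.
* **Emptied groups** during calibration-based allocation (a group whose
  only member is the held-out individual) are scored with 1000 prior-draw
  states.
* A participant alone in their group reduces exactly — including the
  random stream — to the calibration-only personal model.

## Feature extraction

Preprocessing and feature definitions follow standard stay-point practice;
every threshold is exposed in `FeatureConfig`:

* accuracy filter 100 m; duplicate timestamps keep the most accurate fix;
* stationary/transition split at centroid speed > 1 km/h sustained, with
  stays shorter than 5 min folded into transition time;
* places by greedy leader clustering of stay centroids (descending dwell
  order, 200 m great-circle threshold); cluster ids ranked by total dwell;
* home = place with maximal 00:00–06:00 local dwell over the *whole* trace
  (stable anchor for distance-from-home), ties to the lower id; weeks with
  no identifiable home get missing home-dependent features;
* log location variance uses ln(var(lat)+var(lon)+1e-12) so constant
  traces stay finite;
* circadian power: least-squares sine/cosine fit per period on a
  23.5–24.5 h grid in 0.1 h steps; the period minimizing total residual is
  selected and its summed squared amplitude across coordinate dimensions
  returned;
* all distances are haversine with Earth radius 6371.0 km; weeks are keyed
  by the local Monday 00:00 boundary; weeks with under 50% of hours
  covered are dropped;
* home-stay and transition percentages are of *recorded* time (first to
  last fix of the week), not calendar time.

## Similarity baseline

The comparative baseline clusters on feature *values*, not on
feature–score relationships: probes are drawn uniformly over the bounding
box of cohort-wide z-scored mean weekly feature vectors, and for each
probe the nearest quarter of the cohort (ties included) is marked.
Similarity(i, j) is the fraction of probes marking both among probes
marking either, so identical individuals score 1. The published
similarity-conditioned boosting classifier is realized as its minimal
regression analogue: per-row precision multipliers in the Bayesian Lasso
likelihood, with the held-out individual's calibration rows at weight 1.
This weighting scheme is a declared stand-in — the original work does not
describe its regression adaptation.

## Synthetic data

The cohort generator draws weekly features as independent truncated
Gaussians on their natural scales (percentages in [0, 100], entropies and
distances ≥ 0, normalized entropy in [0, 1]) with means and spreads
plausible for adults carrying a phone, then produces scores from a sparse
group-specific linear model (≤3 nonzero loadings per group) plus Gaussian
noise, clipped to [0, 27]. Scores are kept real-valued because the models
treat them as continuous; an option rounds to integers to mimic the
questionnaire. The benchmark cohorts fix the per-feature effect at 2 score
points per feature SD against noise SD 1: `two_group_orthogonal_config`
(two groups loading on disjoint single features, 8 individuals × 20 weeks
each) and `multi_group_config` (three groups, two of them antagonistic on
the same feature, with control/bipolar/borderline-style labels).

The trace generator follows a daily anchor schedule (home/work/other) with
constant-speed 5 km/h walking transitions — chosen so the transition-time
feature is exercised without extra configuration — isotropic Gaussian GPS
jitter, and a `depression_modulation` knob that shrinks away-from-home
windows, emulating the tendency of more depressed individuals to visit
fewer places and stay home more.

What the generators do **not** emulate: week-to-week autocorrelation of
behavior, feature cross-correlations, missing weeks, irregular sampling,
indoor GPS dropout, or episodic mood dynamics. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
conditions, not performance on real cohorts; the published real-data error
magnitudes are not reproducible from synthetic data and are not targeted.

## Verification problem sizes

The test suite verifies the Gibbs sampler against 3-D brute-force
trapezoid quadrature of the marginal posterior on a fixed univariate
5-point dataset (50,000 draws, agreement within 3 batch-means Monte-Carlo
SEs); the clustering prior against the analytic CRP expectation
Σ 1/(α+i−1) over 10,000 sequential seatings (n = 10, α = 1); partition
recovery on the two-group benchmark across five seeds at the full
5000-sweep length; and the six-model comparison on the three-group cohort
(24 participants, 300-sweep Lasso chains, 1500-sweep DP run) — chain
lengths chosen so the whole comparison completes in minutes while the MAE
ordering and its significance are stable across seeds.

## Known limitations

* λ is shared across groups (the per-group reading is ambiguous in the
  source method); a per-group λ is not implemented.
* No split–merge moves or slice sampling; mixing relies on Algorithm 8
  alone, which is adequate at these cohort sizes.
* No hyperpriors on α or λ; both are fixed or grid-searched by maximizing
  the best observed joint log probability over shortened chains (500
  sweeps, shared seed per grid point).
* The preprocessing constants (accuracy, speed, dwell, cluster radius) are
  explicit stand-ins for an external preprocessing pipeline whose exact
  parameters are not published; they are defaults, not reconstructions.
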