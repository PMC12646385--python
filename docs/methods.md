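# Methods

This note documents the models, defaults and numerical choices behind
`sdgeval`, what the cohort simulator does and does not emulate, and the
known limitations of each stage.

## Study design encoded by the pipeline

One experiment is: simulate (or load) a population; freeze one random
train/holdout split per dataset (the split is a function of the dataset
id and master seed only, so every variant of a dataset trains on the same
records); build variants by adding adjunct subsets to the core; fit each
generator on each variant's training table; sample an ensemble of
replicate synthetic datasets; project replicates to the core subset for
fidelity and utility; run the membership attack on both the core and the
full (core + adjunct) scope; finally model each metric as a function of
the adjunct count k with dataset-level random intercepts and slopes.

Defaults mirror the full-scale design: 10 000 training and 10 000
holdout records (a 50:50 split), 10 replicates per fitted generator,
significance level 0.05.  Tests and the acceptance script run scaled-down
configurations (e.g. 2 000-record cohorts, 3 replicates, training and
holdout of 1 000 each); those sizes are the package's smoke-scale
choices and are stated where used.

### Seeding

Every stage derives a child seed from the master seed plus a token tuple
(module, dataset, generator, variant, replicate) via SHA-256
(`sdgeval._seeding.child_seed`).  Identical master seeds reproduce every
artifact bit for bit; no stage shares a stream with another.

## Cohort simulator

The simulator emulates the stated structural properties of restricted
cross-sectional medical datasets: 6–20 core predictors, adjunct pools of
configurable size, mixed categorical/continuous types, outcome imbalance
anywhere in (0, 1) (the motivating datasets span 51/49 to 99/1), missing
values, and both redundant and independent core↔adjunct dependence.

- **Dependence backbone: Gaussian copula.** Core predictors are latent
  standard normals with correlation matrix R (default: exchangeable
  ρ = 0.3).  A configurable fraction (default 0.5) is discretised into
  2–5 equal-mass quantile bins to form categoricals.  The copula gives
  controllable core-core and core-adjunct dependence with a single PSD
  matrix.
- **Outcome.** Bernoulli with logit linear in the *latent* core values;
  the intercept is calibrated by 1-D Gauss–Hermite quadrature plus a
  Brent root-find so the marginal prevalence matches the requested value
  exactly in expectation (βᵀZ is univariate normal, so no Monte-Carlo
  calibration error).
- **Adjunct modes.** `independent` (pure noise), `redundant` (noisy copy
  of one core variable; when the source is categorical the adjunct uses
  the same quantile discretisation after rescaling, so a noiseless copy
  attains NMI 1), `informative` (noisy linear combination of core
  latents).  The default pool mixes these 2:1:1.
- **Missingness: MCAR** at a configurable rate (default 5%) on all
  non-outcome columns.  No mechanism beyond MCAR is implemented; real
  health data is often MAR/MNAR, so missingness-sensitive conclusions do
  not transfer automatically.
- **Flags.** The first `qi_count` non-outcome variables are marked as
  quasi-identifiers; the first continuous core predictor is the
  parameter of interest, with its generating coefficient recorded in the
  ground truth for recovery tests.

What the simulator does **not** emulate: real marginal shapes (skewed
labs, heaped ages), MAR/MNAR missingness, hierarchical record structure,
and measurement error.  Passing tests therefore demonstrate that the
pipeline's machinery is correct and well-calibrated on data with known
structure — not that any real dataset would yield the same effect sizes.

## Variants

Pools up to the enumeration cap (default 12 → 4 096 subsets) are fully
enumerated, including the empty core-only subset (so a pool of size m
yields 2^m variants).  Larger pools are sampled per adjunct count k: the
number of distinct subsets at k is `min(max(target(k), 5), C(m, k))`,
with exactly one variant at k = 0 and one at k = m.  The default target
is proportional to log₂ C(m, k), giving more samples where the
combinatorial space is larger; any callable over k can replace it.  An
optional Halton low-discrepancy sampler draws combination ranks more
evenly across the space (subsets are unranked via the combinatorial
number system).

## Generators

- **Sequential decision trees.** Variable 1 in the visit order (default:
  schema order, outcome last) is bootstrapped from its marginal; each
  later variable is modelled by a CART (classification for categorical,
  regression for continuous; min leaf 5, unlimited depth) on its
  predecessors, and synthesis draws *donor* training values from the
  reached leaf.  Donor sampling keeps continuous values in the training
  support.  Missing values: categoricals carry an explicit missing
  category; a continuous column's donor pool retains the NaN of training
  rows that reach the same leaf, so missingness is reproduced
  conditionally on the predecessors (the regression tree itself is fitted
  on observed rows only).
- **Bayesian network.** Continuous columns are discretised into
  equal-frequency bins (default max 8; missing is an extra state);
  structure is the Chow–Liu maximum-spanning tree on pairwise mutual
  information rooted at the first column; CPTs use add-α smoothing
  (α = 0.5); sampling is ancestral; continuous values re-materialise
  uniformly within the sampled bin's observed training range.
- **Independent marginals** bootstraps each column separately (missing
  cells included), destroying the joint — a fidelity floor and privacy
  near-ceiling baseline.
- **Copy** bootstraps whole training rows.  It exists to calibrate the
  membership attack (it should be the most vulnerable generator) and as
  a TSTR reference; it is not a release candidate.
- Deep tabular models (GANs, VAEs, flows, adversarial random forests)
  are out of scope; `register_generator` accepts any object following the
  fit/sample contract.

## Fidelity

Records are encoded (one-hot categoricals with an explicit missing
level; continuous standardised by the pooled mean/sd with mean-fill plus
a missingness indicator) and pooled; k-means (G = 20 by default, 10
restarts, fixed seed) clusters the pool.  The score is
1 − U/(c(1−c)) with U = Σ (n_j/n)(p_j − c)²; the size weights make the
c(1−c) normalisation exact, so the score is always in [0, 1].  Centers
are fitted on a lexicographically sorted copy of the pooled matrix, so
the clustering depends only on the multiset of records — this makes the
score invariant to swapping the real/synthetic arguments at equal sizes
and independent of row order.  In the pipeline the "real" side is the
holdout half, keeping the fidelity reference disjoint from the records
the generator saw.

## TSTR

AUROC on the real holdout, averaged over replicates.  The GBM spec uses
LightGBM (deterministic, single-thread) with an optional 5-fold CV grid
(≤ 24 combinations) optimised for AUROC; the MLP spec is a fixed
(32, 16) network with early stopping and no grid search.  Categoricals
are integer-coded for the GBM (LightGBM handles NaN natively) and
one-hot for the MLP, with imputation statistics fitted on the synthetic
training replicate only so the holdout never leaks into training.
Replicates whose synthetic outcome collapses to one class are recorded
as missing with a warning; a single-class holdout is an error.

## Replicability

Logistic regression (statsmodels MLE) on complete cases with dummy-coded
categoricals; Wald SE and CI for the flagged coefficient; separation and
non-convergence raise a distinguishable failure.  Combining rules over m
replicates: q̄ = mean, w̄ = mean squared SE, b = between-replicate
variance, T = w̄ + b/m (the partial-synthesis form, never negative), CI
via a t reference with Barnard–Rubin-style df (m−1)(1 + w̄/(b/m))²,
normal when b = 0.  The fully-synthetic variance rule is available via
`rule="full"`.  Agreement metrics follow the literal definitions:
decision = same sign and same significance status (CI excludes 0);
estimate = synthetic point inside the real CI; standardized difference =
|Δq|/√(SE²+SE²) ≤ z₀.₉₇₅; overlap = the average of the intersection
length as a proportion of each interval, truncated at 0.  In the
pipeline the "real" estimate is fitted on the training half — the data
the generator actually saw — which is the sharpest replicability
question; the holdout would answer a subtly different one.

## Membership attack

The attack sample (default min(1000, n/10) targets, member fraction
p = 0.5) is matched against synthetic records on the compared columns:
equality for categoricals (missing is a matchable state), a tolerance of
0.05 pooled SD for continuous, up to h mismatches allowed (default 0).
The naive predict-all baseline has F1 = 2p/(1+p); relative F1 =
max(0, F1 − 2p/(1+p)), with 0.2 as the conventional acceptance
threshold.  With p = 0.5 the baseline is 2/3, so a perfect attack scores
relative F1 = 1/3 — the statistic is bounded well below 1 by design.
Matching uses hashed exact keys when h = 0 and all compared columns are
categorical, and a vectorised mismatch-count scan otherwise; a
brute-force matcher in the tests verifies both paths.  Attack
parameters are reconstructions (the convention, not a published recipe)
and are all config-exposed.

## Dependence diagnostic (NMI)

NMI(X, Y) = I(X;Y)/√(H(X)H(Y)) on pairwise-complete observations,
continuous variables discretised into 10 equal-frequency bins.  Plug-in
entropies without bias correction: at n = 50 000 the independence floor
is ≈ 0.01–0.02, which is why the simulator tests use that threshold.
Constant variables have zero entropy; their NMI is defined as 0 with a
warning.

## Effect models

Linear mixed models (statsmodels MixedLM, ML) with random intercept and
slope per dataset.  Optimisation tries BFGS, then Powell, then L-BFGS,
then an uncorrelated intercept/slope structure — the unstructured fit
with these scale-disparate variance components (intercept SDs of 0.05
against slope SDs of 0.0005) is exactly where default optimisers stall.
P-values use a between-within t reference with df = (number of
datasets − 2): the slope is a dataset-level contrast, so its effective
df is tied to the number of datasets, not observations.  This is the
standard small-sample stand-in for a Satterthwaite computation, which
the backend does not provide; simulation at 12 datasets puts the type-I
error of the slope test at roughly 3–7% against ~7–10% for a normal
reference.  CIs: likelihood profile by response shifting (fixing the
slope at β₀ is equivalent to refitting y − β₀k with an intercept-only
fixed part), inverted against χ²₁; Wald-t fallback on profiling failure,
with the method recorded in the output.

Binary agreement metrics use a binomial-logit GLMM with random intercept
and slope fitted by variational Bayes (statsmodels
`BinomialBayesMixedGLM`); the fixed effect is reported as an odds ratio
with Wald-style intervals from the posterior SD.  The VB posterior is
known to understate uncertainty somewhat, so these intervals are mildly
anticonservative; the fitting method is recorded in every estimate.

Before modelling, continuous metrics are averaged over replicates within
each variant (the `variant_id` column keeps variants with equal k
distinct); binary agreement metrics are already variant-level and pass
through.

## Known limitations

- MCAR-only missingness in the simulator.
- The VB binomial GLMM's intervals are approximate (see above).
- The membership attack's parameters and the relative-F1 form are
  conventional reconstructions; absolute vulnerability numbers should be
  compared within a run, not across implementations.
- The cluster-fidelity encoding treats all one-hot columns and
  standardised continuous columns with equal weight; variables with many
  categories implicitly weigh more.
- No longitudinal or repeated-measures support; single binary outcome
  only.
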