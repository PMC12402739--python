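# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the simulated populations do and do
not emulate, and the numerical conventions that matter for reproducing a
run.

## Problem setting

A generator *G* is trained on a sample *T* drawn from a population variant
*P* (all records of a reference population, restricted to a column subset)
and emits synthetic datasets *S*.  A synthetic record is a **hallucination**
when it does not exist anywhere in *P* — a factuality violation, judged
against the population rather than the training sample, so that legitimate
diversity (records in *P \ T*) is not penalized.  The pipeline quantifies
(1) how the structural complexity of the training data drives the
hallucination rate and (2) whether the hallucination rate degrades the
utility of the synthetic data for a downstream prognostic task.

## Simulated reference populations

Real individual-level health tables of the kind this analysis targets are
dominated by categorical variables; a handful of "core" variables carry a
predefined binary outcome, and a large pool of "adjunct" variables ranges
from binary flags to long-tailed code lists.  `synth_population` emulates
that structure:

* Categorical variables draw from explicit weights, uniform weights, or a
  truncated Zipf law (default exponent 1.2) for long-tailed high-cardinality
  codes.  Numeric variables (kept a minority; suite defaults ≥ 80%
  categorical) are normal mixtures.
* The outcome is Bernoulli with logit P(y=1) = β₀ + Σ βⱼ xⱼ over designated
  signal variables (level index for categoricals, raw value for numerics).
  An optional prevalence target is met by shifting the intercept via
  bisection.
* Missingness is injected completely at random per variable (no mechanism
  is asserted for real data; MCAR is the testable default) and never in the
  outcome or the record id.

What this does **not** emulate: the content of any real dataset (joint
dependence structure beyond the outcome model, informative missingness,
event-level records).  Passing tests demonstrate the pipeline's correctness
and the direction/detectability of effects under controlled structure, not
empirical rates for any specific real population.

## Variants, split, and complexity

A variant keeps every record and the core columns, adding a sampled adjunct
subset.  The sampler stratifies the target subset size v over a log-spaced
grid from 0 to m (uniform v-subset per stratum, duplicates rejected, the
core-only variant always included); tiny pools (m ≤ 5) are enumerated
exhaustively.  This is an explicit stand-in for a weighted sampling scheme
whose purpose is coverage of the complexity range without combinatorial
blow-up (with m = 100 the full space is 2¹⁰⁰ ≈ 1.27 × 10³⁰ subsets).

One train/holdout split of fixed sizes (defaults 10,000/10,000) is drawn
per population on record ids and reused by every variant, so differences
across variants are attributable to the column set alone.

Complexity is C = log Σⱼ cⱼ with cⱼ the cardinality of variable j measured
on the canonical matching form: observed levels for categoricals, occupied
bins for numerics, plus one level when missing values occur.  Natural log
by default and configurable — the base only rescales the axis, leaving
every monotone relationship and mixed-model sign unchanged.  Cardinality is
measured on the variant's full record set (configurable to training scope).

## Generators

**Sequential decision trees (ST).**  Variables are visited in a fixed order
— core variables first with the outcome last among them, then adjuncts in
schema order (configurable).  The first variable keeps its empirical
marginal; each later variable is modeled by a CART tree (minimum leaf size
20, no depth cap) on the previously visited variables, and sampling draws a
donor value uniformly from the training records in the destination leaf.
Outcome-last keeps the predictive relationship conditioned on the features.

**Chow–Liu Bayesian network (BN).**  Pairwise empirical mutual information
over the discretized variables; maximum-MI spanning tree (a tiny positive
shift keeps exact-zero-MI edges in the graph, so the result is always a
tree; genuinely disconnected components are sampled independently);
Laplace-smoothed CPTs (α = 1) rooted at the first variable in the schema;
ancestral sampling.  Smoothing never invents a missing level for a variable
with no missing values in training.

Both built-ins synthesize numerics on a discretized scale (equal-width bins
fit on the training data, default 10) and back-transform by sampling
uniformly within the sampled bin — aligning generation with the exact-match
convention of the audit.  Every categorical value sampled by a built-in is
a training-observed level.  Replicate r of a trained generator uses a
deterministic sub-seed derived from (seed, r).

Other families participate through `register_plugin(name, fit_fn,
sample_fn)`; replicate assembly rejects schema or row-count violations.

## Hallucination audit

Records are canonicalized before matching: numerics become bin labels on
edges fixed from the population variant (left-closed/right-open, last bin
closed, dedicated below/above-range bins), missing values become a sentinel
token that matches itself, categoricals are compared as strings, and every
column of the variant — outcome included — participates (a record is a full
row).  Hallucinated rows are found by a row-wise antijoin of the canonical
tables; a quadratic minimum-Hamming-distance implementation is kept as an
independent oracle and must agree exactly (tested on hundreds of random
fixtures).  HR is reported per replicate and as the across-replicate mean;
the effect models consume the mean.

The bin count is a first-class knob because it changes what counts as an
exact match: finer binning can only raise the HR (tested as a monotonicity
law, together with column-set monotonicity and the HR ∈ {0, 1} boundary
cases).

## Downstream utility

The task is binary classification on the core variables.  TSTR trains one
classifier per synthetic replicate and scores AUROC on the fixed real
holdout (replicates with a single-class outcome are recorded as missing and
excluded from the mean, with a warning); TRTR uses the real training rows.
Holdout ids never enter generator or classifier training (asserted at run
time).  Because TRTR depends only on the shared core columns, the pipeline
computes it once per population per learner and reuses the value across
variants.

* **GBM**: LightGBM; hyperparameters by mean 5-fold CV AUROC over a small
  grid (learning rate {0.05, 0.1}, leaves {15, 31, 63}, estimators
  {100, 300}; configurable, and a single-combination grid skips CV), refit
  on all training rows.  Categoricals are integer-coded against training
  levels with native categorical handling; unseen levels map to the missing
  code.
* **MLP**: two hidden layers of 16 units with a sigmoid output (scikit-learn
  `MLPClassifier`), one-hot categoricals (missing as its own category),
  median-imputed and standardized numerics with missingness indicators.
  Overfitting is controlled by early stopping on a 10% validation split
  (patience 10, ≤ 100 epochs) plus a small L2 penalty, in place of a
  dropout layer, which the underlying library does not provide; on the test
  fixtures this matches the GBM within a few AUROC points and tracks the
  closed-form Bayes AUROC within 0.03.

AUROC is the rank-based (Mann–Whitney) statistic with ties averaged.

## Effect models

The unit of analysis is one row per population × variant × generator.  The
reference population is a random intercept in both models — each population
has its own distribution, core set and task, so its observations share an
offset.

**HR ~ complexity** is a binomial-logit random-intercept GLMM on the
aggregated hallucinated counts (successes out of k × |S| trials per trained
generator).  Aggregated counts handle HR = 1 boundaries without ad-hoc
corrections.  The marginal likelihood factorizes over populations into
one-dimensional integrals, evaluated by adaptive Gauss–Hermite quadrature
(15 nodes centered at the per-group Laplace mode); the fixed effect is
reported as an odds ratio per complexity unit with Wald 95% CIs from the
numerical Hessian.  Calibration is verified by simulation: nominal (93–97%)
CI coverage under the null and at the study's effect scales (OR 1.10 per
unit; slope −0.0002 per HR percentage point).  An independent cross-check
against lme4's Laplace fit agrees on coefficient and SE.

**TSTR ~ HR** is a linear random-intercept model (REML, Wald CIs) with HR
in percentage points, so the slope reads directly as AUROC change per
percentage point of HR.  Only populations with P90 − P10 HR spread ≥ 0.25
across their variants enter (per generator; linear-interpolation
percentiles) — without spread the slope is unidentified.  When a single
population survives the filter, OLS is used and conditional R² equals
marginal R².

**R²** follows the variance-decomposition convention: marginal =
var(fixed predictor) / total, conditional = (fixed + random) / total, with
residual variance π²/3 on the latent scale for the binomial-logit model.
Wald rather than profile CIs are used throughout for speed at desk scale;
the estimation method is recorded in each estimate.  Significance is
assessed at α = .05 with no multiplicity adjustment across generator
families.  Subset sensitivity refits both models on random 50% / 25%
per-population subsets of the variants.

## Seeds, determinism, and problem sizes

A single master seed fans out through named `SeedSequence` paths
(population / split / plans / generator / replicates / learner), so any
stage is reproducible in isolation and a full run is bit-reproducible.
The bundled `scaled_study_config` runs two simulated populations × 20
variants × both built-ins × 3 replicates of 2,000 records with a
single-combination GBM grid — sized so the complexity gradient spans HR ≈ 0
to HR = 1 and the whole run finishes in minutes on one CPU; simulation-based
calibration checks use 200 replications per condition.  Degenerate inputs
are handled explicitly: constant training tables resample the observed
record; all-missing columns carry the single missing level and are flagged;
empty replicates, single-class outcomes, single-group random effects and
non-convergent fits raise informative errors rather than returning silent
results.

## Known limitations

* The simulated populations are structural stand-ins; absolute HR levels
  and AUROCs depend on the simulated law and do not estimate any real
  dataset's values.
* The adjunct-subset sampler and the GLMM family/link, CI method, and
  percentile rule are declared package conventions, documented above and in
  the estimates' provenance fields.
* Exact-match hallucination is deliberately strict: it ignores semantic
  closeness and constraint violations, and the numeric bin count changes
  what counts as a hallucination (hence the monotonicity guarantees and the
  exposed knob).
* The deep-learning generator families are supported only through the
  plugin contract, not re-implemented.
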