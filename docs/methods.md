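# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the known limitations of `usvsyntax`. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

A *session* is the ordered list of calls one pup emits during a 5-minute
recording at one age (P8 or P12), each call annotated with one of 12 type
codes and per-call acoustic parameters (at minimum duration in ms and
MaFmi, the maximum frequency minimum of the call, in kHz). Sessions are
treated as single sequences; no bout segmentation by inter-call interval is
applied (the annotation tables carry no interval information, and the
transition statistics are therefore conditional on "next call in session").
Behavior records hold two social-interaction session times and sniffing
times for 7 odorants x 3 trials, all in seconds and bounded by the session
length (300 s by default).

The inclusion filter keeps pups with **more than ten calls** at the
analysis age (default P8), read strictly: 10 calls exclude, 11 include.
Genotype is coded WT = 0, DEL = 1 wherever a number is needed; the deletion
genotype is the positive class throughout.

### Dependent variables

`social_interaction` = Session 1; `social_habituation` = Session 1 −
Session 2; `olfactory_response` = Trial 1 of the urine odorant (default
`Ur1`, configurable — the choice of which urine stimulus defines the
response is a free parameter of the analysis, not of the data);
`olfactory_habituation` = Trial 1 − Trial 3. Habituation scores may be
negative. Missing trials yield NaN; nothing is imputed.

## Sequence features

Per pup: 12 type counts, 12 type ratios, 144 transition counts, 144
transition conditional probabilities, acoustic means, genotype — 315
columns by default. A transition probability for a source type never
emitted (or emitted only as the final call) is **0, not missing**: the
absence of a transition is informative, and the selection models require a
complete matrix. Acoustic summaries are per-pup means over all calls (a
per-call-type breakdown is not emitted by default). Counts are left
unstandardized in the matrix; standardization is done inside each model.

Feature names follow the field convention — `U(R)`, `Fs→D(#)`, `Fs→D` —
with an ASCII `->` rendering available for file headers.

## Entropy orders

H0 = log2(number of distinct types used); H1 = plug-in Shannon entropy of
the type frequencies; for k ≥ 2, Hk = plug-in conditional entropy of the
next call given the preceding k−1 calls, computed from the sequence's
k-gram counts with 0·log 0 = 0. Log base 2 throughout. No small-sample
bias correction is applied: the inclusion filter bounds sequence length
from below, and the plug-in estimator keeps the worked arithmetic exact
(e.g. a deterministic alternation has H2 = 0 exactly).

A caveat that matters for property testing: because each order's k-gram
table spans a slightly different window of positions (a length-n sequence
has n−k+1 k-grams), the chain-rule inequality H1 ≥ H2 ≥ H3 ≥ H4 is **not a
theorem** for these per-order plug-in estimates. The shortest
counterexample is the sequence A,A,B: H1 = 0.918 but H2 = 1.0. On random
12-symbol sequences of lengths 11–200 the violation rate is roughly 0.2–0.3%
per sequence, always driven by contexts observed once or twice near the
sequence boundary. The estimator follows the worked definition (which the
degenerate and alternating examples pin down) rather than a wrap-around
(cyclic) counting scheme that would restore monotonicity but would insert
an artificial last-call→first-call transition.

Genotype comparisons of entropy use the two-sided Mann–Whitney test per
(order, age) cell with BH correction across the 5x2 family. This is a
deliberate nonparametric simplification; mixed-model (REML) comparisons of
group means are out of scope for this package.

## Markov models and frequent connections

Per (genotype, age): transition counts pooled over pups, row-normalized to
the MLE transition matrix (rows with no occurrences stay all-zero).
"Most frequent call connections" is operationalized as the `top_k = 8`
edges by conditional probability among edges with pooled count
≥ `min_count = 5`; ties break by count, then alphabet order, so the edge
list is deterministic and invariant to pup ordering. Both thresholds are
configurable — a figure-style edge rendering has no canonical cutoff.

## Sparse PLS-DA

Standardized X (transition probabilities) against the centered one-hot
class matrix. Per component the loading vector is the dominant left
singular vector of XᵀY, soft-thresholded to at most `keep_x` nonzero
entries (threshold = largest excluded magnitude) and renormalized to unit
norm; X is deflated on the component score. Sign convention: first nonzero
loading positive. With `keep_x = all` this reduces exactly to PLS-DA
(verified against an SVD oracle). Degenerate cases are handled explicitly:
if the deflated cross-covariance is numerically zero (class structure fully
explained by earlier components) the component sequence is truncated, and
an exact magnitude tie under soft-thresholding falls back to hard
thresholding. Default labels are genotype with samples pooled across ages,
so a developmental axis can emerge on component 1.

## Lasso paths and the selection rule

Predictors are standardized internally; coefficients are reported on the
standardized scale. The λ grid is log-spaced, 100 points, from λ_max (the
smallest penalty with an all-zero solution) down to λ_max·10⁻³. The
fraction of deviance explained is 1 − dev(λ)/dev(null) (R² in the gaussian
family). The **selected set** contains the features already nonzero at the
first grid point where this fraction reaches the cutoff (default 0.25),
each tagged with the fraction of deviance explained at its own path entry;
smaller entry values (larger λ) mark the more robust predictors. Genotype
is a penalized candidate like any other column in the behavioral models.

The gaussian path uses coordinate descent (tolerance 1e-12, which the
orthonormal-design soft-threshold closed form requires). The binomial path
(genotype as response) minimizes (1/n)·neg-loglik + λ‖β‖₁ with an
unpenalized intercept by accelerated proximal gradient (FISTA) with warm
starts along the grid; on separable data at very small λ the minimizer is
unbounded and the iteration cap acts as the usual path truncation.

A statistical note on planted-effect recovery at the study's scale: with
n = 19 observations and ~283 candidate features, the expected maximum
spurious absolute correlation of a pure-noise feature is ≈ 0.8, which
rivals the population correlation (≈ 0.71) of a planted standardized unit
effect with unit noise. Selection of the planted feature at the 0.25
cutoff therefore succeeds in roughly 85–90% of replicates and
first-entry in roughly 65–80%, with seed-to-seed wobble of a few percent —
an intrinsic property of that design, not of the solver (which matches the
closed form to machine precision).

## Random-forest evaluation

A single seeded forest (default 1000 trees) is evaluated **out-of-bag**:
each sample is classified by majority vote of the trees that did not draw
it. OOB evaluation was chosen over cross-validation because it needs one
fit, is deterministic under the seed, and is the standard error estimate
for random forests. From the confusion matrix (positive = DEL):
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy = (TP+TN)/N.
Accuracy is tested one-sided against the no-information rate
(majority-class frequency) by exact binomial. The sensitivity-vs-
specificity contrast uses McNemar's test on the discordance between true
class and correctness — b = misclassified DEL, c = misclassified WT — an
unusual construction, so both raw counts are exposed for audit.

McNemar: the continuity-corrected statistic (|b−c|−1)²/(b+c) is always
reported; the p-value uses the χ²₁ tail when b+c ≥ 25 and the exact
two-sided binomial(b+c, ½) tail otherwise; b = c = 0 returns p = 1 flagged
degenerate.

## Stratified prediction and the path graph

Each (feature, behavior) pair is fit by OLS separately within each
genotype stratum with at least 4 complete pairs; zero-variance features in
a stratum are skipped with a warning. BH correction is applied within each
behavior's family of tested (feature, stratum) fits. Significance tiers for
the path rendering use the **raw** fit p (matching the figure-legend
convention of x/2x/4x line weights at p<0.05/0.01/0.001); BH-adjusted
values are always reported alongside in the same table so both views are
available. The path-summary tables carry call→call edges weighted by
pooled transition probability and feature→behavior edges for
significant-tier fits only.

## Exact small-sample tests

Mann–Whitney: exact enumeration when n_a·n_b ≤ 400 and the pooled data are
tie-free; otherwise a tie-corrected normal approximation with continuity
correction. The exact binomial test uses the minimum-likelihood two-sided
convention. BH adjustment is the standard step-up; note that re-applying
the adjustment to its own output inflates values (adjusted p-values are
not a fixed point of the procedure) — the invariant that holds, and that
the tests assert, is that thresholding the adjusted values at any α
reproduces the step-up rejection set.

## Synthetic-data generator

The generator is the package's study-conditions model, not a tuning dial:

- **Cohorts**: 33 WT and 16 DEL pups by default (the P8 analysis cohort
  sizes), each recorded at P8 and P12.
- **Sequences**: first-order Markov chains per (genotype, age) over the
  12-type alphabet. Default matrices are uniform with a set of boosted
  edges (weight 7 vs 1 before row normalization): at P8 the boosted sets
  differ by genotype (each group's frequent connections plus shared ones);
  at P12 both genotypes share one softer set, creating the developmental
  contrast. Uniform start distribution.
- **Lengths**: negative binomial, mean 60, dispersion 5, floored at 1.
  The recordings are fixed 5-minute sessions, so any length model is a
  modeling choice; the negative binomial captures the overdispersed call
  counts of real litters and is configurable.
- **Acoustics**: per-call-type normal (mean, sd); durations 12–60 ms by
  type (floored at 0.5 ms), MaFmi 55–72 kHz.
- **Behavior**: each derived dependent equals baseline + Σ beta·feature
  (effects applied only within their stated genotype) + N(0, noise sd).
  Session/trial components are back-solved (s2 = s1 − habituation, urine
  Trial 3 = Trial 1 − habituation) so the derived variables equal the
  planted linear model exactly, then clipped to [0, 300] s; the floor
  mimics the assay's bounded times and binds only in extreme
  configurations (never in the noiseless case the tests use). Filler
  trials (other odorants, Trial 2) are baseline-decay plus noise.
- **Reproducibility**: every pup draws from a counter-based substream
  keyed by (genotype, pup index, lane) under the global seed, so enlarging
  a group never perturbs previously generated pups.

What the generator does **not** emulate: within-session nonstationarity
(bout structure, drift in call rate), litter and dam effects, correlated
acoustic parameters within calls, missing behavioral data patterns, and
any coupling between acoustics and sequence structure. Passing tests
therefore certify the statistical machinery under the stated generative
model, not the biology of any particular dataset.

## Pipeline and determinism

`run_pipeline` executes filter → features → entropy → Markov → sPLS-DA →
Lasso (4 gaussian responses + binomial genotype) → random forest →
stratified regressions → path summary, writing plain CSV per stage and a
JSON manifest with parameters, seeds, row counts and SHA-256 checksums of
every output. The pipeline is a pure function of (inputs, config): reruns
are byte-identical, which the test suite asserts.

Problem sizes in the verification suite (1,000 sequences for the entropy
oracle, ≥ 5x10⁴ pooled transitions for Markov recovery, 200 replicates for
selection/power studies, 100–200 forests for OOB calibration) were chosen
to keep Monte-Carlo standard errors small relative to the properties being
checked while the whole suite runs in minutes on one CPU.

## Known limitations

- Entropy orders are plug-in estimates; for very short sequences the
  higher orders are strongly downward-biased, and the monotonicity caveat
  above applies. A Miller–Madow-style correction is not implemented.
- The binomial Lasso path truncates rather than diverges on separable
  data; coefficients at the smallest penalties are then iteration-capped.
- The McNemar construction for sensitivity-vs-specificity treats the two
  error sets as paired discordances, which is a reconstruction of an
  under-specified procedure; the raw counts are exposed so users can apply
  an alternative.
- Per-pup acoustic summaries are means only; distributional acoustic
  features (percentiles, variances) are not extracted.
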