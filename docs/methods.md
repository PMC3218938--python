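# Methods

`fovsample` answers a sampling-design question for quantitative
immunofluorescence (AQUA-style) biomarker assays on tumor sections: **how
many 20X fields of view (FOVs) must be scored so that their average is a
representative measurement of the whole section?** It implements three
stages — between-run normalization, mixed-effects quantification of
intra-tumor heterogeneity, and cross-validated selection of the field
count — plus a synthetic-cohort generator that makes every stage testable
without clinical data.

## The data model

The universal input is a long table of per-FOV scores keyed by subject,
region of interest (ROI) and field. Scores are nonnegative reals on an
arbitrary fluorescence scale (intensity per unit masked area, normalized to
exposure time). ROI labels are optional per cohort: some archives never
recorded which ROI a field came from, and such tables are accepted
everywhere except the mixed-model stage, which needs the ROI level to
separate variance components. Sampling and per-subject summaries always
pool a subject's FOVs across ROIs — the field, not the ROI, is the sampling
unit.

## Synthetic cohorts

The generator simulates the three-level random-intercept model forward:

    y_ijk = β₀ + b_i + b_ij + ε_ijk,
    b_i ~ N(0, σ²_subject),  b_ij ~ N(0, σ²_roi),
    ε_ijk ~ N(0, [σ_resid · (μ_ij/β₀)^δ]²),   μ_ij = β₀ + b_i + b_ij.

Parameters (score units): `beta0` — grand mean (default 50, a mid-range
AQUA-like score); `sigma_subject` (default 10, i.e. 20% between-tumor CoV);
`sigma_roi` (default 3) and `sigma_resid` (default 5), together an
intra-tumor CoV of ~12%, mid-range for the markers this kind of assay
targets; `het_power` δ (default 0) turns on the power-of-the-mean variance
function — the standard choice when residual spread grows with expression
level, as residual-vs-fitted plots of real immunofluorescence data show.
Draws follow a fixed order (subjects, then ROIs, then fields) from a single
seeded generator, so a spec and seed reproduce a table exactly. Scores are
truncated at zero rather than resampled, and the truncated fraction is
reported in the table's metadata; with β₀ well above the total SD it is
negligible.

What the generator deliberately does **not** emulate: spatial
autocorrelation between neighboring fields, mixtures of marker-positive and
-negative tumors, per-subject differences in field counts beyond what the
caller specifies, and non-normal score distributions. Conclusions drawn
from synthetic cohorts are conclusions about the exchangeable-normal
hierarchical world; see "Scale invariance of the selected field count"
below for a case where this matters.

## Between-run normalization

Scores from different staining runs drift (bulb hours, reagent lots). Each
run also stains a shared control array ("index array"); normalization
proceeds in three steps:

1. **Quantile normalization** of the matched index-array vectors. The
   common distribution is the mean of the per-run quantile functions on a
   common probability grid (with complete data: the row means of the
   column-sorted matrix). Ties receive the mean of the target values at
   their tied ranks; missing cores are handled by interpolating that run's
   quantile function from its non-missing entries rather than deleting the
   core from every run.
2. **Transfer-function fit** per run: a cubic smoothing spline from the
   run's original index scores to its quantile-normalized scores, penalty
   chosen by generalized cross-validation (overridable). The fitted curve
   is evaluated on a dense grid and isotonized, so the final map is
   guaranteed monotone — a higher raw score can never normalize below a
   lower one.
3. **Application** to the run's subject scores. Inputs outside the fitted
   index range extrapolate linearly with the boundary slope; the count of
   extrapolated points is reported rather than treated as an error.

The baseline run is user-designated (default: first run in file order,
echoed in the log).

## Intra-tumor heterogeneity

The three-level model above is fit by REML — restricted likelihood because
the variance components themselves are the target. The homoscedastic fit
goes through statsmodels' `MixedLM` with a nested-ROI variance component.
The heteroscedastic fit (residual SD ∝ (fitted/β₀)^δ with δ estimated) is a
profiled REML implemented in this package: subjects are independent blocks,
so the likelihood is evaluated per-subject via Cholesky factors of
σ²_s11' + σ²_r·blockdiag + σ²_e·diag(w²); the weights w depend on the
conditional ROI means, which are refreshed from the current BLUPs between
optimization passes (four passes by default — the same alternation
variance-function mixed-model software uses).

The headline statistic is the **intra-tumor coefficient of variation**

    CoV = 100 · sqrt(σ²_roi + σ²_resid) / β₀   [percent],

within-tumor components only. Between-subject variance measures how tumors
differ, not how heterogeneous one tumor is, so it is excluded by default;
`include_subject=True` exists for sensitivity analysis. Tables without ROI
labels raise a structured error — the intra-tumor decomposition is simply
not identified for them.

Confidence intervals come from a parametric bootstrap: simulate cohorts
from the fitted components with the table's exact subject/ROI/field layout,
refit, take 2.5/97.5 percentiles. Two refit engines are offered: `"reml"`
(the full fit; default) and `"anova"` — the closed-form balanced
nested-ANOVA moment estimators, which coincide with REML on balanced
designs whenever no component truncates at zero and are orders of magnitude
faster, making coverage experiments affordable. Measured calibration on
balanced 12-subject cohorts: 48/50 replications covered the true CoV at
nominal 95%.

## Field-count selection

The core procedure asks, for each candidate field count m (default 1..35):
how well does the average of m sampled fields predict the whole-section
average ȳ_i (the subject's "true" score)? Two resampling layers separate
model selection from error estimation:

* **Outer layer** — prediction error. Either 10-fold cross-validation over
  subjects (`kfold_mc`) or leave-one-out (`loo_boot`). Per fold, a simple
  linear regression of ȳ on the m-field average x̄_m is fit on the training
  subjects (one fresh draw of x̄_m per subject) and scored on the held-out
  subjects: PE(m) = (1/N) Σ (ŷ_i − ȳ_i)².
* **Inner layer** — model selection inside each training set. `kfold_mc`:
  Monte-Carlo 90/10 learning/evaluation splits; `loo_boot`: bootstrap
  learning sets with out-of-bag evaluation (empty out-of-bag sets are
  redrawn). Each of the `n_inner` (default 1000) iterations draws fresh
  x̄_m for every candidate m, fits the regression on the learning set and
  evaluates PE on the evaluation set. The **first local minimum** of the
  iteration-averaged PE curve is recorded per training set: the smallest m
  with PE(m) ≤ PE(m−1) and PE(m) < PE(m+1), with monotone curves and
  terminal plateaus falling back to the global minimum (smallest index on
  ties — the fewer-fields-is-better reading of an ambiguous boundary).

The average first local minimum over the outer training sets (rounded
half-up) is the *minimum model*; its across-fold standard error of test PE
feeds the **one-standard-error rule**: select the smallest m at or below
the minimum model whose mean test PE is within one SE of the minimum
model's. The whole procedure repeats `n_repeats` times (default 100); the
final recommendation is the rounded mean of the per-repeat selections. Two
stability numbers are reported and explicitly labeled, because they answer
different questions: the SD of the selected m over repetitions (stability
of the estimate) and the across-fold SE of test PE at the minimum (the
quantity the parsimony rule consumed).

Accuracy at the selected m is also summarized by the average absolute
standardized score: mean over subjects of |ŷ_i − ȳ_i| / sd_i, i.e. the
prediction's distance from the truth in units of that subject's own
field-to-field SD (subjects with zero SD are excluded and counted).
Averaging is innermost-first: within an evaluation/test set, then across
folds, then across repetitions.

### Sampling modes

* **direct** — draw m observed FOV scores without replacement; m beyond a
  subject's field count K caps at the full-section mean (the subject stays
  in, as the per-subject K in the PE definition implies).
* **parametric** — draw from Normal(mean_i, sd_i) matched to the subject,
  for cohorts whose subjects have too few fields for honest subsampling.
  `validate_parametric_mode` runs both modes side by side, deriving the
  parametric summaries from a fixed-size random subset of each subject's
  fields, exactly the check one runs before trusting the shortcut on a
  small cohort.

The two modes are *not* interchangeable near m ≈ K: a without-replacement
mean has variance s²(1/m − 1/K), which keeps improving all the way to zero
at m = K, while the normal model's s²/m does not. The inflated late-curve
decrement (factor 1/(1 − m/K)) delays direct mode's first local minimum, so
direct selections run a few fields higher unless K is several times the
largest candidate m or the curves stop early. On a 122-subject
heteroscedastic synthetic cohort with 120 fields per subject the two modes
agreed within one pooled SD; homoscedastic variants with smaller K showed
gaps of 1–1.5 pooled SDs, always with direct higher.

### Numerical and implementation choices

* All inner-loop work is vectorized over iterations and candidate m;
  without-replacement subsets are selected as the m smallest of K uniform
  random keys. Every candidate m gets independent draws within an
  iteration. This is load-bearing, not cosmetic: the first-local-minimum
  rule stops where the PE curve's decrement falls below its Monte-Carlo
  noise, and reusing one sample across m (e.g. prefix means of a single
  permutation) correlates that noise away, driving the selection toward the
  top of the range.
* Degenerate learning draws (zero variance in x̄) fall back to the
  intercept-only regression. Redrawing — the other candidate policy —
  cannot terminate on a constant cohort, where the intercept-only model is
  also exactly right: every PE is 0, the flat-curve tie rules select m = 1.
* One master seed drives a `SeedSequence` tree (per repetition, then per
  fold), so results are exactly reproducible and independent of execution
  order.
* The vectorized engine was cross-checked against a naive scalar-loop
  rendition of the procedure built from the public elemental operations;
  selected-m distributions and PE curves agree within Monte-Carlo error.

### Scale invariance of the selected field count

A finding worth stating plainly, because it bounds what synthetic
experiments can show. Under the exchangeable-normal generator, every
quantity the stopping rules compare scales with the intra-tumor variance
s²: the PE curve is approximately σ²_b·ν(m)/(σ²_b + ν(m)) with sampling
noise ν(m) ∝ s²/m (σ²_b the between-subject variance of ȳ), its Monte-Carlo
noise is proportional to the PE magnitude, and so is the across-fold SE.
To first order in ν/σ²_b the selected m is therefore *invariant* to s — and
the second-order term flattens the early curve for high-s markers, nudging
selection slightly *down*. Paired synthetic experiments confirm this: with
intra-tumor CoV 5% vs 40% on a shared 30-subject design, the higher-CoV
epitope selected a larger field count in only 1/12 (10-fold design) and
0/12 (leave-one-out design) replicates. The expectation that more
heterogeneous markers need more fields — true enough in real cohorts —
must therefore rest on features real data have and this generator
deliberately omits: subjects differing in field counts and in per-subject
SDs, non-normality, and spatial structure. Synthetic cohorts here can
validate the machinery (limits, determinism, concordance, calibration) but
cannot reproduce that ordering.

## Problem sizes

Defaults mirror the canonical design (1000 inner iterations, 100
repetitions, m up to 35). The test suite and the acceptance script run
reduced but structurally identical configurations — typically 200 inner
iterations and 5–10 repetitions on cohorts of 14–200 subjects — chosen so
each experiment's Monte-Carlo error is small against the effect it checks;
the reduced-iteration stability test verifies the reduction is benign.

## Known limitations

* The heteroscedastic REML uses a fixed number of weight-refresh passes
  rather than a joint convergence criterion; on near-degenerate cohorts the
  estimated power has wide sampling error (recovery to ±0.35 at 80
  subjects).
* The bootstrap CI is percentile-based; no BCa correction.
* No spatial model: fields are exchangeable within ROI, ROIs within
  subject.
* Between-block (multi-section) variation is out of scope; a whole-section
  average is treated as the subject's truth, so recommended field counts
  are minimums with respect to deeper sectioning.
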