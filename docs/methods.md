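# Methods

`vocpanel` implements a complete urinary volatile-organic-compound (VOC)
biomarker-discovery analysis for a two-tumor-model mouse study design,
together with a synthetic-data generator that reproduces the statistical
structure such a study assumes. This note records the models, the
defaults and why they were chosen, and what the synthetic studies do and
do not establish.

## Study design and data model

The emulated design is factorial: two tumor models (cell lines injected
into mice, labelled LKR and LLC), each with a tumor and a saline-placebo
group of 25 animals, urine profiled by headspace GC/MS at an early
(pre-tumor, days 1–3) and a terminal collection period, and 47 total-ion
chromatogram peaks shared by every animal. A peak table is the
samples × peaks matrix of peak heights for one (group, timepoint).

Peak heights are treated as log-normal: all effects and noise act
additively on log-intensity. The generator draws the log-intensity of
peak *p* for an animal in model *m*, condition *c*, timepoint *t* as

    mu_p + tau_p·[t = late]
         + (delta_p + gamma_{p,m})·[t = late and c = tumor]
         + eps,   eps ~ N(0, sigma_p²) i.i.d.

* `tau_p` — the **term effect**: drift between the two collection
  periods common to tumor and placebo animals (ageing, husbandry,
  season). Default +0.5 log units on every peak.
* `delta_p` — the shared tumor effect. Default: 11 of 47 peaks carry
  |delta| = 3·sigma, predominantly negative (down-regulation is the
  dominant observed pattern), with 2 of the 11 positive.
* `gamma_{p,m}` — model-specific interaction, summing to zero over
  models so that `delta_p` remains the shared effect (the same
  parameterization the two-way ANOVA estimates). Default: 4 peaks,
  disjoint from the differential 11, with |gamma| = 2·sigma and no
  shared effect — the "opposite response in the two models" pattern.
  The magnitude is set by power: the interaction F-test on subtracted
  values has noncentrality n·gamma²/(2·sigma²); at |gamma| = sigma this
  is ~12.5, giving only ~64% power at p < 0.002 (df 1, 96), whereas
  2·sigma gives ~50 and near-certain detection. Neither magnitude is an
  estimate from real data; both bands are conventions.
* `sigma_p` — log-scale noise SD, default 0.25 (≈25% CV in height,
  typical of replicate headspace-SPME quantification).
* `mu_p` — baselines 4.0 + 0.05·p log units (≈55–550 raw intensity).

Tables are returned on the linear scale, `exp(log-intensity)`.
Generation is bit-reproducible from `(design, effects, seed)`.

The cubic growth fits (`growth_curve`) and the caliper volume formula
`3.14·d·p²/6` (`tumor_volume`, coefficient deliberately the rounded
3.14 of the source convention) are provided for scheduling and
completeness; the analysis itself uses only the two abstract timepoints.

## Chromatogram preprocessing

Raw traces are synthesized (`generate_tic`) as Gaussians on a
retention-time grid plus baseline and optional white noise. Window
detection operates on the point-wise **mean** trace of all samples so
that every animal is quantified over identical windows: local maxima
with prominence ≥ `min_prominence` × (mean-trace max) become centres;
adjacent windows meet at the midpoint between centres and never extend
more than `min_separation` minutes from their centre. Windows are
half-open `[start, end)` to avoid double-counting boundary grid points.
Height is the window maximum. No retention-time warping or co-elution
deconvolution is attempted — the generator never misaligns peaks, so a
passing round-trip says nothing about alignment on real data.

Quantified tables are log-transformed (`ln(v + 1)`; the offset keeps
zero heights finite and is configurable) and row-centred
(`normalize_intensity`) to cancel per-sample loading differences.
Row-centring is part of the raw-trace ingestion path only: the
generator plants no loading variation, and centring rows that contain
systematic tumor effects would leak a small opposite-signed bias into
null peaks. With loading variation absent the correction is a no-op in
expectation, so omitting it for generator-produced tables is the
unbiased choice.

## Term-effect subtraction and screening

For each animal, `R_i = tH_i − eH_i`: the late-stage log height minus
the early-stage log height of peak *i* (per-sample maxima across
collections first, if a stage has several). Any additive change shared
by tumor and placebo groups — the term effect — cancels in the
tumor-vs-placebo comparison of `R`. Note `Var(R) = 2·sigma²`: the
subtraction pays a factor √2 in noise for removing the term effect.

`R` is z-scored per peak over the pooled analysis set of one model
(population SD; zero-variance columns become zeros with a warning).
Screening is a per-peak two-sided Welch t-test at a raw threshold of
1e-4. The source analysis names no test behind its threshold; Welch is
the robust default, with pooled-variance t and Wilcoxon rank-sum
selectable. **No multiple-testing correction is applied** — the
deliberately strict raw threshold stands in for it, mirroring the
original analysis convention; with 47 peaks the expected number of null
false positives is 47 × 1e-4 ≈ 0.005 per study.

## Two-way ANOVA interaction screen

Per peak, the normalized subtracted value is decomposed as
`y = mu + a_i + b_j + (ab)_ij + e` (condition × model, sum-to-zero
constraints). Only the balanced 2×2 layout is supported; the classical
cell-means decomposition is then closed-form and exactly testable
against a least-squares oracle (SS, F, p agree to 1e-8 relative in the
test suite). df = (1, 1, 1, N−4). A peak is "model-specific" when its
interaction p falls below the strict threshold 0.002 (the loose 0.05
list is also reported); the strict threshold controls false positives
over ~47 parallel tests without a formal correction. When all cell
residuals are exactly zero the F statistics degenerate; they are
reported as 0 (no effect SS) or +inf (positive effect SS).

## PCA and the RBF support-vector classifier

PCA centres by column means and takes eigenvectors of the sample
covariance; components are sign-fixed (largest-magnitude loading entry
positive) and requesting components beyond the numerical rank is an
error. The scores-plot analysis projects a model's full analysis set
onto the first two components and classifies scores.

The classifier is a standard soft-margin SVM with Gaussian kernel
`k(x, x') = exp(−sigma·‖x − x'‖²)`. **Convention:** `sigma` multiplies
the squared distance (the kernlab `rbfdot` convention), so sigma = 0.9
equals scikit-learn's `gamma = 0.9`. Defaults sigma = 0.9 and C = 1
(the penalty is not dictated by the source convention and is exposed in
config). Training delegates to libsvm (tolerance 1e-8); prediction is
recomputed in-package from the extracted dual coefficients, bias and
support vectors, making the model a transparent serializable object and
keeping the hot evaluation path free of wrapper overhead. Exact-zero
decision values are assigned +1 with a warning. The dual solution is
checked in the tests against an independent quadratic-programming
oracle (objective within 1e-6) and the KKT conditions.

Sensitivity, specificity and accuracy follow the usual confusion-table
definitions with tumor = positive; a rate whose denominator is empty is
reported as missing, never as 0. ROC-space points are
`(1 − specificity, sensitivity)`.

## Panel search protocols

Candidates are the screened peaks (capped at the 11 smallest p-values).
All `2^p − 1` non-empty subsets are enumerated in lexicographic prefix
order and each is scored under:

* **cv10** — per class, the 25 samples are randomly partitioned into 10
  folds of 2–3 animals; fold *j* of both classes is the test set while
  the classifier trains on the rest. Per-fold confusion metrics are
  averaged (mean ± SEM over folds, SEM = sd/√k); a test fold lacking a
  class contributes nothing to that class's rate.
* **holdout** — 13 training / 12 test animals per class, one random
  split per seed; repeated-seed mode gives mean ± SEM over seeds.
* **transfer** — train on every sample of one model, test on every
  sample of the other; preprocessing is always fitted on the training
  model only.

By default, feature standardization (and PCA when enabled) is fitted on
training samples of each split only — no information leaks from test
folds. The `paper_mode` flag instead pools all samples, reproducing the
common practice of projecting a complete dataset at once; it is off by
default and changes nothing about the protocol otherwise. Panels are
ranked by mean accuracy (desc), then subset size (asc), then mean
sensitivity (desc), then lexicographic peak order; the tie-break chain
beyond accuracy is this package's convention. Enumeration beyond 20
candidates is refused unless explicitly overridden.

## What the synthetic studies do and do not show

Passing tests establish that the pipeline recovers what the generator
plants, at the planted magnitudes, under i.i.d. log-normal noise: they
validate the statistics and the machinery, not the biology. Real GC/MS
data add retention-time drift, co-eluting peaks, heteroscedastic and
correlated noise, batch effects and per-sample loading variation, none
of which the generator emulates (loading variation deliberately so; see
above). The original study's data were never deposited, so its specific
accuracies (e.g. a best 10-fold-CV panel at 98 ± 2%) are narrative
context, not reproduction targets; the synthetic defaults produce
comparably separable studies by construction.

## Problem sizes and numerics

The acceptance-scale runs use the full study conditions: 100 seeds for
the screening power check, 60 for the interaction screen, 20 seeds ×
2047 panels × 10 folds (n = 50) for end-to-end panel recovery, 100
random instances for the ANOVA oracle and 25 for the SVM/QP oracle.
`scripts/acceptance.py` reports the same quantities at 50/50/8 seeds.
Z-scores use population SD; SEMs use ddof = 1; CSV floats round-trip at
full float64 precision (`float_precision="round_trip"` on read). All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; equal seeds give byte-identical CSV output.
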