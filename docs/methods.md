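# Methods

`cfocr` classifies genomic regions into three chromatin accessibility
states — closed (CCR), open (OCR) and partially open (pOCR) — from the
fragmentation signature of cell-free DNA (cfDNA), using a three-stage
framework: a robust multivariate control chart that purges mislabeled
samples from a binary training set, a *sensitized* chart that fuses a
MEWMA control chart with a classifier to define three decision bands,
and a confident-learning / co-teaching refinement of the resulting
noisy three-class labels. This note records the model, its
assumptions, the parameters that matter, and the design decisions
taken where the design was genuinely open.

## 1. Signal model

Apoptotic cfDNA fragments (~167 bp) are protected by nucleosomes
spaced ~190 bp apart. Four per-base tracks carry the accessibility
signal over a monitored segment:

* **WPS** (windowed protection score, window w = 120 bp): fragments
  completely spanning the window centered on a base minus fragments
  with an endpoint inside it. Nucleosomes produce peaks; open
  chromatin flattens the score.
* **coverage**: fragment depth; depleted in open regions.
* **Uend / Dend**: counts of 5′ starts and 3′ last covered bases;
  phased end signals flank nucleosomes and vanish in open regions.

Coordinates are 0-based half-open; the 3′ endpoint of `[s, e)` is
`e − 1`. A segment (default 20 kb) is tiled with non-overlapping
200-bp windows; within-window means give the windows × 4 matrix
(100 × 4 at the defaults) that the first-stage chart monitors. The
per-sample summary vector for the second-stage chart is the
population standard deviation of the windowed WPS and coverage
columns. Windows are non-overlapping because exactly 100 windows of
200 bp tile 20 kb; a stride parameter exists but is not the default.
Trailing partial windows are dropped.

## 2. Synthetic data generator

No deposited cfDNA accession is required: the generator emulates the
statistical structure the charts assume.

* **Closed state**: nucleosome centers on a 190-bp lattice with 10 bp
  Gaussian placement jitter; Poisson(`depth_ccr` = 110) fragments per
  nucleosome, i.e. ~97× coverage, matching deeply sequenced plasma
  cfDNA; fragment lengths normal (167, 15) truncated to [100, 400] bp.
* **Open state**: the lattice is erased and fragments land uniformly
  at `ocr_depletion` = 0.3 of the closed coverage.
* **Sample segments**: a closed sample is a full 20-kb lattice; an
  open sample carries a planted accessible span of width uniform in
  [600, 4000] bp (length scale of ATAC/DNase open regions around
  active promoters) centered in the segment — monitored intervals in
  real data contain open sub-regions, they are not open end to end.
* **Depth heterogeneity**: one mean-one lognormal factor per segment
  with CV `depth_cv` = 0.2 emulates the regional depth variation (GC,
  mappability, copy number) of real libraries. It is essential to the
  realism of the probability fusion: without it, between-sample
  variation is pure Poisson noise, classes sit tens of standard
  deviations apart, and every calibrated posterior saturates at 0/1 —
  the intermediate pOCR band the method relies on only exists when
  within-class spread is realistic.
* **Partially open samples** are formed at the *feature* level as
  `tau·OCR + (1 − tau)·CCR` with composite rate `tau` = 0.7 (an
  optional fragment-level mode subsamples the union of an open and a
  closed fragment set at rate tau). Their observed label is a random
  coin flip between 0 and 1: the partially open class is invisible to
  the initial binary annotation.
* **Label noise**: a configurable fraction (default 0.2) of open and
  closed observed labels is flipped.

What the generator does *not* model: sequence content, GC-dependent
fragment bias, mappability, tissue-of-origin mixtures, chromatin-state
autocorrelation along the genome, or sub-nucleosomal fragments.
Passing tests therefore demonstrate that the machinery behaves as
designed under its own assumptions, not that these accuracies transfer
to real cfDNA libraries.

## 3. Stage 1 — robust Hotelling T² chart

Window vectors x ∈ R⁴ are monitored with T² = (x−m)′ S⁻¹ (x−m), where
(m, S) must resist the open-window "outliers" present in the training
data. We use the minimum regularized covariance determinant (MRCD):

* median/Qn standardization per variable; identity target matrix;
* h = ⌈n(1 − `alpha_trim`)⌉ with `alpha_trim` = 0.25;
* six deterministic starting scatters (identity, tanh-transform
  correlation, Spearman and normal-scores rank correlations, the ML
  covariance, and the covariance of the half subset with smallest
  norms), each refined by C-steps to a local determinant minimum;
* regularization weight ρ: the smallest grid value for which every
  start's regularized scatter has condition number ≤ 50 (ρ = 0 for
  well-conditioned data, so the estimator then coincides with a
  deterministic MCD);
* the h-subset ML covariance is scaled by the Gaussian consistency
  factor γ / P(χ²_{p+2} ≤ χ²_{p,γ}), γ = h/n. No reweighting step is
  applied, so with `alpha_trim` = 0 and ρ = 0 the estimate equals the
  classical mean and ML covariance exactly — an identity the tests
  exploit. The cost of skipping reweighting is efficiency (Frobenius
  error of the scatter on clean N(0, I) data at n = 500 is ≈ 0.3
  rather than ≈ 0.15); the control-limit calibration below absorbs
  this because it is calibrated against the same estimator.

**Control limit.** T² of a fresh in-control point against an estimated
(m, S) is modeled as d·F(p, q). Monte-Carlo replicates (default
`n_mc` = 1000) fit the estimator to clean N(0, I) samples of size n
and score fresh points; the pooled mean m̂ and variance v̂ are matched
to E = dq/(q−2) and Var = 2d²q²(p+q−2)/(p(q−4)(q−2)²). These two
equations solve in closed form: with r = v̂/m̂², q = (2p−4+4rp)/(rp−2)
and d = m̂(q−2)/q; when rp ≤ 2 the χ² limit (q → ∞, d = m̂) is used.
UCL = d̂·F_{1−α}(p, q̂) at significance level α = 0.05. Because the
calibration is empirical against the same estimator, the out-of-sample
false-alarm rate lands at α regardless of the estimator's small-sample
bias.

**Run rules** upgrade single alarms to open-region calls: (1) ≥ 3
consecutive exceedances (600 bp at the default window — one alarm
window plus a nucleosome-sized error tolerance); (2) an exceedance at
the first or last window of a segment calls a 3-window span extended
inward from the boundary (open regions can straddle segment breaks);
(3) two exceedance runs separated by fewer than 3 in-control windows
merge into one call that includes the intervening windows. Overlapping
calls merge and carry every contributing rule id.

**Training-set filtering**: an open-labeled candidate region is kept
iff it overlaps (≥ 1 bp, half-open) a called open region; a
closed-labeled candidate iff it overlaps none. Candidate regions are
gene-region scale (the planted span, or the central 2 kb for closed
samples), not whole 20-kb segments — with 100 windows per segment and
a 5% alarm rate, essentially every segment contains some short false
call, and a whole-segment candidate would be vetoed by it. The
balanced subset (majority class downsampled) retrains the classifier;
the chart calibrations keep every filtered in-control sample.

## 4. Stage 2 — sensitized T² chart

Each query sample is summarized by its length-2 summary vector and
monitored by a MEWMA chart fitted on filtered in-control samples:
Z_i = λ(x_i − μ) + (1−λ)Z_{i−1}, T² = Z′S_Z⁻¹Z with
S_Z = λ/(2−λ)·S. λ = 0.2 (standard MEWMA practice; the value is a
free parameter here). Samples are monitored independently — one
recursion step from Z₀ = 0 — because each query is a single
observation, not a time series; a sequence mode exists for ordered
windows.

The raw T² maps to an open-state probability through
pT² = sigmoid((T² − BD)/BD), where BD is the mean over B = 1000
bootstrap resamples of the 100(1−α)-th percentile of in-control T²
values. Dividing by BD makes the transform scale-free (pT²(BD) = 0.5
exactly, regardless of the units of T²).

The classifier contributes pC = sigmoid(θ), θ the raw score of its
linear output unit, and its decisiveness δ = 2·|pC − 0.5| gates the
fusion:

    ST² = η·δ·pT² + (1 − η·δ)·pC,    η = 0.3.

ST² is a convex combination of two probabilities, hence in (0, 1) and
between pT² and pC. η ≥ 0.7 pushes partially open statistics below the
control limit and is rejected with a warning; only η ≤ 0.6 is
exercised. No automatic η selection is provided.

**Bands.** CL is the bootstrap mean of the (1−α) quantile of
in-control ST²; the adjusted limit multiplies CL by the mixture ratio
τ (the plain product CL·τ — no more specific functional form is
defensible, and τ = 1 or omitting τ disables the adjustment). Labels:
CCR for ST² ∈ [0, CL_adj], pOCR for (CL_adj, 1−η], OCR for (1−η, 1].
The left band is closed on the right edge; calibration fails loudly if
CL_adj ≥ 1−η (empty pOCR band).

## 5. Stage 3 — confident learning and co-teaching

The chart's three-class labels still contain mistakes. Out-of-fold
predicted probabilities (5-fold, compact softmax model) estimate the
confident joint: the class-j threshold is the mean predicted
probability of class j among samples observed as j; each sample is
assigned to its highest-probability class among classes whose
threshold it reaches, or omitted. Samples counted off-diagonal are
pruned **once** (the framework's three-step list is a single pass, not
a fixed-point iteration); classes are reweighted by inverse retained
frequency (normalized to mean 1); and two peer networks are co-taught:
each epoch every model ranks per-sample losses, keeps the
keep-rate fraction of smallest-loss samples, and its *peer* takes the
gradient step on that selection. The keep rate is 1 during the 10
warm-up epochs and then ramps linearly over 10 epochs down to
1 − min(noise_estimate, 0.3), with the noise estimate taken from the
confident joint's off-diagonal mass. Final predictions average the two
networks' class probabilities; exact ties resolve to the lowest class
index.

**Classifier implementation.** The probability sources pC and the
co-teaching peers are compact fully-deterministic numpy networks
(logistic regression, or one tanh hidden layer) trained with Adam;
the classifier is a *contract* — anything exposing train/probability
semantics can back the chart. Binary training uses small-loss sample
selection after warm-up (same schedule as above). Default weight decay
1e-3 keeps the linear model's probabilities away from hard 0/1, which
the pOCR band requires; the stated optimization defaults
(lr 1e-4, batch 128, 150 epochs, 10 warm-up, 5 seeds) suit a deep
model, so the pipeline's compact linear model raises the learning rate
to 0.02. Input features are, by default, the per-column means and
standard deviations of the windowed matrix ("extended", 8 values); the
length-2 summary vector and the raveled matrix are alternatives. A 2-D
fragment-length × coordinate image encoding is provided for models
that consume images.

## 6. Pipeline, sizes and determinism

`run_pipeline` chains the stages on synthetic data: simulate a noisy
binary training set (defaults 400 open / 1000 closed samples, 20%
label noise, mirroring the scale of the original study design) →
stage 1 filter → stage 2 calibration, 400 simulated pOCRs, three-class
relabeling → stage 3 refinement → evaluation on a fresh test set
(default 100 samples per class, noise-free labels) for both the
chart-only labels and the final model (accuracy, macro
precision/recall/F1, one-vs-rest AUC/AUPR).

All randomness flows from one root seed through spawned
`SeedSequence` children, one per stage; two runs with the same seed
produce byte-identical metrics files. Test-suite and acceptance runs
use desk-scale sizes chosen as this package's own study conditions
(80 open / 320 closed / 80 pOCR training samples, 40 test samples per
class, 200 Monte-Carlo calibration replicates, 300 bootstrap
resamples); the open fraction is kept near 20% because the 25%-trim
MRCD cannot resist contamination beyond its breakdown point, which is
also true of the method at full scale.

## 7. Numerical choices and degenerate inputs

* Population (divide-by-n) standard deviations in the summary vector;
  ddof = 0 classical covariance to match the MRCD internals; MEWMA
  in-control covariance uses ddof = 1.
* Quantiles are linear-interpolated empirical quantiles.
* Zero-spread variables in the MRCD fall back Qn → MAD → sd before
  raising; identical rows raise.
* `rp ≤ 2` in moment matching switches to the χ² branch; an implied
  q ≤ 4 raises with diagnostics (the matched variance must exist).
* Degenerate probabilities (NaN) in the confident joint raise; a small
  (1e-9) slack on the confidence thresholds guards float accumulation.
* Pruning that would empty a class raises rather than silently
  continuing.
* Fragments straddling segment edges are discarded by the generator
  (the featurizer clips, with a warning, if handed external data).

## 8. Known limitations

* The generator's nucleosome lattice is an emulation choice — the
  fragment-level generative process of real cfDNA is not specified by
  the framework it emulates; conclusions about real libraries require
  real data.
* Whole-genome application would need GC/mappability correction and a
  treatment of copy-number variation; the depth-heterogeneity factor
  stands in for all of these.
* The sensitized chart decides on ST² alone; no additional requirement
  on pC is imposed for the open band.
* BD and CL are pooled across in-control samples, not per segment.
* Binary-classification performance of the three-class model is
  expected to trail a dedicated binary classifier (some samples are
  diverted to the partially open band).
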