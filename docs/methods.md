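# Methods

This note documents the models implemented in `gistmem`, the synthetic
data they are exercised on, and the numerical and design choices made
where the underlying analysis conventions leave room.

## The experimental design being modelled

A subject studies 60 pictures and is tested after a retention interval
(two groups: 1 day vs 28 days) with 180 recognition trials: the 60 old
pictures, 60 *related lures* sharing the semantic gist of one old picture
each, and 60 novel lures; half of each set is emotionally negative, half
neutral. Each "yes" (old) judgment is followed by a 0–3 confidence
rating. Trials are presented with a jittered inter-trial interval while
BOLD data are acquired at TR = 2.5 s (832 retained volumes per run).

## Behavioral indices

* **Rates.** Hit % for old pictures and FA % for related and novel lures,
  overall and split by emotion. Denominators count only responded trials;
  a picture type with no responses yields a missing value, never zero.
  This exclusion rule for non-responses is our convention — the source
  analyses do not state one.
* **Confidence Score.** Sum over hits of the confidence weight (not at
  all = 0 … very = 3). Range 0 to 3 × n_old; 180 in the nominal design.
  The score is monotone non-decreasing in every individual rating.
* **Pair trichotomy.** For each old picture and its related lure:
  lure endorsed → *transformed* (irrespective of the old response);
  lure rejected and old endorsed → *detailed*; both rejected →
  *forgotten*. A pair with a missing response on either member is
  *unclassified*, so the four categories always partition the pairs.

## GLM machinery

* **Canonical HRF.** Double gamma `g(t; 6) − g(t; 16)/6` (gamma pdfs),
  normalized to unit peak. Regressors are built on a 16×-oversampled grid
  (zero-duration events are unit impulses, longer events dt-scaled unit
  boxcars), convolved with the HRF sampled over 48 s (truncation error
  < 1e−6), and sampled at scan times.
* **Drift.** Discrete-cosine basis inside the design rather than
  pre-filtering, so OLS stays exact and testable. Number of non-constant
  cosines: `floor(2·N·TR/cutoff) + 1` with cutoff 128 s; all drift columns
  are zero-mean and hence orthogonal to the constant.
* **AR(1) prewhitening.** One pooled lag-1 autocorrelation estimated from
  the OLS residuals of each series, then a single Prais–Winsten-style
  filtering pass of both sides and a refit; standard errors come from the
  whitened model. The estimator is deliberately simple (the convention
  behind the original analyses is not specified beyond "AR(1)"); a
  simulation test verifies unbiased betas at φ = 0.4.
* **FIR deconvolution.** Seven stick regressors per condition at lags
  0…6 TR (0–15 s), events assigned to the nearest scan. When events are
  spaced beyond 15 s the estimates provably equal event-locked selective
  averages (tested). FIR condition rows are returned in sorted condition
  order so curves align across participants regardless of trial order.
* **Peak window.** Per participant, conditions are collapsed; the bin with
  the maximal group-mean response is the numerical peak; every other bin
  is compared to it with an uncorrected two-tailed paired t-test across
  participants (both groups pooled), and the window is the peak bin plus
  all bins with p > 0.05. Peak values are means over the window, per
  condition. With a broad 5–7.5 s response plateau this yields the
  {5 s, 7.5 s} window; with a strictly canonical (sharply peaked) shape
  and long stimuli the 7.5 s bin can stand alone — the window is a
  data-driven quantity, not a constant.
* **Single-trial patterns.** Least-squares-all: one canonical regressor
  per trial fitted simultaneously with drift terms; per voxel
  t = β/SE(β). Least-squares-separate is available as an option. Rows are
  ordered by onset; identical onsets are rejected as inestimable.
* **gPPI.** Psychological regressors are the HRF-convolved condition
  boxcars; interactions are *unconvolved* condition indicators multiplied
  by the mean-centered seed at scan resolution, then HRF-convolved; the
  raw seed and drift terms complete the model. We deliberately do not
  hemodynamically deconvolve the seed: deconvolution is ill-posed and the
  convention unstated, and the planted-effect recovery test shows the
  construction is unbiased under this generator. The seed signal is the
  ROI mean (first-eigenvariate extraction is a possible variant).
* **Long axis.** MNI Y bands, inclusive: pHC [−40, −30], mHC [−29, −19],
  aHC [−18, −4]; anything else is `outside` (including the 1 mm gaps
  between the printed bands).

## RSA

* RDM entries are `1 − r` (Pearson) between trial t-patterns; matrices
  are symmetrized and zero-diagonal by construction, and constant
  patterns raise an error naming the trial.
* **Mean pattern similarity** is the mean of `1 − d` over the strictly
  lower triangle (row-major over i > j everywhere), averaging raw r — a
  Fisher-z variant is not the default because the summary is defined on r.
* **Rank scaling** (visualization only): average-rank transform of the
  off-diagonal cells scaled to [0, 1]; invariant to monotone transforms.
* **Model RDMs.** `old_distinct`: 0 for old–old cells, 1 elsewhere;
  `old_related_similar`: 0 within {old, related}, 1 for any cell
  involving a novel trial. The hypotheses do not constrain
  related–related / novel–novel cells under `old_distinct` (nor
  novel–novel under `old_related_similar`); the default fills them with 1
  (fully binary model) and a `masked=True` variant excludes them from the
  fit. Reproducibility of the choice matters more than the choice, so
  both are exposed.
* **Fits and comparisons.** Spearman ρ over (unmasked) lower-triangle
  cells, average ranks for ties; cross-group similarity is the Spearman
  correlation of a single-subject RDM with a reference (group-average)
  RDM; model comparison per group is a one-tailed paired t with
  d = mean(Δ)/SD(Δ). Averaging RDMs requires identical sizes — subjects
  with dropped trials (smaller RDMs) must be excluded from averages,
  mirroring how mismatched RDMs are handled in practice.

## Statistics

* **Mixed ANOVA.** Balanced designs only (equal group sizes, complete
  subject × within-cell grid); one between-subject factor and up to two
  within-subject factors. Sums of squares use the classical balanced
  decomposition (Types I/II/III coincide); between effects are tested
  against subjects-within-groups, each within effect against its own
  factor × subject interaction. Generalized η² divides each effect SS by
  itself plus the sum of all subject-level error SS. For within effects
  with more than one numerator df, Mauchly's W (pooled within-group
  covariance of orthonormal contrast scores) and the Greenhouse–Geisser
  corrected p are reported next to the uncorrected p. The implementation
  reproduces pingouin's mixed and repeated-measures ANOVAs exactly on the
  designs both support; for ε and W we pool the covariance within groups
  (error-covariance convention), which can differ from pingouin's
  all-subject pooling in mixed designs by a small amount.
* **Pearson–Filon z** for two overlapping dependent correlations sharing
  one variable:
  `z = √n (r12 − r13) / √((1−r12²)² + (1−r13²)² − 2k)` with
  `k = r23(1 − r12² − r13²) − ½ r12 r13 (1 − r12² − r13² − r23²)`.
  The correlation triple must form a positive-semidefinite matrix.
  A 2,000-replicate trivariate-normal null simulation confirms nominal
  α = .05 calibration at n = 48.
* t-tests, Shapiro–Wilk and Pearson tests wrap scipy with the effect
  sizes and tail conventions used here (Welch by default between groups;
  pooled-SD d for unpaired, SD-of-differences d for paired). Bonferroni
  correction by the number of ROIs is applied at reporting level only.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume;
all numeric defaults are free parameters chosen once to reproduce the
qualitative group pattern, and are documented as such.

* **Memory states.** Each pair draws detailed/gist/forgotten from a
  per-group categorical distribution — defaults 1 d ≈ (0.70, 0.15, 0.15),
  28 d ≈ (0.30, 0.35, 0.35), i.e. fewer detailed and more transformed and
  forgotten pairs at the long delay. For negative pairs the gist and
  forgotten probabilities are shifted on the log scale by (+0.3, −0.3)
  and renormalized (negative material: more transformation, slower
  forgetting).
* **Responses.** Detailed → old "yes" (confidence concentrated on 3),
  lure "no"; gist → lure "yes" (confidence on 1–2) and old "yes" with
  probability 0.75 (a free parameter — how often gist-memory subjects
  also endorse the old picture is not constrained by the design); lapse-
  free otherwise; novel FA probability 0.02 (1 d) / 0.05 (28 d). With
  these rules the pair categorization recovers the planted states
  exactly, which the round-trip tests exploit.
* **Patterns.** `pattern(trial) = c·h_all + oc·h_old + m·h_set +
  a·g(pair) + b·u(trial) + ε` with all latents standard normal per voxel:
  `h_all` shared by every trial, `h_old` by old trials, `h_set` by old
  *and* related trials (set-level gist — the structure the
  "Old and Related Similar" model describes), `g` by an old picture and
  its lure (novel trials draw their own), `u` trial-unique, ε i.i.d.
  noise. With only the pair term, E[r(old, lure)] = a²/(a²+b²+σ²)
  (verified against a Monte-Carlo oracle). Defaults give the anterior ROI
  distinct, old-dominated patterns that weaken at 28 d, and the posterior
  ROI higher overall similarity with set-level gist emerging at 28 d.
  Worth knowing: with pair-level gist alone, per-subject model
  discrimination between the two categorical models plateaus near ~87%
  regardless of trial count, because only the 60 old↔own-lure cells of
  16,110 carry model-relevant signal; the set-level component is what
  makes the gist regime clearly recoverable.
* **BOLD.** Condition amplitudes × canonical HRF (per-ROI, per-group
  amplitudes; anterior activity halves at 28 d, posterior stays flat),
  plus slow cosine drift with random coefficients and AR(1) noise
  initialized from its stationary distribution. Trials last 3.5 s with
  inter-trial intervals uniform on [5, 9] s ("7 ± 2 s" read as a uniform
  jitter). Voxel-wise BOLD scales each trial's regressor by the trial's
  pattern value, so single-trial GLMs recover the planted patterns.
* **Reproducibility.** Each subject's RNG stream derives from the master
  seed and (group, subject index) via `SeedSequence` spawn keys, so any
  subject regenerates identically in isolation; fixed seeds give
  byte-identical outputs.

What the generator does **not** emulate: encoding-session free recall,
multi-run sessions, physiological noise beyond drift + AR(1), spatial
voxel correlations, motion, or between-subject anatomical variability.
Passing tests therefore demonstrate correctness of the estimators under
this generative model, not robustness to real-data artifacts.

## Problem sizes used in tests and the acceptance script

The end-to-end pipeline test uses a reduced cohort (3 + 3 subjects, 8
pairs, 24 voxels, 120 scans); model-recovery and calibration checks use
the full per-subject design (180 trials, 120 voxels; 100 simulated
subjects per regime; 2,000 Pearson–Filon replicates); FIR/gPPI recovery
use the full 832-scan run and a 400-scan variant respectively. These
sizes are the package's chosen demonstration scales and are stated in the
relevant docstrings.

## Known limitations

* The mixed ANOVA requires balance; unbalanced real datasets would need a
  regression-based (Type III) implementation.
* AR(1) prewhitening uses a single pooled coefficient per series, not a
  spatially regularized or per-voxel estimate.
* gPPI omits hemodynamic deconvolution of the seed (documented above); a
  ridge-deconvolution variant is a natural extension hook.
* NIfTI support is limited to extracting ROI-mean series from a 4-D image
  plus an integer-labelled mask (`gistmem.io.read_nifti_roi_series`); the
  pipeline itself operates on plain-text matrices and performs no spatial
  preprocessing (realignment, normalization, smoothing are out of scope).
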