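# Methods

`ecgxai` is a complete, desk-scale pipeline for *explainable* atrial-
fibrillation (AFib) detection on single-lead ECGs: synthetic data with
exact ground truth, denoising, R-peak detection, a residual convolutional
classifier, two point-wise attribution methods (LIME, kernel SHAP), the
beat-level RR-interval aggregation of those attributions, and 1D Grad-CAM
localization.  This note documents the models, the parameters that matter,
the numerical choices, and what the synthetic experiments do and do not
demonstrate.

## Synthetic ECG model

Each beat is an additive sum of Gaussian bumps for the P, Q, R, S and T
deflections (a deliberately simplified, fully analytic variant of
dynamical ECG simulators).  A width parameter `w` means a Gaussian with
standard deviation `w/2`, so `center ± w` holds ~95% of the deflection's
energy.  Defaults (mV, s): P 0.20/0.05 at −0.16; QRS with R 1.0, Q −0.10,
S −0.15 spread over 0.08; T 0.30/0.14 at +0.30; mean RR 0.8 s.  These sit
inside standard adult ranges for a lead-I-like signal.

The two rhythm classes encode the cardinal single-lead AFib signs:

* **Sinus rhythm** — P-wave before every QRS; RR coefficient of variation
  (cv) ≤ 0.05 (default 0.03), i.i.d. Gaussian RR truncated at ±3 sd.
* **AFib** — no P-waves; an amplitude-modulated 6 Hz fibrillatory (f-)
  wave (default 0.05 mV, inside the physiological 4–10 Hz band); slightly
  pronounced T (0.35 mV); RR cv ≥ 0.15 (default 0.25) drawn i.i.d.
  log-normal with matched mean and cv — heavy-tailed, uncorrelated
  spacing.  RR draws are floored at 0.3 s (ventricular refractoriness,
  and it keeps adjacent beat templates from merging).

Additive noise: 0.3 Hz baseline wander (0.10 mV), mains interference
(50 Hz, 0.02 mV), white sensor noise (0.02 mV sd).  Dataset generation
jitters all amplitudes, widths and the mean rate by ±10% per record from
independent substreams.

What the generator does **not** emulate: real f-wave morphology (it is a
narrowband tone, not broadband atrial activity), RR autocorrelation,
ectopy, electrode artifacts, the corpus's "other rhythm"/"noisy" classes,
or inter-patient morphology variation beyond ±10% jitter.  Passing tests
therefore demonstrate that the *pipeline machinery* recovers planted,
well-separated diagnostic structure — not clinical performance.

## Denoising

Two stages, both length-preserving, both with reflect padding (chosen to
avoid boundary spikes that would pollute attributions):

1. **Wavelet shrinkage** — db4, level 4, universal threshold
   σ√(2 ln N) with σ = median(|d₁|)/0.6745, soft thresholding of all
   detail bands.  Level 4 at 300 Hz confines shrinkage to bands above
   ~9 Hz; deeper decompositions let the soft threshold bite into the
   2–9 Hz bands that carry P/T energy and measurably *worsen* clean-signal
   RMSE, so 4 is the default (6 remains configurable).
2. **Median cascade** — sequential median filters at 0.2 s and 0.6 s
   (QRS-scale then ST-T-scale), widths converted to odd sample counts.
   By default the cascade output is treated as the baseline-wander
   estimate and subtracted.  The material calls the refinement stage an
   adaptive Kalman filter but specifies a sequential median cascade; the
   cascade is what is implemented, with `subtract_baseline` switching
   between baseline-removal and plain-smoothing readings.

Measured on the synthetic fixtures: ≥ 80% of a 0.3 Hz drift's amplitude
removed in steady state (the first/last 0.5 s contain the reflect-padding
transient and are excluded from the amplitude measurement), R-peak
attenuation ≤ 10% (typically ~3%), P-waves preserved.

## R-peak detection and RR intervals

Pan–Tompkins-style: 5–15 Hz band-pass (2nd-order Butterworth, zero-phase),
derivative, squaring, 150 ms moving-average integration, peak picking with
a 200 ms refractory period and an adaptive amplitude gate (20% of the 90th
percentile of candidate heights), then snapping each detection to the
local raw-signal maximum within ±50 ms.  The contract is ±50 ms F1 ≥ 0.99
on clean synthetic records; any compliant detector could be substituted.

RR intervals are half-open index ranges `[R_i, R_{i+1})`: every sample
between the first and last peak belongs to exactly one interval, which is
what makes the aggregation below an exact partition.  Interval statistics
use the n−1 sample standard deviation.

## Classifier

A residual 1D network: strided stem (conv k15 stride 2 → BN → ReLU →
max-pool 4), sixteen residual blocks (conv–BN–ReLU–conv–BN plus identity
or 1×1-projection shortcut, ReLU after the add), downsampling ×2 with
channel doubling (capped at 32) every 4 blocks, global average pooling,
linear two-class head.  Global pooling makes the network length-agnostic
(30 s and 60 s strips both work).  The desk profile (base 16 channels,
~0.4 M parameters) trains on 200 records in ~2 minutes on one CPU; a wide
`paper_scale_config()` preset exists for real-corpus work but is not
exercised by the tests.

Training: Adam (lr 1e-3), softmax cross-entropy, batch 16, per-record
z-scoring, 10 epochs.  The shuffle order is drawn once from the seed and
reused each epoch, which makes training exactly reproducible and lets a
zero learning rate provably freeze the loss.  All layers are implemented
directly on numpy arrays (im2col convolutions against BLAS); the explicit
backward pass is shared between training and Grad-CAM.

## Point-wise attribution

Both methods attribute over a partition into 0.1 s segments (30 samples at
300 Hz).  Perturbing single samples moves a convolutional classifier far
too little to identify a surrogate; 0.1 s is below every deflection width
of interest.  Per-sample output is kept by spreading each segment's score
evenly over its member samples, so sums over whole segments — and hence
over RR intervals — preserve total attribution mass.

* **LIME**: each perturbation flips an independent coin per segment and
  adds Gaussian noise (default sd = 0.2× the signal sd) to chosen
  segments; a ridge surrogate (penalty 1e-3, unpenalized intercept)
  weighted by exp(−h²/0.25²), h = fraction of segments perturbed, maps
  mask vectors to the model response.  Coefficients are negated so that
  "perturbing it hurts the AFib score" reads as positive AFib evidence.
* **Kernel SHAP**: coalitions keep segments at their original values and
  replace the complement with a background signal (default zeros — the
  natural off-state for a baseline-corrected signal; a flat-mean option
  exists).  The Shapley-kernel-weighted regression is solved with the
  additivity constraint eliminated exactly, so
  Σφ = f(x) − f(background) holds to machine precision.  With ≤ 20
  segments and enough budget all 2^M − 2 proper coalitions are enumerated
  and the solution equals exact Shapley values (verified against
  factorial-form enumeration to 1e-6); otherwise coalition sizes are
  importance-sampled from the kernel's size profile.

**Response link.** A well-trained classifier saturates: every small
perturbation still yields probability 1.0 to numerical precision, and a
probability-scale surrogate becomes degenerate.  Both explainers therefore
explain the log-odds by default (`link="logit"`).  For the two-class
network the log-odds is taken directly as the logit difference, with no
intermediate probability and hence no ceiling; generic probability-
returning models fall back to log(p/(1−p)) with clipping.  The identity
link remains available and is what the probability-scale additivity tests
use.

## RR-interval aggregation

Per-sample importances are summed over each half-open RR interval
("accumulation"; a mean option exists for duration-independent
comparisons, at the cost of the conservation identity).  Samples before
the first and after the last R-peak are reported as head/tail residuals,
never dropped, so

    Σ interval sums + head + tail = Σ all importances

holds to ≤ 1e-9 relative error and is asserted on every aggregation.
Scores are normalized per record by the maximum absolute interval score
(signed color intensities in [−1, 1]; red = AFib evidence, blue =
against), and ranked descending with ties broken toward earlier onset.

## Grad-CAM

Channel weights are the time-averaged gradients of the target-class logit
with respect to a residual stage's feature maps; the rectified weighted
sum is linearly interpolated to signal resolution (feature j maps to
sample (j+0.5)·L/Lf) and max-normalized.  Highlight regions are maximal
runs above a per-record quantile threshold (default 0.8), discarding runs
shorter than 20 ms.  The default stage is the final block (most
class-specific, coarsest).

For *localization analyses* two considerations govern the stage choice.
First, resolution: a 0.1 s P-window cannot be resolved by the final
stage's 213 ms feature spacing, so only stages with finer spacing can
localize it (`localization_layer()` encodes this bound).  Second, and
empirically decisive: *which* fine stage represents P-wave absence varies
between training runs — retraining the same architecture on a resampled
dataset moved the informative stage from block 7 to block 5.  The
analysis protocol therefore selects the stage on calibration records
that are disjoint from the evaluation panel (`select_cam_layer()`:
maximize mean overlap margin over the random-mask baseline on 5
calibration AFib records), then measures overlap on fresh records.

## Localization experiments

A trained classifier explains whichever cue dominates its training data,
so the two localization analyses each control the competing cue.  Both
use P-wave-contrast datasets (no f-waves, matched T amplitude; classes
differ only in P presence and RR irregularity):

* **Grad-CAM / P-wave absence** — timing contrast minimized (rr_cv 0.05
  vs 0.15, the class invariant bounds).  Metric: fraction of highlighted
  samples inside fixed-width pre-R windows (where P-waves would sit) on
  AFib records, against the coverage fraction — the expected overlap of a
  uniformly random mask.
* **RR ranking / timing anomalies** — generator-default timing contrast
  (rr_cv 0.03 vs 0.25).  Intervals whose duration deviates from the
  record median by more than the upper-quartile deviation are "anomalous";
  the statistic is the mean normalized rank of anomalous intervals,
  tested one-sided against a within-record rank-permutation null
  (1000 permutations).  The LIME surrogate here needs more perturbations
  than segments (~300 for 30 s), hence 500 per record; an
  under-determined surrogate produces ridge-prior noise that can
  masquerade as localization.

**Sensitivity of the ranking analysis.**  This analysis only became
informative once the explained response was the *unclipped* log-odds
taken directly from the logit difference: a converged desk model is
saturated (|log-odds| ≈ 30), so any link computed through clipped
probabilities flattens every perturbation response and the interval
ranks degenerate to ridge-prior noise.  With the direct log-odds
response the effect is present at the study conditions (mean normalized
anomalous rank ≈ 0.41, permutation p ≈ 0.001) but remains
model-instance-dependent: independently trained instances of the same
architecture range from p ≈ 0.001 to non-significant.  Two mechanisms
bound what is achievable: additive-noise perturbations cannot move beat
*timing* itself (they only corrupt the waveform near it), and which
internal features a given training run ends up using determines how much
of its evidence is spatially attributable.  The P-wave Grad-CAM
localization, which does not depend on timing perturbations, is robust
across instances.

## Evaluation utilities

Hand-computed confusion-matrix rates (so consistency between matrix and
rates is exact by construction; cross-checked against scikit-learn in the
tests), a threshold-sweep ROC with trapezoidal AUC, half-up-rounded split
sizes (a 90/10 split of 5830 gives exactly 5247/583), and balanced k-fold
indices.  The decision threshold on the AFib probability is 0.5.

## Figures

Three idioms: the interval heat strip (signal over red/blue per-interval
shading with yellow R-peak markers and a colorbar), the top-beat gallery
(±context seconds around each top-ranked interval), and the Grad-CAM
overlay (class-colored waveform, green highlight spans, activation trace).
Figures render with a pinned style and DPI; repeated calls are
byte-identical.

## Problem sizes

The test suite and the acceptance script train three desk models (200
records × 30 s, 10 epochs each), run the Grad-CAM panel on 10 AFib
records, the ranking analysis on 20 records with 200 LIME perturbations
each, and the detection panel on 40 records.  These sizes give stable
statistics for every planted effect while keeping a full run in the
minutes range on a single CPU.

## Known limitations

* Synthetic-only validation; none of the measured rates transfer to real
  corpora (the benchmark table recomputations are arithmetic checks, not
  reproductions of the underlying experiment).
* The WFDB reader covers headers with format-16 binary and MAT-style
  signal files only.
* The f-wave model is a narrowband tone; explanation methods keying on
  true fibrillatory broadband structure are not exercised.
* Kernel-SHAP sampling error with hundreds of segments and the default
  1000 coalitions is substantial; exact values are only guaranteed in the
  exhaustive regime.
* The classifier is desk-scale by default; no attempt is made to match
  the parameter count of any published network.

## Method agreement

LIME and kernel SHAP corroborate each other's interval rankings on
P-wave-contrast records (mean Spearman ≈ +0.08 over the panel), but on
full-phenotype records with fibrillatory waves their agreement drops to
zero or slightly below.  The divergence is mechanistic, not numerical:
LIME perturbs by *adding* broadband noise, which inside an RR gap
resembles extra fibrillatory activity and can raise the AFib score, while
SHAP *deletes* the gap content, which removes that evidence — the two
operations probe the same region with opposite physiological meaning.
Corroboration claims between the two methods should therefore be read
per-phenotype.
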