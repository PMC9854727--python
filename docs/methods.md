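# Methods

## Signal model and the divisive correction

A trial recording is modelled as the emotion-related signal convolved
with a subject-specific degradation kernel plus noise,
`g = f * h + n`. The resting-state baseline, recorded immediately
before the stimulus, is taken to carry the kernel and no emotion
content; under the convolution theorem and the zero-noise idealisation,
dividing the trial's magnitude spectrum bin-wise by the baseline's
magnitude spectrum removes the kernel and leaves the emotion signal's
spectrum. The pipeline is:

1. cut each trial into equal non-overlapping slots of `slot_seconds`
   (trailing samples that do not fill a slot are discarded);
2. take the one-sided magnitude spectrum of each slot (unnormalized
   forward FFT, phase discarded);
3. correct each slot spectrum with one of three methods — divisive
   (`invbase`), subtractive (`subtractive`, clipped at zero so
   magnitudes stay non-negative), or none (`nbc`) — and restrict to the
   analysis band;
4. average consecutive groups of corrected slot spectra into windows of
   `window_seconds` (an integer multiple of the slot; trailing
   incomplete groups discarded);
5. per window, channel and band, compute the mean and variance of the
   magnitudes and flatten channel-major into one feature record;
6. binarize the trial's valence/arousal ratings at 5.5 into low/high
   labels inherited by every window of the trial.

The property that carries the subject-independence claim is exact and
testable: multiplying both trial and baseline signals of a channel by
any positive constant leaves the divisive output unchanged, while the
subtractive and uncorrected outputs scale linearly. The test suite
asserts this at the spectrum level (≤1e-9 relative) and through the
full feature pipeline, alongside a deconvolution oracle: when a slot is
constructed as the circular convolution of a source with a strictly
positive kernel and the baseline equals that kernel, the divisive
output recovers the source magnitude spectrum to 1e-6 relative error.

## Numerical choices

* **Magnitude, not power.** Whether spectra are divided as amplitudes
  or squared amplitudes is form-invariant for the division (the
  quotient is squared, the log-equivalence is doubled); the package
  operates on magnitudes by default and exposes
  `RemovalConfig(spectrum="power")` to square first.
* **Division floor.** The divisor is floored at
  `epsilon_rel = 1e-8` of each channel's baseline-spectrum maximum.
  The idealised model is noise-free; the relative floor only prevents
  blow-up at near-zero baseline bins and leaves in-band values
  untouched. A channel whose baseline is identically zero is passed
  through with a warning.
* **Grid alignment.** A 6 s slot and a 3 s baseline live on different
  DFT grids (1/6 Hz vs 1/3 Hz spacing). The baseline magnitude is
  linearly interpolated onto the slot grid, clamping to edge values
  outside its range. Zero-padding the baseline to the slot length was
  rejected because it introduces ripple into the divisor. How bins
  should be matched when durations differ is genuinely underdetermined
  in the underlying model; interpolation is this package's choice and
  equal slot/baseline durations avoid the question entirely.
* **Band membership.** Bands have integer edges
  (theta 3–7, alpha 8–13, beta 14–29, gamma 30–47 Hz). Closed integer
  intervals would leave fractional-frequency bins (e.g. 7.5 Hz on a 6 s
  grid) unassigned, so a bin at frequency f belongs to band
  (f_lo, f_hi) iff `f_lo ≤ f < f_hi + 1`; the four bands then tile
  [3, 48) with no gaps or double counting. The analysis band retained
  after correction is [3, 47] Hz, matching the outermost band edges.
* **Variance divisor.** Band variances use the population divisor (bin
  count): the window spectrum is treated as the complete population of
  bins, not a sample.
* **Rating ties.** A rating of exactly 5.5 is classed high, keeping
  "low" = [1, 5.5).
* **Windows never straddle trials**, and every window inherits the
  whole-trial labels.

## Evaluation

Stratified k-fold (default k = 10, shuffled with a fixed seed) operates
at the window-record level, so records from one trial may land in
different folds; leave-one-subject-out (LOSO) holds out all records of
one subject per fold and is the protocol that actually measures
transfer to unseen subjects. Accuracy is correct/total; F1 is the
harmonic mean of precision and recall with the high class positive
(macro-averaged if a target ever has more than two classes). Features
are z-scored with statistics fit on the training split only —
classifiers with RBF kernels or sigmoid-free hidden layers are
scale-sensitive and band magnitudes span orders of magnitude; the
toggle is `ClassifierConfig(standardize=False)`. The MLP uses hidden
layers (64, 32) and is otherwise pinned by `mlp_max_iter = 400` and the
seed, both recorded in every report's config snapshot; the SVM uses an
RBF kernel; kNN uses a kd-tree with 5 neighbours.

## Synthetic generator

The generator emulates the structure of the benchmark emotion corpora —
32 channels at 128 Hz, 60 s trials, 3 s pre-trial baselines, 1–9
ratings, 32 subjects × 40 trials — under exactly the degradation model
above, so the divisive correction's claims are testable without
restricted data.

* **Subject kernel.** Each subject's per-channel spectral gain profile
  is `exp` of Gaussian noise on a dense (0.125 Hz) grid, smoothed with a
  Gaussian of width `kernel_smoothness` (default 4 Hz — broad enough
  that a band sees a coherent gain, narrow enough that bands decorrelate
  across the spectrum) and scaled so the log-gain standard deviation
  across subjects is `subject_gain_sd` at every frequency. The default
  1.0 makes subject identity the dominant source of spectral variance,
  which is the regime that motivates baseline removal in the first
  place.
* **Trials.** The emotion signal is white noise whose spectrum is
  scaled per band by the class effect; the trial spectrum is that
  magnitude times the subject kernel, returned to the time domain with
  the noise's phase. The baseline is the kernel driven by flat unit
  excitation with independent random phase — statistically, not
  numerically, equal to the trial's distortion, so the division floor
  and grid interpolation are exercised honestly. Both signals receive
  additive sensor noise (`noise_sd`, default 0.05 µV, small relative to
  signal amplitude).
* **Class effects.** The high class boosts beta and gamma power by
  ×1.2, the low class boosts theta and alpha by ×1.2. The modulation is
  deliberately subtle: in real recordings emotion effects on band power
  are small relative to between-subject variability (uncorrected
  features transfer to unseen subjects at near-chance accuracy), and
  the generator reproduces that regime — a much larger effect would let
  uncorrected features classify across subjects, which real data do not
  support.
* **Labels.** High-class trials are rated 7.5, low-class 2.5, on both
  axes, so labels flow through the ordinary binarization path; classes
  alternate within subject, giving exact per-subject balance. The whole
  corpus is bit-reproducible from the config seed.

What passing tests on this generator do **not** show: robustness to
non-stationary baselines (the kernel is fixed within a subject), 1/f
background structure, artifacts (ocular, muscular), electrode-geometry
effects, or rating noise — real trials have continuous, disagreeing
ratings, whereas synthetic ratings are two-valued. The generator
isolates exactly one confound, the multiplicative subject gain.

## Problem sizes

The evaluation experiments shipped with the package (tests and
`scripts/acceptance.py`) use a scaled corpus — 8 subjects × 20 trials ×
8 channels, three generator seeds — which keeps the full LOSO
comparison of corrected vs uncorrected features to tens of seconds
while preserving the phenomenon: divisive correction holds LOSO
accuracy near 0.9 where no correction falls to ≈0.55–0.62. Structural
counts (256 features, 1280 trials) are computed at the full 32-channel,
32-subject layout.

## Known limitations

* The correction assumes the baseline is emotion-free and stationary
  over the trial; drifting resting-state spectra violate the model.
* Magnitude-domain division discards phase; any emotion information in
  phase is lost by construction.
* The subtractive method's clipped-at-zero output means its features
  are not strictly linear in the input when the baseline exceeds the
  slot spectrum.
* Slot/baseline grid interpolation is an arbitrary (if defensible)
  resolution of an underdetermined bin-matching problem; results with
  slot durations equal to the baseline duration avoid it.
* No artifact removal is performed; inputs are assumed pre-cleaned.
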