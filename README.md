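# invbase

Subject-independent EEG emotion features via inverse-filter baseline
removal.

## The problem

EEG-based emotion classification (low/high valence and arousal on the
usual 1–9 self-rating scales) is plagued by subject dependence: two
people watching the same stimulus produce very different spectra,
because each brain imposes its own background spectral profile on
everything it emits. Features extracted from raw trial spectra therefore
encode *who* was recorded at least as strongly as *what they felt*, and
a classifier evaluated on a subject it never saw collapses toward
chance.

The resting-state baseline recorded just before each trial carries that
subject-specific profile and (ideally) nothing else. Modelling a trial
recording as the emotion signal distorted by the subject's profile,

    g(t) = f(t) * h(t) + n(t),

with `f` the emotion signal, `h` the subject's degradation kernel and
`n ≈ 0`, the convolution theorem turns the correction into a point-wise
division in the frequency domain. This package implements that
correction — **InvBase** — for each time slot `i` of a trial:

    |X_rem(ν)| = |X_i(ν)| / |X_base(ν)|

where `|X_i|` is the slot's magnitude spectrum and `|X_base|` the
baseline's. A per-channel multiplicative gain applied to both trial and
baseline cancels exactly under the division, which is the precise sense
in which the resulting features are subject-independent. Two reference
corrections are included: **subtractive** (`|X_i| − |X_base|`, clipped
at 0, the conventional approach) and **NBC** (no baseline correction).

Downstream, slot spectra are averaged over fixed windows, cut into
theta (3–7 Hz), alpha (8–13 Hz), beta (14–29 Hz) and gamma (30–47 Hz)
bands, and summarised by per-band per-channel mean and variance —
8 features per channel, 256 for a 32-channel montage. Ratings are
binarized at 5.5. Classifiers (MLP with hidden layers 64/32, RBF-kernel
SVM, kd-tree kNN with 5 neighbours) are evaluated by stratified 10-fold
cross-validation and by leave-one-subject-out (LOSO), the operational
test of subject independence.

Because the benchmark emotion corpora in this format are
access-restricted, the package ships a synthetic generator that emulates
their structure (32 channels, 128 Hz, 60 s trials, 3 s pre-trial
baselines, 1–9 ratings) under the multiplicative degradation model, with
log-normal subject-specific spectral gains and class-dependent band
power. All claims are testable end-to-end on generated data.

## Worked example

```python
import invbase

cfg = invbase.SynthConfig(n_subjects=8, n_trials_per_subject=20, n_channels=8, seed=0)
dataset = invbase.generate_dataset(cfg)
for method in ("invbase", "subtractive", "nbc"):
    records = invbase.assemble_features(
        dataset, invbase.RemovalConfig(method=method), slot_seconds=6.0, window_seconds=12.0
    )
    report = invbase.run_loso(records, "valence", invbase.ClassifierConfig(kind="mlp", seed=0))
    print(f"{method:12s} LOSO accuracy {report.mean_accuracy:.3f}  F1 {report.mean_f1:.3f}")
```

prints

```
invbase      LOSO accuracy 0.850  F1 0.827
subtractive  LOSO accuracy 0.682  F1 0.620
nbc          LOSO accuracy 0.680  F1 0.617
```

Each trial (60 s at 128 Hz) is cut into ten 6 s slots; slot spectra are
baseline-corrected, averaged pairwise into five 12 s windows, and each
window becomes one 64-feature record (8 channels × 4 bands × 2 stats).
The LOSO report holds out each of the 8 synthetic subjects in turn.
Because the generator gives every subject a strong idiosyncratic
spectral gain (log-sd 1.0), uncorrected and subtractively corrected
features transfer poorly across subjects, while the divisive correction
cancels the gain and keeps accuracy high.

## Command line

```
invbase simulate -c config.yaml -o corpus/     # write HDF5 subject files + manifest
invbase extract  -c config.yaml -o features.csv
invbase evaluate -c config.yaml -o report      # report.csv + report.json
invbase sweep    -c config.yaml -o sweep/      # slot sizes 1,3,6,12,15,30 s
```

The YAML config holds a `synthetic` section (or `input_files` pointing
at HDF5 subject containers), a `removal` section, slot/window sizes,
`classifier`, `protocol` (`kfold`/`loso`) and `target`
(`valence`/`arousal`); flags override file values. The sweep fixes the
window at 12 s for slots up to 12 s and sets window = slot above that.
Single trials can also be imported from EDF via
`invbase.read_edf_trial`.

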