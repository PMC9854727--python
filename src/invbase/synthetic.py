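"""Synthetic EEG generator for exercising baseline removal.

Trials follow a multiplicative degradation model: an "emotion" signal —
band-limited white noise whose per-band power depends on the class label
— is shaped in the frequency domain by a subject-specific, spectrally
smooth gain profile (the subject's resting-state kernel).  The baseline
segment is an independent realisation driven by the same kernel, so the
kernel can be estimated from the baseline and divided out of the trial.
Per-subject kernels are log-normal across subjects, which is exactly the
nuisance that leave-one-subject-out evaluation punishes and inverse
filtering cancels.

No attempt is made at physiological realism (1/f background, artifacts,
electrode geometry); the generator isolates the subject-gain confound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core_io import EEGDataset, EEGTrial
from .exceptions import ValidationError
from .features import DEFAULT_BANDS

__all__ = ["SynthConfig", "make_subject_kernel", "generate_trial", "generate_dataset"]


def _default_class_effects() -> dict[str, dict[str, float]]:
    # high valence/arousal boosts fast activity, low boosts slow activity;
    # a 20% band-power modulation keeps the emotion effect subtle relative
    # to the between-subject gain spread, as in real recordings
    return {
        "high": {"theta": 1.0, "alpha": 1.0, "beta": 1.2, "gamma": 1.2},
        "low": {"theta": 1.2, "alpha": 1.2, "beta": 1.0, "gamma": 1.0},
    }


@dataclass
class SynthConfig:
    """Generator settings; defaults mirror a 32-channel, 128 Hz corpus
    with 60 s trials and 3 s pre-trial baselines.

    ``subject_gain_sd`` is the across-subject standard deviation of the
    log spectral gain (1.0 = strong subject identity in raw spectra);
    ``kernel_smoothness`` is the correlation scale of the gain profile
    in Hz; ``noise_sd`` is additive time-domain sensor noise in µV.
    """

    n_subjects: int = 32
    n_trials_per_subject: int = 40
    n_channels: int = 32
    fs: float = 128.0
    trial_seconds: float = 60.0
    baseline_seconds: float = 3.0
    class_effects: dict[str, dict[str, float]] = field(
        default_factory=_default_class_effects
    )
    subject_gain_sd: float = 1.0
    kernel_smoothness: float = 4.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_subject < 1:
            raise ValidationError("need at least one subject and one trial")
        if self.n_channels < 1:
            raise ValidationError("n_channels must be >= 1")
        if self.fs <= 0 or self.trial_seconds <= 0 or self.baseline_seconds <= 0:
            raise ValidationError("fs and durations must be positive")
        if self.subject_gain_sd < 0 or self.noise_sd < 0:
            raise ValidationError("spreads must be non-negative")
        if self.kernel_smoothness <= 0:
            raise ValidationError("kernel_smoothness must be positive")
        for label, effects in self.class_effects.items():
            for band, mult in effects.items():
                if mult <= 0:
                    raise ValidationError(
                        f"class_effects[{label}][{band}] must be > 0"
                    )

    @property
    def kernel_grid(self) -> np.ndarray:
        """Dense frequency grid (Hz) on which subject kernels are sampled."""
        df = 0.125
        return np.arange(0.0, self.fs / 2 + df / 2, df)


def make_subject_kernel(cfg: SynthConfig, subject_index: int) -> np.ndarray:
    """Per-channel strictly positive spectral gain profile for one subject.

    The log-profile is white Gaussian noise on the dense kernel grid,
    smoothed with a Gaussian of width ``kernel_smoothness`` Hz and
    rescaled so its marginal standard deviation across subjects equals
    ``subject_gain_sd`` at every frequency.  Deterministic given the
    config seed and subject index.
    """
    grid = cfg.kernel_grid
    rng = np.random.default_rng([cfg.seed, 1, subject_index])
    z = rng.standard_normal((cfg.n_channels, grid.size))
    sigma_bins = cfg.kernel_smoothness / (grid[1] - grid[0])
    smooth = gaussian_filter1d(z, sigma=sigma_bins, axis=1, mode="reflect")
    # smoothing shrinks variance by the filter's squared norm; undo it
    impulse = np.zeros(grid.size)
    impulse[grid.size // 2] = 1.0
    w = gaussian_filter1d(impulse, sigma=sigma_bins, mode="reflect")
    norm = np.sqrt(np.sum(w**2))
    log_gain = cfg.subject_gain_sd * smooth / norm
    return np.exp(log_gain)


def _band_multipliers(
    freqs: np.ndarray, effects: dict[str, float]
) -> np.ndarray:
    """Per-bin class multipliers; bins outside all bands keep gain 1."""
    mult = np.ones_like(freqs)
    for name, f_lo, f_hi in DEFAULT_BANDS:
        if name in effects:
            mult[(freqs >= f_lo) & (freqs < f_hi + 1)] = effects[name]
    return mult


def _interp_kernel(cfg: SynthConfig, kernel: np.ndarray, freqs: np.ndarray):
    grid = cfg.kernel_grid
    return np.vstack([np.interp(freqs, grid, row) for row in kernel])


def generate_trial(
    cfg: SynthConfig,
    kernel: np.ndarray,
    class_label: str,
    rng: np.random.Generator,
    subject_id: str = "S00",
    trial_id: int = 0,
) -> EEGTrial:
    """One synthetic trial: class-shaped noise times the subject kernel.

    The trial's magnitude spectrum is |white noise DFT| x class band
    multipliers x kernel (phase inherited from the noise); the baseline
    is the kernel driven by flat unit excitation with independent random
    phase.  Ratings are 7.5 for the high class and 2.5 for the low class
    so labels flow through the ordinary binarization path.
    """
    if class_label not in cfg.class_effects:
        raise ValidationError(f"unknown class label {class_label!r}")
    n = int(round(cfg.trial_seconds * cfg.fs))
    nb = int(round(cfg.baseline_seconds * cfg.fs))
    trial_freqs = np.fft.rfftfreq(n, d=1.0 / cfg.fs)
    base_freqs = np.fft.rfftfreq(nb, d=1.0 / cfg.fs)

    mult = _band_multipliers(trial_freqs, cfg.class_effects[class_label])
    kern_trial = _interp_kernel(cfg, kernel, trial_freqs)
    white = rng.standard_normal((cfg.n_channels, n))
    spectrum = np.fft.rfft(white, axis=1) * mult * kern_trial
    trial_signal = np.fft.irfft(spectrum, n=n, axis=1)

    kern_base = _interp_kernel(cfg, kernel, base_freqs)
    phase = rng.uniform(0.0, 2 * np.pi, size=kern_base.shape)
    phase[:, 0] = 0.0
    if nb % 2 == 0:
        phase[:, -1] = 0.0  # Nyquist bin of a real signal is real
    baseline_signal = np.fft.irfft(kern_base * np.exp(1j * phase), n=nb, axis=1)

    if cfg.noise_sd > 0:
        trial_signal = trial_signal + cfg.noise_sd * rng.standard_normal(
            trial_signal.shape
        )
        baseline_signal = baseline_signal + cfg.noise_sd * rng.standard_normal(
            baseline_signal.shape
        )

    rating = 7.5 if class_label == "high" else 2.5
    return EEGTrial(
        subject_id=subject_id,
        trial_id=trial_id,
        fs=cfg.fs,
        trial_signal=trial_signal,
        baseline_signal=baseline_signal,
        ratings={"valence": rating, "arousal": rating},
    )


def generate_dataset(cfg: SynthConfig) -> EEGDataset:
    """Full synthetic corpus: balanced classes per subject (alternating),
    bit-reproducible from the config seed."""
    trials: list[EEGTrial] = []
    for s in range(cfg.n_subjects):
        kernel = make_subject_kernel(cfg, s)
        subject_id = f"S{s:02d}"
        for t in range(cfg.n_trials_per_subject):
            label = "high" if t % 2 == 0 else "low"
            rng = np.random.default_rng([cfg.seed, 2, s, t])
            trials.append(
                generate_trial(
                    cfg, kernel, label, rng, subject_id=subject_id, trial_id=t
                )
            )
    return EEGDataset(trials)
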