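"""Slot segmentation, magnitude spectra and baseline removal.

The trial signal is cut into fixed-length non-overlapping time slots and
each slot is taken to the frequency domain with an FFT.  Three baseline
corrections are offered:

``invbase``
    Point-wise division of each slot spectrum by the resting-state
    baseline spectrum.  Treating the resting state as the subject's
    spectral "degradation" profile, the division is the frequency-domain
    form of inverse filtering: a per-channel multiplicative gain applied
    to both trial and baseline cancels exactly, which is what makes the
    resulting features subject-independent.
``subtractive``
    The conventional correction: baseline spectrum subtracted from each
    slot spectrum, clipped at zero.
``nbc``
    No baseline correction; slot spectra pass through unchanged.

All three operate on one-sided magnitude spectra (phase discarded); a
``power`` switch squares magnitudes first.  Division is floored at a
small fraction of each channel's baseline maximum so that near-zero
baseline bins cannot blow up the quotient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .core_io import EEGTrial
from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "Spectrum",
    "RemovalConfig",
    "segment_slots",
    "compute_spectrum",
    "baseline_spectrum",
    "align_grids",
    "invbase_remove",
    "subtractive_remove",
    "remove_baseline",
]

METHODS = ("invbase", "subtractive", "nbc")


@dataclass
class Spectrum:
    """One-sided magnitude spectrum for a set of channels.

    ``magnitudes`` is channels x n_bins and non-negative; ``freqs`` is the
    ascending frequency grid in Hz.  ``origin`` records whether the
    spectrum came from a trial slot, the baseline segment, or a window
    average; ``index`` is the slot or window index where applicable.
    """

    magnitudes: np.ndarray
    freqs: np.ndarray
    origin: str = "slot"
    index: int | None = None

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.magnitudes.ndim != 2:
            raise ValidationError("magnitudes must be channels x n_bins")
        if self.magnitudes.shape[1] != self.freqs.shape[0]:
            raise ValidationError("freqs length does not match magnitudes")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValidationError("freqs must be strictly increasing")
        if self.freqs[0] < 0:
            raise ValidationError("freqs must be non-negative")
        if np.any(self.magnitudes < 0):
            raise ValidationError("magnitudes must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.magnitudes.shape[1]


@dataclass
class RemovalConfig:
    """Baseline-removal configuration.

    Parameters
    ----------
    method : {"invbase", "subtractive", "nbc"}
    epsilon_rel : float
        Division floor, relative to each channel's baseline-spectrum
        maximum; guards the quotient against near-zero baseline bins.
    analysis_band : (float, float)
        Frequency range in Hz retained for feature extraction; the
        default spans the outermost band edges of the theta-gamma range.
    spectrum : {"magnitude", "power"}
        Whether removal operates on magnitudes or squared magnitudes.
    """

    method: str = "invbase"
    epsilon_rel: float = 1e-8
    analysis_band: tuple[float, float] = (3.0, 47.0)
    spectrum: str = "magnitude"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigurationError(
                f"unknown method {self.method!r}; expected one of {METHODS}"
            )
        if not (0 < self.epsilon_rel < 1):
            raise ConfigurationError("epsilon_rel must lie in (0, 1)")
        f_lo, f_hi = self.analysis_band
        if not (0 < f_lo < f_hi):
            raise ConfigurationError("analysis_band must satisfy 0 < f_lo < f_hi")
        if self.spectrum not in ("magnitude", "power"):
            raise ConfigurationError("spectrum must be 'magnitude' or 'power'")


def segment_slots(trial: EEGTrial, slot_seconds: float) -> list[np.ndarray]:
    """Split the trial signal into equal non-overlapping time slots.

    Returns ``floor(samples / slot_samples)`` consecutive channel x
    slot_samples arrays; trailing samples that do not fill a slot are
    discarded.
    """
    slot_samples = int(round(slot_seconds * trial.fs))
    if slot_samples <= 0:
        raise ValidationError(f"slot of {slot_seconds} s is empty at fs={trial.fs}")
    if slot_samples > trial.n_samples:
        raise ValidationError(
            f"slot of {slot_samples} samples exceeds trial length "
            f"{trial.n_samples}"
        )
    n_slots = trial.n_samples // slot_samples
    return [
        trial.trial_signal[:, i * slot_samples : (i + 1) * slot_samples]
        for i in range(n_slots)
    ]


def compute_spectrum(
    segment: np.ndarray, fs: float, origin: str = "slot", index: int | None = None
) -> Spectrum:
    """One-sided magnitude spectrum of a channels x n segment.

    Unnormalized forward DFT; bin k sits at k*fs/n for k = 0..floor(n/2).
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    n = segment.shape[1]
    if n < 2:
        raise ValidationError(f"segment must have >= 2 samples, got {n}")
    mags = np.abs(np.fft.rfft(segment, axis=1))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return Spectrum(mags, freqs, origin=origin, index=index)


def baseline_spectrum(trial: EEGTrial) -> Spectrum:
    """Magnitude spectrum of the full resting-state baseline segment."""
    return compute_spectrum(trial.baseline_signal, trial.fs, origin="baseline")


def align_grids(base: Spectrum, target_freqs: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto a target frequency grid.

    Needed because slot and baseline durations generally differ, so
    their DFT grids do; values outside the base grid take the nearest
    edge value.
    """
    target_freqs = np.asarray(target_freqs, dtype=float)
    if base.freqs.shape == target_freqs.shape and np.array_equal(
        base.freqs, target_freqs
    ):
        return base
    mags = np.vstack(
        [np.interp(target_freqs, base.freqs, row) for row in base.magnitudes]
    )
    return Spectrum(mags, target_freqs, origin=base.origin, index=base.index)


def _aligned(slot: Spectrum, base: Spectrum) -> Spectrum:
    if base.n_channels != slot.n_channels:
        raise ValidationError(
            f"channel mismatch: slot has {slot.n_channels}, "
            f"baseline has {base.n_channels}"
        )
    return align_grids(base, slot.freqs)


def invbase_remove(slot: Spectrum, base: Spectrum, cfg: RemovalConfig) -> Spectrum:
    """Divide the slot spectrum by the baseline spectrum, bin-wise.

    The divisor is floored at ``cfg.epsilon_rel`` times the channel's
    baseline maximum.  A channel whose baseline is identically zero is
    passed through unchanged with a warning (there is nothing to remove).
    """
    base = _aligned(slot, base)
    out = np.empty_like(slot.magnitudes)
    for ch in range(slot.n_channels):
        peak = base.magnitudes[ch].max()
        if peak == 0.0:
            warnings.warn(
                f"all-zero baseline on channel {ch}; slot passed through",
                RuntimeWarning,
                stacklevel=2,
            )
            out[ch] = slot.magnitudes[ch]
            continue
        divisor = np.maximum(base.magnitudes[ch], cfg.epsilon_rel * peak)
        out[ch] = slot.magnitudes[ch] / divisor
    return Spectrum(out, slot.freqs.copy(), origin="slot", index=slot.index)


def subtractive_remove(slot: Spectrum, base: Spectrum, cfg: RemovalConfig) -> Spectrum:
    """Subtract the baseline spectrum from the slot spectrum, clipped at 0."""
    base = _aligned(slot, base)
    out = np.clip(slot.magnitudes - base.magnitudes, 0.0, None)
    return Spectrum(out, slot.freqs.copy(), origin="slot", index=slot.index)


def _band_restrict(spec: Spectrum, band: tuple[float, float]) -> Spectrum:
    f_lo, f_hi = band
    keep = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    return Spectrum(
        spec.magnitudes[:, keep], spec.freqs[keep], origin=spec.origin, index=spec.index
    )


def remove_baseline(slot: Spectrum, base: Spectrum, cfg: RemovalConfig) -> Spectrum:
    """Apply the configured correction and restrict to the analysis band."""
    if cfg.spectrum == "power":
        slot = replace(slot, magnitudes=slot.magnitudes**2)
        base = replace(base, magnitudes=base.magnitudes**2)
    if cfg.method == "invbase":
        out = invbase_remove(slot, base, cfg)
    elif cfg.method == "subtractive":
        out = subtractive_remove(slot, base, cfg)
    elif cfg.method == "nbc":
        out = Spectrum(
            slot.magnitudes.copy(), slot.freqs.copy(), origin="slot", index=slot.index
        )
    else:  # pragma: no cover - guarded by RemovalConfig
        raise ConfigurationError(f"unknown method {cfg.method!r}")
    return _band_restrict(out, cfg.analysis_band)
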