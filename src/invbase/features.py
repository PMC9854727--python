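"""Windowing, band statistics and label binarization.

Consecutive baseline-removed slot spectra are grouped into fixed-size
windows and averaged bin-wise; each window then yields, per channel and
per frequency band (theta 3-7, alpha 8-13, beta 14-29, gamma 30-47 Hz by
default), the mean and population variance of the spectral magnitudes —
8 values per channel, 256 for a 32-channel montage.  Ratings on the 1-9
valence/arousal scale are binarized at 5.5 into low/high classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import EEGDataset
from .exceptions import ValidationError
from .spectral import (
    RemovalConfig,
    Spectrum,
    align_grids,
    baseline_spectrum,
    compute_spectrum,
    remove_baseline,
    segment_slots,
)

__all__ = [
    "BandSet",
    "FeatureLayout",
    "FeatureRecord",
    "window_average",
    "band_slices",
    "band_features",
    "assemble_features",
    "binarize_rating",
]

DEFAULT_BANDS = [("theta", 3, 7), ("alpha", 8, 13), ("beta", 14, 29), ("gamma", 30, 47)]

STATS = ("mean", "variance")


@dataclass
class BandSet:
    """Ordered, non-overlapping named frequency bands with integer Hz edges."""

    bands: list[tuple[str, int, int]] = field(
        default_factory=lambda: list(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        prev_hi = -np.inf
        for name, f_lo, f_hi in self.bands:
            if f_lo > f_hi:
                raise ValidationError(f"band {name}: f_lo {f_lo} > f_hi {f_hi}")
            if f_lo <= prev_hi:
                raise ValidationError(f"band {name} overlaps its predecessor")
            prev_hi = f_hi

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)


@dataclass
class FeatureLayout:
    """Canonical ordering of a flattened feature vector.

    Channel-major: all stats of channel 1 (band-major, mean then
    variance), then channel 2, and so on.
    """

    channel_names: list[str]
    band_names: list[str]
    stats: tuple[str, ...] = STATS

    def column_names(self) -> list[str]:
        return [
            f"{ch}_{band}_{stat}"
            for ch in self.channel_names
            for band in self.band_names
            for stat in self.stats
        ]

    @property
    def n_features(self) -> int:
        return len(self.channel_names) * len(self.band_names) * len(self.stats)


@dataclass
class FeatureRecord:
    """One analysis window's flattened feature vector with labels."""

    subject_id: str
    trial_id: int
    window_index: int
    features: np.ndarray
    valence_label: str
    arousal_label: str
    layout: FeatureLayout

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (self.layout.n_features,):
            raise ValidationError(
                f"feature vector length {self.features.shape} does not match "
                f"layout ({self.layout.n_features})"
            )


def binarize_rating(r: float) -> str:
    """Binarize a 1-9 rating at 5.5: below -> "low", 5.5 and above -> "high"."""
    if not (1.0 <= r <= 9.0):
        raise ValidationError(f"rating {r} outside [1, 9]")
    return "low" if r < 5.5 else "high"


def window_average(
    slot_spectra: list[Spectrum], slot_seconds: float, window_seconds: float
) -> list[Spectrum]:
    """Average consecutive groups of slot spectra into window spectra.

    The window must be a positive integer multiple of the slot; trailing
    slots that do not fill a window are discarded.
    """
    if window_seconds < slot_seconds:
        raise ValidationError(
            f"window ({window_seconds} s) shorter than slot ({slot_seconds} s)"
        )
    ratio = window_seconds / slot_seconds
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9:
        raise ValidationError(
            f"window ({window_seconds} s) is not an integer multiple of the "
            f"slot ({slot_seconds} s)"
        )
    if not slot_spectra:
        return []
    freqs = slot_spectra[0].freqs
    for s in slot_spectra:
        if not np.array_equal(s.freqs, freqs):
            raise ValidationError("slot spectra must share one frequency grid")
    n_windows = len(slot_spectra) // k
    out = []
    for w in range(n_windows):
        group = slot_spectra[w * k : (w + 1) * k]
        mean = np.mean([s.magnitudes for s in group], axis=0)
        out.append(Spectrum(mean, freqs.copy(), origin="window", index=w))
    return out


def band_slices(grid: np.ndarray, bands: BandSet) -> dict[str, np.ndarray]:
    """Map each band to the indices of its bins on the grid.

    A bin at frequency f belongs to band (f_lo, f_hi) iff
    ``f_lo <= f < f_hi + 1``: the half-open upper edge lets the integer
    band edges tile the spectrum without losing fractional-frequency bins.
    """
    grid = np.asarray(grid, dtype=float)
    out: dict[str, np.ndarray] = {}
    for name, f_lo, f_hi in bands:
        out[name] = np.where((grid >= f_lo) & (grid < f_hi + 1))[0]
    return out


def band_features(window: Spectrum, bands: BandSet) -> np.ndarray:
    """Mean and population variance per band per channel.

    Returns a channels x (2 * n_bands) array; per channel the order is
    band-major, mean then variance.  Raises if any band has no bins on
    the window's grid.
    """
    slices = band_slices(window.freqs, bands)
    for name, idx in slices.items():
        if idx.size == 0:
            raise ValidationError(f"band '{name}' has no bins on the grid")
    cols = []
    for name, _, _ in bands:
        vals = window.magnitudes[:, slices[name]]
        cols.append(vals.mean(axis=1))
        cols.append(vals.var(axis=1))  # population divisor: bins are the population
    return np.column_stack(cols)


def assemble_features(
    dataset: EEGDataset,
    cfg: RemovalConfig,
    slot_seconds: float,
    window_seconds: float,
    bands: BandSet | None = None,
) -> list[FeatureRecord]:
    """Run the full pipeline over a dataset.

    Per trial: slot segmentation, slot FFTs, baseline removal (baseline
    spectrum aligned once per trial), window averaging, band statistics;
    one :class:`FeatureRecord` per window, labels binarized from the
    trial's ratings.
    """
    bands = bands or BandSet()
    layout = FeatureLayout(dataset.channel_names, bands.names)
    records: list[FeatureRecord] = []
    for trial in dataset:
        slots = segment_slots(trial, slot_seconds)
        slot_spectra = [
            compute_spectrum(seg, trial.fs, index=i) for i, seg in enumerate(slots)
        ]
        base = align_grids(baseline_spectrum(trial), slot_spectra[0].freqs)
        removed = [remove_baseline(s, base, cfg) for s in slot_spectra]
        windows = window_average(removed, slot_seconds, window_seconds)
        v_label = binarize_rating(trial.ratings["valence"])
        a_label = binarize_rating(trial.ratings["arousal"])
        for w in windows:
            feats = band_features(w, bands).ravel()  # channel-major
            records.append(
                FeatureRecord(
                    subject_id=trial.subject_id,
                    trial_id=trial.trial_id,
                    window_index=w.index,
                    features=feats,
                    valence_label=v_label,
                    arousal_label=a_label,
                    layout=layout,
                )
            )
    return records
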