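"""Domain containers and file I/O.

An :class:`EEGTrial` holds one stimulus presentation: the trial signal
recorded while the stimulus played, the resting-state baseline recorded
immediately before it, and the subject's valence/arousal self-ratings on
the usual 1-9 scale.  An :class:`EEGDataset` is an ordered, homogeneous
collection of trials (shared sampling rate, channel layout and durations),
mirroring how per-subject EEG emotion corpora are distributed.

On-disk formats:

* subject files — one HDF5 file per subject with datasets ``trial_data``
  (trials x channels x samples), ``baseline_data`` (trials x channels x
  baseline samples), ``ratings`` (trials x 2, valence then arousal), and
  root attributes ``fs``, ``channel_names``, ``subject_ids``, ``trial_ids``;
* single-trial EDF import (uniform sampling rate only);
* CSV feature tables, one row per analysis window.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .exceptions import FormatError, UnsupportedFormatError, ValidationError

__all__ = [
    "EEGTrial",
    "EEGDataset",
    "read_subject_file",
    "write_subject_file",
    "read_edf_trial",
    "write_feature_table",
    "read_feature_table",
]

RATING_MIN = 1.0
RATING_MAX = 9.0


@dataclass
class EEGTrial:
    """One stimulus presentation with its pre-stimulus baseline.

    Parameters
    ----------
    subject_id : str
        Subject identifier; free-form label.
    trial_id : int
        Non-negative trial index within the subject.
    fs : float
        Sampling rate in Hz, shared by trial and baseline signals.
    trial_signal : ndarray, shape (channels, samples)
        Amplitudes in µV recorded during the stimulus.
    baseline_signal : ndarray, shape (channels, baseline_samples)
        Resting-state amplitudes in µV recorded before the stimulus.
    ratings : dict
        Keys ``"valence"`` and ``"arousal"``, values in [1, 9].
    channel_names : list of str
        Channel labels, one per row of the signal arrays.
    """

    subject_id: str
    trial_id: int
    fs: float
    trial_signal: np.ndarray
    baseline_signal: np.ndarray
    ratings: dict[str, float]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.trial_signal = np.asarray(self.trial_signal, dtype=float)
        self.baseline_signal = np.asarray(self.baseline_signal, dtype=float)
        if self.trial_id < 0:
            raise ValidationError(f"trial_id must be >= 0, got {self.trial_id}")
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if self.trial_signal.ndim != 2 or self.baseline_signal.ndim != 2:
            raise ValidationError("signals must be 2-D (channels x samples)")
        if self.trial_signal.shape[0] != self.baseline_signal.shape[0]:
            raise ValidationError(
                "trial and baseline channel counts differ: "
                f"{self.trial_signal.shape[0]} vs {self.baseline_signal.shape[0]}"
            )
        if self.trial_signal.shape[1] == 0 or self.baseline_signal.shape[1] == 0:
            raise ValidationError("signals must contain at least one sample")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.n_channels} channels"
            )
        for axis, r in self.ratings.items():
            if not (RATING_MIN <= float(r) <= RATING_MAX):
                raise ValidationError(
                    f"{axis} rating {r} outside [{RATING_MIN}, {RATING_MAX}] "
                    f"(subject {self.subject_id}, trial {self.trial_id})"
                )

    @property
    def n_channels(self) -> int:
        return self.trial_signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.trial_signal.shape[1]

    @property
    def n_baseline_samples(self) -> int:
        return self.baseline_signal.shape[1]


@dataclass
class EEGDataset:
    """Homogeneous ordered collection of :class:`EEGTrial`.

    All trials must share sampling rate, channel count and order, trial
    duration and baseline duration; ``(subject_id, trial_id)`` pairs are
    unique.
    """

    trials: list[EEGTrial]

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValidationError("dataset must contain at least one trial")
        first = self.trials[0]
        seen: set[tuple[str, int]] = set()
        for t in self.trials:
            if t.fs != first.fs:
                raise ValidationError(
                    f"mixed sampling rates: {t.fs} vs {first.fs}"
                )
            if t.channel_names != first.channel_names:
                raise ValidationError("mixed channel layouts across trials")
            if t.n_samples != first.n_samples:
                raise ValidationError("mixed trial durations across trials")
            if t.n_baseline_samples != first.n_baseline_samples:
                raise ValidationError("mixed baseline durations across trials")
            key = (t.subject_id, t.trial_id)
            if key in seen:
                raise ValidationError(f"duplicate (subject, trial) pair {key}")
            seen.add(key)

    @property
    def fs(self) -> float:
        return self.trials[0].fs

    @property
    def n_channels(self) -> int:
        return self.trials[0].n_channels

    @property
    def channel_names(self) -> list[str]:
        return self.trials[0].channel_names

    @property
    def subject_ids(self) -> list[str]:
        out: list[str] = []
        for t in self.trials:
            if t.subject_id not in out:
                out.append(t.subject_id)
        return out

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


_REQUIRED_DATASETS = ("trial_data", "baseline_data", "ratings")


def read_subject_file(path: str | os.PathLike) -> EEGDataset:
    """Read an HDF5 subject container into an :class:`EEGDataset`.

    Trial order is preserved.  Raises :class:`FormatError` for missing
    datasets and :class:`ValidationError` for shape or rating violations.
    """
    with h5py.File(path, "r") as f:
        for name in _REQUIRED_DATASETS:
            if name not in f:
                raise FormatError(f"missing dataset '{name}' in {path}")
        trial_data = np.asarray(f["trial_data"], dtype=float)
        baseline_data = np.asarray(f["baseline_data"], dtype=float)
        ratings = np.asarray(f["ratings"], dtype=float)
        if "fs" not in f.attrs:
            raise FormatError(f"missing attribute 'fs' in {path}")
        fs = float(f.attrs["fs"])
        channel_names = [str(c) for c in f.attrs.get("channel_names", [])]
        subject_ids = [str(s) for s in f.attrs.get("subject_ids", [])]
        trial_ids = [int(t) for t in f.attrs.get("trial_ids", [])]

    if trial_data.ndim != 3 or baseline_data.ndim != 3:
        raise FormatError("trial_data and baseline_data must be 3-D")
    n_trials = trial_data.shape[0]
    if baseline_data.shape[0] != n_trials:
        raise ValidationError("trial_data and baseline_data trial counts differ")
    if baseline_data.shape[1] != trial_data.shape[1]:
        raise ValidationError(
            "channel axis mismatch: trial_data has "
            f"{trial_data.shape[1]} channels, baseline_data has "
            f"{baseline_data.shape[1]}"
        )
    if ratings.shape != (n_trials, 2):
        raise FormatError(
            f"ratings must be (n_trials, 2), got {ratings.shape}"
        )
    bad = np.where(
        (ratings < RATING_MIN).any(axis=1) | (ratings > RATING_MAX).any(axis=1)
    )[0]
    if bad.size:
        raise ValidationError(
            f"ratings outside [1, 9] for trial indices {bad.tolist()}"
        )
    if not subject_ids:
        subject_ids = ["S01"] * n_trials
    if not trial_ids:
        trial_ids = list(range(n_trials))

    trials = [
        EEGTrial(
            subject_id=subject_ids[i],
            trial_id=trial_ids[i],
            fs=fs,
            trial_signal=trial_data[i],
            baseline_signal=baseline_data[i],
            ratings={"valence": ratings[i, 0], "arousal": ratings[i, 1]},
            channel_names=list(channel_names),
        )
        for i in range(n_trials)
    ]
    return EEGDataset(trials)


def write_subject_file(dataset: EEGDataset, path: str | os.PathLike) -> str:
    """Write an :class:`EEGDataset` as an HDF5 subject container.

    Round-trips bit-exactly through :func:`read_subject_file`.
    """
    trial_data = np.stack([t.trial_signal for t in dataset.trials])
    baseline_data = np.stack([t.baseline_signal for t in dataset.trials])
    ratings = np.array(
        [[t.ratings["valence"], t.ratings["arousal"]] for t in dataset.trials]
    )
    with h5py.File(path, "w") as f:
        # track_times off so identical datasets give identical files
        f.create_dataset("trial_data", data=trial_data, track_times=False)
        f.create_dataset("baseline_data", data=baseline_data, track_times=False)
        f.create_dataset("ratings", data=ratings, track_times=False)
        f.attrs["fs"] = float(dataset.fs)
        f.attrs["channel_names"] = [str(c) for c in dataset.channel_names]
        f.attrs["subject_ids"] = [t.subject_id for t in dataset.trials]
        f.attrs["trial_ids"] = [t.trial_id for t in dataset.trials]
    return str(path)


def _edf_header_sample_rates(path: str | os.PathLike) -> list[float]:
    """Per-signal sampling rates parsed from the ASCII EDF header."""
    with open(path, "rb") as f:
        header = f.read(256)
        if len(header) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            duration = float(header[244:252].decode("ascii"))
            ns = int(header[252:256].decode("ascii"))
        except (UnicodeDecodeError, ValueError) as e:
            raise FormatError(f"{path}: malformed EDF header") from e
        sig_header = f.read(256 * ns)
    if duration <= 0:
        raise FormatError(f"{path}: non-positive EDF record duration")
    # samples-per-record field starts after label/transducer/dim/min/max/
    # prefilter blocks: ns * (16+80+8+8+8+8+8+80) bytes into signal headers
    off = ns * 216
    rates = []
    for i in range(ns):
        raw = sig_header[off + 8 * i : off + 8 * (i + 1)].decode("ascii")
        rates.append(int(raw) / duration)
    return rates


def read_edf_trial(
    path: str | os.PathLike,
    subject_id: str,
    trial_id: int,
    baseline_seconds: float,
    ratings: dict[str, float],
) -> EEGTrial:
    """Import one trial from an EDF recording.

    The first ``baseline_seconds`` of the record become the baseline
    signal; the remainder is the trial signal.  Only uniform sampling
    rates across channels are supported (mixed-rate EDFs would otherwise
    be silently resampled by the reader).  Amplitudes are returned in µV.
    """
    import mne

    rates = _edf_header_sample_rates(path)
    if len(set(rates)) != 1:
        raise UnsupportedFormatError(
            f"{path}: non-uniform channel sampling rates {sorted(set(rates))}"
        )
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # mne returns Volts; store µV
    total_seconds = data.shape[1] / fs
    if baseline_seconds <= 0 or baseline_seconds >= total_seconds:
        raise ValidationError(
            f"baseline_seconds={baseline_seconds} must lie strictly inside "
            f"the {total_seconds:g} s record"
        )
    n_base = int(round(baseline_seconds * fs))
    return EEGTrial(
        subject_id=subject_id,
        trial_id=trial_id,
        fs=fs,
        trial_signal=data[:, n_base:],
        baseline_signal=data[:, :n_base],
        ratings=ratings,
        channel_names=list(raw.ch_names),
    )


_META_COLUMNS = [
    "subject_id",
    "trial_id",
    "window_index",
    "valence_label",
    "arousal_label",
]


def write_feature_table(records: list, path: str | os.PathLike) -> str:
    """Write feature records as a CSV table.

    Columns: subject_id, trial_id, window_index, valence_label,
    arousal_label, then one column per feature named
    ``<channel>_<band>_<stat>`` in canonical (channel-major) order.
    An empty record list yields a header-only CSV with metadata columns.
    """
    if not records:
        pd.DataFrame(columns=_META_COLUMNS).to_csv(path, index=False)
        return str(path)
    layout = records[0].layout
    n_feat = len(records[0].features)
    for r in records:
        if len(r.features) != n_feat or r.layout.column_names() != layout.column_names():
            raise ValidationError("records have heterogeneous feature layouts")
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "trial_id": r.trial_id,
            "window_index": r.window_index,
            "valence_label": r.valence_label,
            "arousal_label": r.arousal_label,
        }
        row.update(zip(layout.column_names(), r.features))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return str(path)


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature CSV back into a DataFrame (metadata + feature columns)."""
    return pd.read_csv(path)
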