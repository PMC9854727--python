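"""Shared fixtures: small synthetic datasets, direct feature records, and
a minimal EDF writer (test fixtures are generated, never stored)."""

from __future__ import annotations

import numpy as np
import pytest

from invbase import EEGTrial, FeatureLayout, FeatureRecord, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """2 subjects x 4 trials, 3 channels, 12 s trials at 128 Hz."""
    cfg = SynthConfig(
        n_subjects=2,
        n_trials_per_subject=4,
        n_channels=3,
        trial_seconds=12.0,
        baseline_seconds=3.0,
        seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trial(
    rng,
    n_channels=2,
    fs=128.0,
    trial_seconds=12.0,
    baseline_seconds=3.0,
    subject_id="S00",
    trial_id=0,
    ratings=None,
):
    n = int(round(trial_seconds * fs))
    nb = int(round(baseline_seconds * fs))
    return EEGTrial(
        subject_id=subject_id,
        trial_id=trial_id,
        fs=fs,
        trial_signal=rng.standard_normal((n_channels, n)),
        baseline_signal=rng.standard_normal((n_channels, nb)),
        ratings=ratings or {"valence": 5.0, "arousal": 6.0},
    )


def make_records(
    rng,
    n=40,
    n_features=8,
    n_subjects=4,
    separable=False,
    shift=5.0,
):
    """Feature records built directly, half high / half low per subject.

    With ``separable`` the high class is shifted by ``shift`` in every
    feature, making the two classes trivially linearly separable.
    """
    n_ch = max(1, n_features // 8)
    layout = FeatureLayout(
        channel_names=[f"ch{i}" for i in range(n_ch)],
        band_names=["theta", "alpha", "beta", "gamma"],
    )
    assert layout.n_features == n_ch * 8
    n_features = layout.n_features
    records = []
    for i in range(n):
        label = "high" if i % 2 == 0 else "low"
        feats = rng.standard_normal(n_features)
        if separable and label == "high":
            feats = feats + shift
        records.append(
            FeatureRecord(
                subject_id=f"S{i % n_subjects:02d}",
                trial_id=i,
                window_index=0,
                features=feats,
                valence_label=label,
                arousal_label=label,
                layout=layout,
            )
        )
    return records


def _ascii(text: str, width: int) -> bytes:
    return text.ljust(width)[:width].encode("ascii")


def write_edf(path, data, fs, record_seconds=1.0, samples_per_record=None):
    """Write a minimal EDF file.

    ``data`` is channels x samples in digital units (int16 range);
    ``samples_per_record`` may be given per channel to produce a
    mixed-rate file (data rows are then truncated/tiled as needed).
    """
    data = np.asarray(data)
    n_channels = data.shape[0]
    if samples_per_record is None:
        samples_per_record = [int(round(fs * record_seconds))] * n_channels
    n_records = data.shape[1] // samples_per_record[0]
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate 01-JAN-2024 X X X", 80),
            _ascii("01.01.24", 8),
            _ascii("00.00.00", 8),
            _ascii(str(256 * (1 + n_channels)), 8),
            _ascii("", 44),
            _ascii(str(n_records), 8),
            _ascii(f"{record_seconds:g}", 8),
            _ascii(str(n_channels), 4),
        ]
    )
    fields = [
        ("EEG ch{}", 16),
        ("AgAgCl electrode", 80),
        ("uV", 8),
        ("-1000", 8),
        ("1000", 8),
        ("-32768", 8),
        ("32767", 8),
        ("", 80),
    ]
    sig = b""
    for template, width in fields:
        for ch in range(n_channels):
            sig += _ascii(template.format(ch), width)
    for ch in range(n_channels):
        sig += _ascii(str(samples_per_record[ch]), 8)
    sig += b" " * (32 * n_channels)
    body = b""
    for r in range(n_records):
        for ch in range(n_channels):
            spr = samples_per_record[ch]
            chunk = np.resize(data[ch], n_records * spr)[r * spr : (r + 1) * spr]
            body += chunk.astype("<i2").tobytes()
    with open(path, "wb") as f:
        f.write(header + sig + body)
    return path
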