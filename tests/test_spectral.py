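"""Slotting, spectra and the three baseline-removal methods."""

import numpy as np
import pytest

from invbase import (
    ConfigurationError,
    RemovalConfig,
    Spectrum,
    ValidationError,
    align_grids,
    baseline_spectrum,
    compute_spectrum,
    invbase_remove,
    remove_baseline,
    segment_slots,
    subtractive_remove,
)

from conftest import make_trial


def spec(mags, freqs=None, **kw):
    mags = np.atleast_2d(np.asarray(mags, dtype=float))
    if freqs is None:
        freqs = np.arange(mags.shape[1], dtype=float)
    return Spectrum(mags, np.asarray(freqs, dtype=float), **kw)


class TestSegmentSlots:
    # expected slot/discard counts frozen from floor-division arithmetic:
    # round(s*128) slot samples into 60*128 = 7680 trial samples
    @pytest.mark.parametrize(
        "slot_seconds,n_slots,discarded",
        [(6.0, 10, 0), (60.0, 1, 0), (7.0, 8, 512)],
    )
    def test_slot_counts_and_discard(self, rng, slot_seconds, n_slots, discarded):
        trial = make_trial(rng, trial_seconds=60.0)
        slots = segment_slots(trial, slot_seconds)
        assert len(slots) == n_slots
        slot_samples = slots[0].shape[1]
        assert trial.n_samples - n_slots * slot_samples == discarded
        if n_slots > 1:
            # consecutive, non-overlapping, channel order preserved
            np.testing.assert_array_equal(
                slots[1][:, 0], trial.trial_signal[:, slot_samples]
            )

    def test_oversized_slot_rejected(self, rng):
        with pytest.raises(ValidationError):
            segment_slots(make_trial(rng, trial_seconds=12.0), 13.0)

    def test_zero_slot_rejected(self, rng):
        with pytest.raises(ValidationError):
            segment_slots(make_trial(rng), 0.0)


class TestComputeSpectrum:
    def test_integer_period_cosine_concentrates_in_one_bin(self):
        fs, n, f0 = 128.0, 768, 10.0
        t = np.arange(n) / fs
        s = compute_spectrum(np.cos(2 * np.pi * f0 * t)[None, :], fs)
        peak_bin = int(np.argmax(s.magnitudes[0]))
        assert s.freqs[peak_bin] == pytest.approx(f0)
        # closed form: an integer-period unit cosine has DFT magnitude n/2
        assert s.magnitudes[0, peak_bin] == pytest.approx(n / 2)
        far = np.abs(s.freqs - f0) >= 2.0
        assert np.all(s.magnitudes[0, far] < 1e-9 * s.magnitudes[0, peak_bin])

    def test_zero_segment_gives_zero_spectrum(self):
        s = compute_spectrum(np.zeros((2, 64)), 128.0)
        assert np.all(s.magnitudes == 0)

    def test_homogeneity(self, rng):
        x = rng.standard_normal((2, 256))
        a = compute_spectrum(x, 128.0)
        b = compute_spectrum(3.5 * x, 128.0)
        np.testing.assert_allclose(b.magnitudes, 3.5 * a.magnitudes, rtol=1e-12)

    def test_grid_spans_zero_to_nyquist(self, rng):
        s = compute_spectrum(rng.standard_normal((1, 768)), 128.0)
        assert s.freqs[0] == 0.0
        assert s.freqs[-1] == pytest.approx(64.0)
        np.testing.assert_allclose(np.diff(s.freqs), 128.0 / 768)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValidationError):
            compute_spectrum(np.zeros((1, 1)), 128.0)


class TestBaselineSpectrum:
    def test_three_second_baseline_grid(self, rng):
        s = baseline_spectrum(make_trial(rng, baseline_seconds=3.0))
        assert s.n_bins == 193  # floor(384/2) + 1
        np.testing.assert_allclose(np.diff(s.freqs), 1 / 3)
        assert s.origin == "baseline"

    def test_cosine_baseline_dominant_bin(self, rng):
        trial = make_trial(rng, n_channels=1, baseline_seconds=3.0)
        t = np.arange(trial.n_baseline_samples) / trial.fs
        trial.baseline_signal = np.cos(2 * np.pi * 10 * t)[None, :]
        s = baseline_spectrum(trial)
        assert s.freqs[int(np.argmax(s.magnitudes[0]))] == pytest.approx(10.0)


class TestAlignGrids:
    def test_identical_grid_is_identity(self):
        base = spec([[2.0, 4.0, 6.0]], [0.0, 1.0, 2.0])
        out = align_grids(base, np.array([0.0, 1.0, 2.0]))
        np.testing.assert_array_equal(out.magnitudes, base.magnitudes)

    def test_hand_linear_interpolation(self):
        base = spec([[2.0, 4.0, 6.0]], [0.0, 1.0, 2.0])
        out = align_grids(base, np.array([0.5, 1.5]))
        np.testing.assert_allclose(out.magnitudes, [[3.0, 5.0]])

    def test_constant_preserved_and_edges_clamped(self):
        base = spec([[7.0, 7.0, 7.0]], [1.0, 2.0, 3.0])
        out = align_grids(base, np.array([0.5, 2.5, 9.0]))
        np.testing.assert_allclose(out.magnitudes, [[7.0, 7.0, 7.0]])


class TestRemoval:
    def test_invbase_of_itself_is_all_ones(self, rng):
        mags = rng.uniform(0.5, 2.0, size=(3, 50))
        slot, base = spec(mags), spec(mags.copy())
        out = invbase_remove(slot, base, RemovalConfig())
        np.testing.assert_allclose(out.magnitudes, 1.0, rtol=1e-12)

    def test_flat_unit_baseline_is_identity_divisor(self, rng):
        mags = rng.uniform(0.0, 3.0, size=(2, 40))
        out = invbase_remove(spec(mags), spec(np.ones((2, 40))), RemovalConfig())
        np.testing.assert_allclose(out.magnitudes, mags, rtol=1e-12)

    def test_elementwise_division(self):
        out = invbase_remove(
            spec([[4.0, 9.0, 16.0]]), spec([[2.0, 3.0, 4.0]]), RemovalConfig()
        )
        np.testing.assert_allclose(out.magnitudes, [[2.0, 3.0, 4.0]])

    def test_all_zero_baseline_channel_passes_through_with_warning(self, rng):
        mags = rng.uniform(0.5, 1.0, size=(2, 10))
        base = np.ones((2, 10))
        base[1] = 0.0
        with pytest.warns(RuntimeWarning, match="all-zero baseline"):
            out = invbase_remove(spec(mags), spec(base), RemovalConfig())
        np.testing.assert_allclose(out.magnitudes[1], mags[1])

    def test_division_floor_prevents_blowup(self):
        base = spec([[1.0, 0.0]])
        out = invbase_remove(spec([[1.0, 1.0]]), base, RemovalConfig(epsilon_rel=1e-3))
        assert out.magnitudes[0, 1] == pytest.approx(1e3)

    def test_subtractive_of_itself_is_zero(self, rng):
        mags = rng.uniform(0.5, 2.0, size=(2, 30))
        out = subtractive_remove(spec(mags), spec(mags.copy()), RemovalConfig(method="subtractive"))
        np.testing.assert_array_equal(out.magnitudes, 0.0)

    def test_elementwise_subtraction_and_clipping(self):
        out = subtractive_remove(
            spec([[4.0, 9.0, 16.0, 1.0]]),
            spec([[2.0, 3.0, 4.0, 5.0]]),
            RemovalConfig(method="subtractive"),
        )
        np.testing.assert_allclose(out.magnitudes, [[2.0, 6.0, 12.0, 0.0]])

    def test_log_domain_equivalence(self, rng):
        # away from the floor, division is subtraction in log magnitude
        slot_m = rng.uniform(0.5, 4.0, size=(3, 64))
        base_m = rng.uniform(0.5, 4.0, size=(3, 64))
        out = invbase_remove(spec(slot_m), spec(base_m), RemovalConfig())
        np.testing.assert_allclose(
            np.log(out.magnitudes), np.log(slot_m) - np.log(base_m), atol=1e-10
        )

    def test_deconvolution_recovers_source_spectrum(self, rng):
        # slot = circular convolution of source with a strictly positive
        # kernel; baseline = the kernel itself (equal lengths). Dividing
        # the spectra must recover the source magnitude spectrum.
        n = 384
        H = rng.uniform(0.5, 2.0, size=n // 2 + 1)
        h = np.fft.irfft(H, n=n)
        f = rng.standard_normal(n)
        slot_t = np.fft.irfft(np.fft.rfft(f) * np.fft.rfft(h), n=n)
        fs = 128.0
        slot = compute_spectrum(slot_t[None, :], fs)
        base = compute_spectrum(h[None, :], fs)
        out = invbase_remove(slot, base, RemovalConfig())
        np.testing.assert_allclose(
            out.magnitudes[0], np.abs(np.fft.rfft(f)), rtol=1e-6
        )


class TestRemoveBaselineDispatch:
    def test_nbc_passes_through_restricted_to_band(self, rng):
        fs, n = 128.0, 768
        slot = compute_spectrum(rng.standard_normal((2, n)), fs)
        base = compute_spectrum(rng.standard_normal((2, n)), fs)
        out = remove_baseline(slot, base, RemovalConfig(method="nbc"))
        # count of bins k with 3 <= k/6 <= 47: k = 18..282
        assert out.n_bins == 265
        keep = (slot.freqs >= 3.0) & (slot.freqs <= 47.0)
        np.testing.assert_array_equal(out.magnitudes, slot.magnitudes[:, keep])

    def test_invbase_dispatch_matches_direct_call(self, rng):
        fs = 128.0
        slot = compute_spectrum(rng.standard_normal((2, 768)), fs)
        base = compute_spectrum(rng.standard_normal((2, 384)), fs)
        cfg = RemovalConfig(method="invbase")
        direct = invbase_remove(slot, align_grids(base, slot.freqs), cfg)
        keep = (slot.freqs >= 3.0) & (slot.freqs <= 47.0)
        out = remove_baseline(slot, base, cfg)
        np.testing.assert_allclose(out.magnitudes, direct.magnitudes[:, keep])

    @pytest.mark.parametrize("method", ["invbase", "subtractive", "nbc"])
    def test_no_negative_magnitudes(self, rng, method):
        fs = 128.0
        slot = compute_spectrum(rng.standard_normal((2, 768)), fs)
        base = compute_spectrum(rng.standard_normal((2, 384)), fs)
        out = remove_baseline(slot, base, RemovalConfig(method=method))
        assert np.all(out.magnitudes >= 0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError):
            RemovalConfig(method="wiener")

    def test_power_switch_squares_before_removal(self, rng):
        slot_m = rng.uniform(0.5, 2.0, size=(1, 768 // 2 + 1))
        base_m = rng.uniform(0.5, 2.0, size=(1, 768 // 2 + 1))
        freqs = np.fft.rfftfreq(768, 1 / 128.0)
        slot, base = spec(slot_m, freqs), spec(base_m, freqs)
        out = remove_baseline(slot, base, RemovalConfig(spectrum="power"))
        keep = (freqs >= 3.0) & (freqs <= 47.0)
        np.testing.assert_allclose(
            out.magnitudes, (slot_m[:, keep] / base_m[:, keep]) ** 2, rtol=1e-12
        )


class TestGainCancellation:
    """Per-channel gains applied jointly to trial and baseline cancel
    under division, scale the other methods linearly — the testable core
    of subject independence."""

    @pytest.mark.parametrize("method,scaling", [("invbase", "invariant"), ("subtractive", "linear"), ("nbc", "linear")])
    def test_joint_gain(self, rng, method, scaling):
        fs = 128.0
        trial = make_trial(rng, n_channels=3, trial_seconds=12.0)
        gains = np.array([0.2, 1.0, 7.5])[:, None]
        slot = compute_spectrum(trial.trial_signal[:, :768], fs)
        base = baseline_spectrum(trial)
        slot_g = compute_spectrum(gains * trial.trial_signal[:, :768], fs)
        base_g = Spectrum(gains * base.magnitudes, base.freqs, origin="baseline")
        cfg = RemovalConfig(method=method)
        out = remove_baseline(slot, base, cfg)
        out_g = remove_baseline(slot_g, base_g, cfg)
        if scaling == "invariant":
            np.testing.assert_allclose(out_g.magnitudes, out.magnitudes, rtol=1e-9)
        else:
            np.testing.assert_allclose(
                out_g.magnitudes, gains * out.magnitudes, rtol=1e-9
            )
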