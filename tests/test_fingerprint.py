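"""Spectrogram, peak picking, pairing and hashing against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from snorefp.audio_io import AudioSignal
from snorefp.fingerprint import (
    DEFAULT_TRUNCATION,
    PairingParams,
    Peak,
    SignalTooShortError,
    SpectrogramParams,
    compute_spectrogram,
    find_peaks,
    fingerprint_signal,
    frame_percentile_floor,
    hash_pair,
    pair_peaks,
)
from snorefp.synthetic_data import SnoreClipParams, gen_snore_clip
from tests.conftest import (
    brute_force_pairs,
    brute_force_peaks,
    make_cmap,
    make_spectrogram,
    naive_dft_magnitudes,
)

SMALL = SpectrogramParams(window_length=512, hop_length=256,
                          magnitude_scale="linear")


class TestComputeSpectrogram:
    def test_zero_signal_gives_zero_magnitudes(self):
        sig = AudioSignal(samples=np.zeros(44100), sample_rate=44100)
        spec = compute_spectrogram(sig)
        assert np.all(spec.magnitudes == 0.0)
        assert spec.n_frames == (44100 - 4096) // 2048 + 1

    def test_pure_tone_concentrates_in_nearest_bin(self):
        t = np.arange(44100) / 44100
        sig = AudioSignal(samples=np.sin(2 * np.pi * 1000 * t),
                          sample_rate=44100)
        spec = compute_spectrogram(sig)
        expected_bin = int(np.argmin(np.abs(spec.bin_freqs - 1000)))
        assert np.all(np.argmax(spec.magnitudes, axis=1) == expected_bin)

    def test_matches_naive_dft_oracle(self):
        rng = np.random.default_rng(3)
        sig = AudioSignal(samples=rng.uniform(-1, 1, 512 + 2 * 256),
                          sample_rate=8000)
        spec = compute_spectrogram(sig, SMALL)
        assert spec.n_frames == 3
        from scipy.signal import get_window
        window = get_window("hann", 512, fftbins=True)  # periodic Hann, as the STFT uses
        for k in range(3):
            frame = sig.samples[k * 256: k * 256 + 512] * window
            np.testing.assert_allclose(spec.magnitudes[k],
                                       naive_dft_magnitudes(frame),
                                       atol=1e-9)

    def test_axes_are_consistent(self):
        sig = AudioSignal(samples=np.zeros(8000), sample_rate=8000)
        spec = compute_spectrogram(sig, SMALL)
        assert np.all(np.diff(spec.frame_times) > 0)
        assert np.all(np.diff(spec.bin_freqs) > 0)
        assert spec.bin_freqs[-1] <= 4000.0
        assert spec.magnitudes.shape == (spec.n_frames, len(spec.bin_freqs))

    def test_too_short_signal_raises(self):
        sig = AudioSignal(samples=np.zeros(100), sample_rate=8000)
        with pytest.raises(SignalTooShortError):
            compute_spectrogram(sig, SMALL)


class TestFindPeaks:
    def test_single_hot_cell(self):
        m = np.zeros((20, 20))
        m[7, 9] = 5.0
        cmap = find_peaks(make_spectrogram(m), (3, 3), floor=1.0)
        assert [(p.frame_index, p.bin_index) for p in cmap] == [(7, 9)]

    def test_constant_plateau_has_no_peaks(self):
        m = np.full((10, 10), 2.0)
        assert len(find_peaks(make_spectrogram(m), (2, 2), floor=0.0)) == 0

    def test_floor_suppresses_low_peaks(self):
        m = np.zeros((20, 20))
        m[3, 3], m[15, 15] = 0.5, 5.0
        cmap = find_peaks(make_spectrogram(m), (2, 2), floor=1.0)
        assert [(p.frame_index, p.bin_index) for p in cmap] == [(15, 15)]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        m=arrays(np.float64, st.tuples(st.integers(5, 40), st.integers(5, 40)),
                 elements=st.floats(0, 10, allow_nan=False)),
        dt=st.integers(1, 6), df=st.integers(1, 6),
        floor=st.floats(0, 5),
    )
    def test_equals_brute_force_scan(self, m, dt, df, floor):
        got = find_peaks(make_spectrogram(m), (dt, df), floor)
        expected = brute_force_peaks(m, dt, df, floor)
        assert {(p.frame_index, p.bin_index) for p in got} == expected

    def test_monotone_in_floor_and_neighborhood(self):
        rng = np.random.default_rng(11)
        m = rng.uniform(0, 10, (50, 50))
        spec = make_spectrogram(m)
        base = {(p.frame_index, p.bin_index) for p in find_peaks(spec, (2, 2), 1.0)}
        higher_floor = {(p.frame_index, p.bin_index)
                        for p in find_peaks(spec, (2, 2), 4.0)}
        bigger_hood = {(p.frame_index, p.bin_index)
                       for p in find_peaks(spec, (5, 5), 1.0)}
        assert higher_floor <= base
        assert bigger_hood <= base

    def test_per_frame_floor_vector(self):
        rng = np.random.default_rng(12)
        m = rng.uniform(0, 10, (30, 30))
        spec = make_spectrogram(m)
        floor = frame_percentile_floor(spec, 60.0)
        got = {(p.frame_index, p.bin_index) for p in find_peaks(spec, (2, 2), floor)}
        assert got == brute_force_peaks(m, 2, 2, floor)


class TestPairPeaks:
    WIDE = PairingParams(fan_out=1000, min_dt_frames=1, max_dt_frames=100,
                         max_df_bins=100)

    def test_empty_and_singleton(self):
        assert pair_peaks(make_cmap([])) == []
        assert pair_peaks(make_cmap([(3, 3)])) == []

    def test_four_collinear_peaks_match_all_pairs_oracle(self):
        cmap = make_cmap([(0, 5), (2, 5), (4, 5), (6, 5)])
        params = PairingParams(fan_out=3, min_dt_frames=1, max_dt_frames=10,
                               max_df_bins=10)
        got = pair_peaks(cmap, params)
        oracle = brute_force_pairs(cmap.peaks, 1, 10, 10)
        assert len(got) == len(oracle) == 6

    def test_random_constellations_match_zone_filter(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            coords = {(int(rng.integers(0, 30)), int(rng.integers(0, 30)))
                      for _ in range(25)}
            cmap = make_cmap(coords)
            got = set(pair_peaks(cmap, self.WIDE))
            oracle = set(brute_force_pairs(cmap.peaks, 1, 100, 100))
            assert got == oracle

    def test_fan_out_caps_targets_per_anchor(self):
        cmap = make_cmap([(0, 0)] + [(i, 0) for i in range(1, 10)])
        params = PairingParams(fan_out=3, min_dt_frames=1, max_dt_frames=100,
                               max_df_bins=10)
        pairs = pair_peaks(cmap, params)
        anchors = [a for a, _ in pairs]
        assert max(anchors.count(a) for a in set(anchors)) == 3
        # targets taken in (frame, bin) order: first anchor pairs with 1,2,3
        first = [t.frame_index for a, t in pairs if a.frame_index == 0]
        assert first == [1, 2, 3]

    def test_zone_constraints_respected(self):
        rng = np.random.default_rng(22)
        coords = {(int(rng.integers(0, 50)), int(rng.integers(0, 50)))
                  for _ in range(60)}
        params = PairingParams(fan_out=5, min_dt_frames=2, max_dt_frames=8,
                               max_df_bins=6)
        for a, t in pair_peaks(make_cmap(coords), params):
            assert 2 <= t.frame_index - a.frame_index <= 8
            assert abs(t.bin_index - a.bin_index) <= 6


class TestHashPair:
    def test_deterministic_and_fixed_length(self):
        a, b = Peak(0, 10, 1.0), Peak(3, 40, 1.0)
        h1, h2 = hash_pair(a, b), hash_pair(a, b)
        assert h1.token == h2.token
        assert len(h1.token) == DEFAULT_TRUNCATION == 20
        assert h1.anchor_time == 0

    def test_grid_of_1000_pairs_all_distinct(self):
        tokens = {hash_pair(Peak(0, f1, 1.0), Peak(dt, f2, 1.0)).token
                  for f1 in range(10) for f2 in range(10, 20)
                  for dt in range(1, 11)}
        assert len(tokens) == 1000

    def test_token_ignores_absolute_time(self):
        h1 = hash_pair(Peak(5, 10, 1.0), Peak(8, 12, 1.0))
        h2 = hash_pair(Peak(105, 10, 1.0), Peak(108, 12, 1.0))
        assert h1.token == h2.token
        assert h1.anchor_time == 5 and h2.anchor_time == 105


class TestFingerprintSignal:
    def test_silence_yields_no_hashes(self):
        sig = AudioSignal(samples=np.zeros(44100), sample_rate=44100)
        assert fingerprint_signal(sig) == []

    def test_deterministic(self):
        clip = gen_snore_clip(SnoreClipParams(seed=4, duration=3.0))
        assert fingerprint_signal(clip) == fingerprint_signal(clip)

    def test_time_shift_covariance_under_prepended_silence(self):
        # hop-aligned silence: tokens unchanged, anchor frames shifted
        clip = gen_snore_clip(SnoreClipParams(seed=5, duration=3.0,
                                              breath_noise_db=None))
        hop = SpectrogramParams().hop_length
        shift_frames = 108  # ~5 s of leading silence
        padded = AudioSignal(
            samples=np.concatenate([np.zeros(shift_frames * hop), clip.samples]),
            sample_rate=clip.sample_rate)
        base = fingerprint_signal(clip)
        shifted = fingerprint_signal(padded)
        assert sorted(h.token for h in base) == sorted(h.token for h in shifted)
        assert (sorted(h.anchor_time + shift_frames for h in base)
                == sorted(h.anchor_time for h in shifted))

    def test_hash_count_bounded_by_fanout_times_peaks(self):
        clip = gen_snore_clip(SnoreClipParams(seed=6, duration=3.0))
        from snorefp.fingerprint import frame_percentile_floor as fpf

        spec = compute_spectrogram(clip)
        cmap = find_peaks(spec, (15, 15), fpf(spec))
        hashes = fingerprint_signal(clip)
        assert len(hashes) <= PairingParams().fan_out * len(cmap)
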