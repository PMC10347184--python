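"""Preprocessing chain: fixed-grid resampling, band-pass, segmentation,
normalization, labeling."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stresskit import preprocess
from stresskit.preprocess import (
    DEFAULT_FILTERS,
    GRID_LEN,
    GRID_RATE,
    SEGMENT_LEN,
    FilterSpec,
    PreprocessError,
)


class TestResample:
    def test_fixed_grid_length_from_any_input(self):
        # the documented worked case: a 494,033-sample ECG onto the grid
        rng = np.random.default_rng(0)
        x = rng.standard_normal(494_033)
        assert preprocess.resample_to_grid(x).shape == (GRID_LEN,)

    @pytest.mark.parametrize("n", [460_800, 230_400, 33_000, 121])
    def test_fixed_grid_various_lengths(self, n):
        x = np.sin(np.linspace(0, 40 * np.pi, n))
        assert preprocess.resample_to_grid(x).shape == (GRID_LEN,)

    def test_constant_maps_to_constant(self):
        out = preprocess.resample_to_grid(np.full(1000, 3.25))
        assert np.allclose(out, 3.25, atol=1e-9)

    def test_tone_frequency_preserved_at_matched_length(self):
        # 15 min at 512 Hz downsampled 2:1 keeps a 4 Hz tone at 4 Hz
        t_in = np.arange(460_800) / 512.0
        out = preprocess.resample_to_grid(np.sin(2 * np.pi * 4.0 * t_in))
        spectrum = np.abs(np.fft.rfft(out))
        f = np.fft.rfftfreq(GRID_LEN, d=1.0 / GRID_RATE)
        assert abs(f[spectrum.argmax()] - 4.0) < 0.01

    def test_too_short_input_rejected(self):
        with pytest.raises(PreprocessError):
            preprocess.resample_to_grid(np.array([1.0]))


class TestBandpass:
    @pytest.mark.parametrize("modality", ["ppg", "ecg", "eeg"])
    def test_gain_matches_analytic_butterworth(self, modality):
        """Measured sinusoid gains track |H(f)|^2 of the analytic filter
        (squared: zero-phase runs the filter forward and backward)."""
        from scipy.signal import butter, sosfreqz

        spec = DEFAULT_FILTERS[modality]
        sos = butter(
            spec.order,
            [spec.low_cut, spec.high_cut],
            btype="bandpass",
            fs=GRID_RATE,
            output="sos",
        )
        center = np.sqrt(spec.low_cut * spec.high_cut)
        probes = [center, spec.high_cut * 2.0]
        t = np.arange(int(GRID_RATE * 60)) / GRID_RATE
        for freq in probes:
            x = np.sin(2 * np.pi * freq * t)
            y = preprocess.bandpass(x, spec)
            # steady-state tone amplitude via Fourier projection (immune to
            # the filter's edge transients)
            core = slice(len(y) // 4, -len(y) // 4)
            phasor = np.exp(-2j * np.pi * freq * t[core])
            measured = 2.0 * np.abs((y[core] * phasor).mean())
            _, h = sosfreqz(sos, worN=[freq], fs=GRID_RATE)
            analytic = np.abs(h[0]) ** 2
            assert measured == pytest.approx(analytic, rel=0.05, abs=0.005)

    def test_ecg_band_passes_10hz_blocks_dc_drift(self):
        t = np.arange(int(GRID_RATE * 30)) / GRID_RATE
        spec = DEFAULT_FILTERS["ecg"]
        in_band = preprocess.bandpass(np.sin(2 * np.pi * 10 * t), spec)
        assert np.ptp(in_band[2000:-2000]) / 2.0 >= 0.7
        slow = preprocess.bandpass(np.sin(2 * np.pi * 0.5 * t), spec)
        assert np.ptp(slow[2000:-2000]) / 2.0 <= 0.1

    def test_zero_in_zero_out_and_length(self):
        x = np.zeros(5000)
        y = preprocess.bandpass(x, DEFAULT_FILTERS["ppg"])
        assert y.shape == x.shape
        assert np.allclose(y, 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(4000)
        spec = DEFAULT_FILTERS["eeg"]
        np.testing.assert_allclose(
            preprocess.bandpass(3.5 * x, spec), 3.5 * preprocess.bandpass(x, spec),
            rtol=1e-9, atol=1e-9,
        )

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(PreprocessError):
            FilterSpec("bad", 5.0, 200.0).validate(GRID_RATE)


class TestSegment:
    def test_grid_record_gives_90_segments(self):
        segs = preprocess.segment(np.zeros(GRID_LEN))
        assert segs.shape == (90, SEGMENT_LEN)

    @pytest.mark.parametrize(
        "n,expected", [(SEGMENT_LEN, 1), (230_000, 89), (SEGMENT_LEN - 1, 0)]
    )
    def test_floor_semantics(self, n, expected):
        segs = preprocess.segment(np.zeros(n))
        assert segs.shape[0] == expected

    def test_multichannel_segmentation_preserves_channels(self):
        segs = preprocess.segment(np.zeros((5, GRID_LEN)))
        assert segs.shape == (90, 5, SEGMENT_LEN)

    def test_contiguous_non_overlapping(self):
        x = np.arange(3 * 100, dtype=float)
        segs = preprocess.segment(x, window_s=1.0, rate=100)
        np.testing.assert_array_equal(np.concatenate(list(segs)), x)


class TestNormalize:
    def test_zero_mean_unit_variance(self, rng):
        seg = rng.normal(5.0, 3.0, size=(4, 2560))
        out = preprocess.normalize(seg)
        assert np.all(np.abs(out.mean(axis=-1)) < 1e-9)
        assert np.all(np.abs(out.std(axis=-1) - 1.0) < 1e-6)

    def test_idempotent(self, rng):
        seg = rng.standard_normal((2, 512))
        once = preprocess.normalize(seg)
        np.testing.assert_allclose(preprocess.normalize(once), once, atol=1e-9)

    def test_constant_channel_zero_filled(self):
        seg = np.vstack([np.full(100, 7.0), np.arange(100, dtype=float)])
        out = preprocess.normalize(seg)
        assert np.allclose(out[0], 0.0)
        assert abs(out[1].std() - 1.0) < 1e-9


class TestScoreToClass:
    @pytest.mark.parametrize(
        "score,cls",
        [(0, 0), (2, 0), (4, 0), (5, 1), (6, 1), (7, 1), (8, 2)],
    )
    def test_mapping(self, score, cls):
        assert preprocess.score_to_class(score) == cls

    @pytest.mark.parametrize("score", [-1, 9, 100])
    def test_out_of_range_rejected(self, score):
        with pytest.raises(PreprocessError):
            preprocess.score_to_class(score)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=2, max_value=5000),
    offset=st.floats(min_value=-5, max_value=5),
)
def test_resample_always_hits_grid_length(n, offset):
    x = np.sin(np.linspace(0, 7.3, n)) + offset
    assert preprocess.resample_to_grid(x, target_len=1024).shape == (1024,)


class TestBuildSegmentSet:
    def test_counts_channels_and_labels(self, small_cohort):
        _, sessions, _ = small_cohort
        for modalities, n_ch in [(("eeg",), 1), (("ppg", "ecg", "eeg"), 5)]:
            ss = preprocess.build_segment_set(sessions, modalities)
            assert len(ss) == 90 * len(sessions)
            assert ss.segments.shape[1:] == (n_ch, SEGMENT_LEN)
            assert set(np.unique(ss.labels)) <= {0, 1, 2}

    def test_labels_broadcast_per_session(self, small_cohort):
        _, sessions, _ = small_cohort
        ss = preprocess.build_segment_set(sessions[:1], ("eeg",))
        assert len(ss) == 90
        assert len(np.unique(ss.labels)) == 1
        assert ss.labels[0] == preprocess.score_to_class(sessions[0].score)

    def test_channel_map_ordering(self, small_cohort):
        _, sessions, _ = small_cohort
        ss = preprocess.build_segment_set(sessions[:2], ("ppg", "ecg", "eeg"))
        assert ss.channel_map == ["PPG1", "PPG2", "PPG3", "ECG", "EEG"]

    def test_segments_normalized(self, small_cohort):
        _, sessions, _ = small_cohort
        ss = preprocess.build_segment_set(sessions[:1], ("ecg",))
        means = ss.segments.mean(axis=-1)
        stds = ss.segments.std(axis=-1)
        assert np.all(np.abs(means) < 1e-5)
        assert np.all(np.abs(stds - 1.0) < 1e-4)

    def test_missing_modality_names_session(self, small_cohort):
        _, sessions, _ = small_cohort
        import copy

        broken = copy.copy(sessions[0])
        broken.signals = {k: v for k, v in sessions[0].signals.items() if k != "eeg"}
        with pytest.raises(PreprocessError, match=broken.participant_id):
            preprocess.build_segment_set([broken], ("eeg",))

    def test_early_finish_session_still_90_segments(self):
        from stresskit import synthgen

        profile = synthgen.make_profile("P09", 2, "hard", 3)
        short = synthgen.make_session(profile, duration_s=33.0, seed=5)
        ss = preprocess.build_segment_set([short], ("ecg",))
        assert len(ss) == 90

    def test_roundtrip_save_load(self, small_cohort, tmp_path):
        _, sessions, _ = small_cohort
        ss = preprocess.build_segment_set(sessions[:2], ("ecg",))
        path = tmp_path / "segments.npz"
        ss.save(path)
        loaded = preprocess.SegmentSet.load(path)
        np.testing.assert_array_equal(loaded.segments, ss.segments)
        np.testing.assert_array_equal(loaded.labels, ss.labels)
        assert loaded.channel_map == ss.channel_map
        assert loaded.provenance["participant_id"].tolist() == (
            ss.provenance["participant_id"].tolist()
        )
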