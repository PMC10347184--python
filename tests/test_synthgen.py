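"""Generator tests: score distributions, waveform structure, cohort layout."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import find_peaks, periodogram

from stresskit import synthgen
from stresskit.preprocess import score_to_class


def band_power(x, rate, lo, hi):
    f, p = periodogram(x, fs=rate)
    return p[(f >= lo) & (f <= hi)].sum()


class TestSampleScores:
    def test_paper_like_range_and_count(self):
        spec = synthgen.CohortSpec(seed=3)
        scores = synthgen.sample_scores(spec, mode="paper-like")
        assert len(scores) == 90
        assert scores["score"].between(0, 8).all()

    def test_paper_like_class_proportions_large_cohort(self):
        # observed cohort imbalance: 6030/1710/360 of 8100 segments
        spec = synthgen.CohortSpec(
            n_participants=300, n_medium=150, n_hard=150, seed=11
        )
        scores = synthgen.sample_scores(spec, mode="paper-like")
        classes = scores["score"].map(score_to_class)
        props = classes.value_counts(normalize=True).reindex([0, 1, 2]).fillna(0)
        expected = np.array([6030, 1710, 360]) / 8100
        assert np.all(np.abs(props.to_numpy() - expected) < 0.05)

    def test_balanced_class_proportions(self):
        spec = synthgen.CohortSpec(
            n_participants=300, n_medium=150, n_hard=150, seed=5
        )
        scores = synthgen.sample_scores(spec, mode="balanced")
        classes = scores["score"].map(score_to_class)
        props = classes.value_counts(normalize=True)
        assert props.between(0.28, 0.39).all()

    def test_scenario_score_ordering(self):
        spec = synthgen.CohortSpec(
            n_participants=200, n_medium=100, n_hard=100, seed=2
        )
        scores = synthgen.sample_scores(spec, mode="paper-like")
        by_scen = scores.groupby("scenario")["score"].mean()
        assert by_scen[1] >= by_scen[2] >= by_scen[3]
        scen1 = scores[scores.scenario == 1]
        assert (
            scen1[scen1.difficulty == "hard"].score.mean()
            >= scen1[scen1.difficulty == "medium"].score.mean()
        )

    def test_unknown_mode_rejected(self):
        with pytest.raises(synthgen.ConfigError):
            synthgen.sample_scores(synthgen.CohortSpec(), mode="nope")


class TestECG:
    def test_beat_count_matches_heart_rate(self):
        profile = synthgen.make_profile("P01", 1, "medium", 0)  # 60 bpm
        x, beats = synthgen.synth_ecg(
            profile, 10.0, 512.0, seed=4, wander_amp=0.0, noise_amp=0.0
        )
        assert x.shape == (5120,)
        peaks, _ = find_peaks(x, height=0.5, distance=int(0.4 * 512))
        assert abs(len(peaks) - 10) <= 1
        assert abs(len(beats) - 10) <= 1

    def test_rr_scales_with_heart_rate(self):
        lo = synthgen.make_profile("P01", 1, "medium", 0)  # 60 bpm
        hi = synthgen.make_profile("P01", 1, "medium", 8)  # 120 bpm
        _, beats_lo = synthgen.synth_ecg(lo, 60.0, 512.0, seed=9)
        _, beats_hi = synthgen.synth_ecg(hi, 60.0, 512.0, seed=9)
        ratio = np.diff(beats_hi).mean() / np.diff(beats_lo).mean()
        assert abs(ratio - 0.5) < 0.05

    def test_zero_duration_rejected(self):
        profile = synthgen.make_profile("P01", 1, "medium", 0)
        with pytest.raises(synthgen.ConfigError):
            synthgen.synth_ecg(profile, 0.0, 512.0)


class TestPPG:
    def test_shape_and_pulse_count(self):
        profile = synthgen.make_profile("P01", 1, "medium", 0)
        _, beats = synthgen.synth_ecg(profile, 10.0, 55.0 * 10, seed=1)
        ppg = synthgen.synth_ppg(profile, beats, 10.0, 55.0, seed=1, noise_amp=0.0)
        assert ppg.shape == (3, 550)
        peaks, _ = find_peaks(ppg[0], height=0.5, distance=int(0.5 * 55))
        assert abs(len(peaks) - len(beats)) <= 1

    def test_noise_free_channels_strongly_correlated(self):
        profile = synthgen.make_profile("P02", 1, "medium", 4)
        beats = np.arange(0.5, 9.5, 1.0)
        ppg = synthgen.synth_ppg(profile, beats, 10.0, 55.0, seed=2, noise_amp=0.0)
        for a in range(3):
            for b in range(a + 1, 3):
                assert np.corrcoef(ppg[a], ppg[b])[0, 1] >= 0.99

    def test_empty_beats_flatline(self, caplog):
        profile = synthgen.make_profile("P03", 1, "medium", 0)
        with caplog.at_level("WARNING"):
            ppg = synthgen.synth_ppg(profile, np.array([]), 5.0, 55.0)
        assert np.allclose(ppg, 0.0)
        assert any("flat-line" in r.message for r in caplog.records)


class TestEEG:
    def test_sample_count(self):
        profile = synthgen.make_profile("P01", 1, "medium", 0)
        x = synthgen.synth_eeg(profile, 10.0, 512.0, seed=0)
        assert x.shape == (5120,)

    def test_beta_alpha_ratio_rises_with_stress(self):
        relaxed = synthgen.make_profile("P01", 1, "medium", 0)
        stressed = synthgen.make_profile("P01", 1, "medium", 8)
        ratios = []
        for profile in (relaxed, stressed):
            x = synthgen.synth_eeg(profile, 30.0, 512.0, seed=21)
            ratios.append(
                band_power(x, 512.0, 13, 30) / band_power(x, 512.0, 8, 12)
            )
        assert ratios[1] > ratios[0]

    def test_zero_oscillation_gives_one_over_f(self):
        profile = synthgen.make_profile("P01", 1, "medium", 0)
        x = synthgen.synth_eeg(profile, 60.0, 256.0, seed=3, osc_amp=0.0)
        f, p = periodogram(x, fs=256.0)
        sel = (f > 1.0) & (f < 100.0)
        slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
        assert abs(slope - (-1.0)) < 0.3


class TestCohort:
    def test_session_count_and_difficulty_split(self, small_cohort):
        spec, sessions, manifest = small_cohort
        assert len(sessions) == spec.n_participants * len(spec.scenarios)
        per_participant = manifest.groupby("participant_id")["difficulty"].nunique()
        assert (per_participant == 1).all()
        counts = manifest.drop_duplicates("participant_id")["difficulty"].value_counts()
        assert counts["medium"] == spec.n_medium
        assert counts["hard"] == spec.n_hard

    def test_default_spec_difficulty_counts(self):
        manifest = synthgen.sample_scores(synthgen.CohortSpec(seed=0))
        counts = manifest.drop_duplicates("participant_id")["difficulty"].value_counts()
        assert counts["medium"] == 15 and counts["hard"] == 15

    def test_sample_counts_match_rates(self, small_cohort):
        spec, sessions, _ = small_cohort
        for sess in sessions:
            sess.validate()
            for mod, rate in spec.device_rates.items():
                expected = round(sess.duration_s * rate)
                assert abs(sess.signals[mod].shape[1] - expected) <= 1

    def test_determinism(self):
        spec = synthgen.CohortSpec(
            n_participants=2, n_medium=1, n_hard=1, scenarios=(1,),
            session_minutes=0.2, seed=42,
        )
        a, _ = synthgen.generate_cohort(spec)
        b, _ = synthgen.generate_cohort(spec)
        for sa, sb in zip(a, b):
            for mod in sa.signals:
                np.testing.assert_array_equal(sa.signals[mod], sb.signals[mod])

    def test_heart_rate_monotone_in_class(self):
        # within one participant, mean HR strictly rises and the alpha/beta
        # ratio strictly falls with the latent class
        profiles = [synthgen.make_profile("P01", 1, "hard", s) for s in (0, 6, 8)]
        hrs = [p.hr_bpm for p in profiles]
        ratios = [p.alpha_beta_ratio for p in profiles]
        assert hrs == sorted(hrs) and len(set(hrs)) == 3
        assert ratios == sorted(ratios, reverse=True) and len(set(ratios)) == 3

    def test_early_finish_truncation(self):
        spec = synthgen.CohortSpec(
            n_participants=4, n_medium=2, n_hard=2, scenarios=(1,),
            session_minutes=1.0, early_finish_fraction=0.5,
            early_finish_min_s=30.0, seed=3,
        )
        _, manifest = synthgen.generate_cohort(spec)
        assert (manifest["duration_s"] < spec.session_seconds).sum() == 2
        assert (manifest["duration_s"] >= spec.early_finish_min_s).all()

    def test_invalid_spec_rejected(self):
        with pytest.raises(synthgen.ConfigError):
            synthgen.CohortSpec(n_participants=10, n_medium=3, n_hard=3).validate()
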