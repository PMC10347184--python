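"""Synthetic multi-device stress-study cohorts.

Emulates a Sudoku-under-distraction protocol: 30 participants (15 assigned
medium-difficulty puzzles, 15 hard), three scenarios each (1: noisy/horror
stimuli, 2: observed by another person, 3: comforting stimuli), one 15-minute
recording per participant x scenario from three wearables — a 3-channel
optical pulse sensor (PPG, 55 Hz, green/red/infrared), a single-lead ECG
(512 Hz) and a single-channel forehead EEG (512 Hz) — plus a 0-8 self-report
stress score per session.

The generator's job is to give every downstream stage data with the
statistical structure the classifiers are supposed to exploit:

* heart rate rises and beat-to-beat variability falls with the latent stress
  class, monotonically within each participant;
* PPG pulse waves are phase-locked to the ECG beat process with a fixed
  pulse-transit delay, and the three optical channels are scaled copies of
  one pulse wave plus independent noise;
* EEG is 1/f background plus alpha (8-12 Hz) and beta (13-30 Hz) narrowband
  activity whose alpha/beta power ratio falls with stress;
* self-report scores follow either a heavily class-0-skewed mix matching the
  observed cohort imbalance ("paper-like") or a uniform mix ("balanced").

All randomness fans out from one cohort seed through ``numpy``
``SeedSequence`` spawns, so any single session is regenerable in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import score_to_class

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


# physiology defaults: nominal class heart rates 60/90/120 bpm, RR jitter
# (HRV proxy) shrinking and alpha/beta ratio falling as stress rises
HR_BASE_BPM = 60.0
HR_STEP_BPM = 30.0
HR_PARTICIPANT_SD = 1.5
RR_JITTER_BASE_S = 0.060
RR_JITTER_STEP_S = 0.015
ALPHA_BETA_BASE = 2.0
ALPHA_BETA_FACTOR = 0.55

# class mix observed in the real cohort: 6030/1710/360 of 8100 segments
PAPER_CLASS_PROBS = np.array([6030.0, 1710.0, 360.0]) / 8100.0

# score distribution within each class (class 0 spans scores 0-4, class 1
# spans 5-7, class 2 is exactly 8)
SCORES_BY_CLASS = {0: np.arange(5), 1: np.array([5, 6, 7]), 2: np.array([8])}
SCORE_WEIGHTS_BY_CLASS = {
    0: np.array([0.15, 0.20, 0.30, 0.20, 0.15]),
    1: np.array([0.4, 0.35, 0.25]),
    2: np.array([1.0]),
}

# log-space class tilts: scenario 1 (noisy) pushes scores up, scenario 3
# (comforting) down; hard puzzles push up slightly. Symmetric tilts keep the
# scenario-averaged class mix at PAPER_CLASS_PROBS to first order.
SCENARIO_TILT = {1: +0.45, 2: 0.0, 3: -0.45}
DIFFICULTY_TILT = {"medium": -0.15, "hard": +0.15}


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for one synthetic cohort."""

    n_participants: int = 30
    n_medium: int = 15
    n_hard: int = 15
    scenarios: tuple[int, ...] = (1, 2, 3)
    session_minutes: float = 15.0
    device_rates: dict = field(
        default_factory=lambda: {"ppg": 55.0, "ecg": 512.0, "eeg": 512.0}
    )
    early_finish_fraction: float = 0.10
    early_finish_min_s: float = 600.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants != self.n_medium + self.n_hard:
            raise ConfigError("n_participants must equal n_medium + n_hard")
        if self.session_minutes <= 0:
            raise ConfigError("session_minutes must be positive")
        if any(r <= 0 for r in self.device_rates.values()):
            raise ConfigError("all device rates must be positive")
        if not self.scenarios:
            raise ConfigError("at least one scenario required")

    @property
    def session_seconds(self) -> float:
        return self.session_minutes * 60.0


@dataclass(frozen=True)
class StressProfile:
    """Latent physiological state for one participant x scenario."""

    participant_id: str
    scenario: int
    difficulty: str
    score: int
    latent_class: int
    hr_bpm: float
    rr_jitter_s: float
    alpha_beta_ratio: float


@dataclass
class RawSession:
    """One participant x scenario multi-device recording."""

    participant_id: str
    scenario: int
    difficulty: str
    score: int
    duration_s: float
    rates: dict
    signals: dict  # modality -> (n_channels, n_samples)

    def validate(self) -> None:
        expected = {"ppg": 3, "ecg": 1, "eeg": 1}
        for mod, nch in expected.items():
            if mod in self.signals:
                arr = self.signals[mod]
                if arr.shape[0] != nch:
                    raise ConfigError(f"{mod} must have {nch} channel(s)")
                want = int(round(self.duration_s * self.rates[mod]))
                if abs(arr.shape[1] - want) > 1:
                    raise ConfigError(
                        f"{mod}: {arr.shape[1]} samples, expected ~{want}"
                    )


def make_profile(
    participant_id: str,
    scenario: int,
    difficulty: str,
    score: int,
    hr_base: float = HR_BASE_BPM,
) -> StressProfile:
    """Derive the latent physiology for a session from its self-report score."""
    cls = score_to_class(score)
    return StressProfile(
        participant_id=participant_id,
        scenario=scenario,
        difficulty=difficulty,
        score=score,
        latent_class=cls,
        hr_bpm=hr_base + HR_STEP_BPM * cls,
        rr_jitter_s=RR_JITTER_BASE_S - RR_JITTER_STEP_S * cls,
        alpha_beta_ratio=ALPHA_BETA_BASE * ALPHA_BETA_FACTOR**cls,
    )


def _class_probs(mode: str, scenario: int, difficulty: str) -> np.ndarray:
    if mode == "balanced":
        return np.full(3, 1.0 / 3.0)
    if mode != "paper-like":
        raise ConfigError(f"unknown score mode {mode!r}; use 'paper-like' or 'balanced'")
    tilt = SCENARIO_TILT.get(scenario, 0.0) + DIFFICULTY_TILT[difficulty]
    w = PAPER_CLASS_PROBS * np.exp(tilt * np.arange(3))
    return w / w.sum()


def sample_scores(
    spec: CohortSpec, mode: str = "paper-like", seed: int | None = None
) -> pd.DataFrame:
    """Draw one 0-8 self-report score per participant x scenario.

    ``paper-like`` reproduces the heavy class-0 skew of the observed cohort,
    with scenario 1 (noisy) scoring highest and scenario 3 (comforting)
    lowest, and hard-puzzle participants scoring slightly higher; ``balanced``
    draws the three classes uniformly for clean model-recovery experiments.
    """
    spec.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed if seed is None else seed, 101])
    )
    rows = []
    for p in range(spec.n_participants):
        difficulty = "medium" if p < spec.n_medium else "hard"
        pid = f"P{p + 1:02d}"
        for scen in spec.scenarios:
            probs = _class_probs(mode, scen, difficulty)
            cls = int(rng.choice(3, p=probs))
            scores = SCORES_BY_CLASS[cls]
            score = int(rng.choice(scores, p=SCORE_WEIGHTS_BY_CLASS[cls]))
            rows.append(
                {
                    "participant_id": pid,
                    "scenario": scen,
                    "difficulty": difficulty,
                    "score": score,
                    "latent_class": cls,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# signal synthesis


#: PQRST wave template: (time offset s relative to R, amplitude, width s)
_ECG_WAVES = (
    (-0.20, 0.15, 0.030),  # P
    (-0.035, -0.15, 0.010),  # Q
    (0.0, 1.00, 0.012),  # R
    (0.035, -0.25, 0.012),  # S
    (0.30, 0.35, 0.060),  # T
)


def ecg_beat_times(
    profile: StressProfile, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Beat (R-peak) times from an RR process: mean 60/HR with Gaussian jitter."""
    if duration_s <= 0:
        raise ConfigError("duration must be positive")
    mean_rr = 60.0 / profile.hr_bpm
    times = []
    t = float(rng.uniform(0.0, mean_rr))
    while t < duration_s:
        times.append(t)
        t += max(0.3, mean_rr + rng.normal(0.0, profile.rr_jitter_s))
    return np.asarray(times)


def _render_pulses(
    n: int, rate: float, event_times: np.ndarray, waves, half_width_s: float
) -> np.ndarray:
    """Sum localized Gaussian bumps around each event time (vectorized per event)."""
    out = np.zeros(n)
    half = int(round(half_width_s * rate))
    t = np.arange(-half, half + 1) / rate
    kernel = np.zeros_like(t)
    for off, amp, width in waves:
        kernel += amp * np.exp(-0.5 * ((t - off) / width) ** 2)
    for et in event_times:
        center = int(round(et * rate))
        lo, hi = center - half, center + half + 1
        klo = max(0, -lo)
        khi = kernel.size - max(0, hi - n)
        if khi <= klo:
            continue
        out[max(0, lo) : min(n, hi)] += kernel[klo:khi]
    return out


def synth_ecg(
    profile: StressProfile,
    duration_s: float,
    rate: float = 512.0,
    seed: int | np.random.Generator = 0,
    beat_times: np.ndarray | None = None,
    wander_amp: float = 0.05,
    noise_amp: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-periodic PQRST ECG with baseline wander and white noise.

    Returns ``(samples, beat_times)`` so the pulse generator can phase-lock
    to the same beat process.
    """
    if duration_s <= 0:
        raise ConfigError("duration must be positive")
    if rate < 100:
        raise ConfigError("ECG rate must be >= 100 Hz")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if beat_times is None:
        beat_times = ecg_beat_times(profile, duration_s, rng)
    n = int(round(duration_s * rate))
    x = _render_pulses(n, rate, beat_times, _ECG_WAVES, half_width_s=0.5)
    t = np.arange(n) / rate
    x += wander_amp * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    x += noise_amp * rng.standard_normal(n)
    return x, beat_times


#: systolic + diastolic pulse shape: (delay s after pulse onset, amp, width s)
_PPG_WAVES = ((0.0, 1.0, 0.12), (0.25, 0.45, 0.18))
#: pulse-transit delay from R-peak to pulse arrival at the wrist, s
PULSE_TRANSIT_S = 0.25
#: relative amplitude of the green/red/infrared channels
PPG_CHANNEL_GAINS = (1.0, 0.8, 0.6)


def synth_ppg(
    profile: StressProfile,
    beat_times: np.ndarray,
    duration_s: float,
    rate: float = 55.0,
    seed: int | np.random.Generator = 0,
    noise_amp: float = 0.03,
) -> np.ndarray:
    """3-channel pulse wave phase-locked to the ECG beat process.

    Each beat contributes one two-Gaussian (systolic/diastolic) pulse delayed
    by a fixed pulse-transit offset; the green/red/infrared channels are
    scaled copies of the same pulse train with independent sensor noise.
    """
    if duration_s <= 0:
        raise ConfigError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size == 0:
        logger.warning("empty beat_times: emitting flat-line PPG")
        return np.zeros((3, n))
    pulse = _render_pulses(
        n, rate, beat_times + PULSE_TRANSIT_S, _PPG_WAVES, half_width_s=0.9
    )
    out = np.empty((3, n))
    for c, gain in enumerate(PPG_CHANNEL_GAINS):
        out[c] = gain * pulse + noise_amp * rng.standard_normal(n)
    return out


def synth_eeg(
    profile: StressProfile,
    duration_s: float,
    rate: float = 512.0,
    seed: int | np.random.Generator = 0,
    osc_amp: float = 0.8,
) -> np.ndarray:
    """1/f background EEG plus alpha- and beta-band narrowband activity.

    Band powers split the oscillation budget according to the profile's
    alpha/beta ratio, so rising stress shows as relatively stronger beta.
    ``osc_amp=0`` gives a pure 1/f spectrum.
    """
    if duration_s <= 0:
        raise ConfigError("duration must be positive")
    if rate < 64:
        raise ConfigError("EEG rate must be >= 64 Hz")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    # 1/f background: shape a white spectrum by f^-1/2 (power ~ 1/f)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** -0.5
    background = np.fft.irfft(spec * shaping, n=n)
    background /= background.std() + 1e-12
    x = background
    if osc_amp > 0:
        r = profile.alpha_beta_ratio
        p_alpha = osc_amp**2 * r / (1.0 + r)
        p_beta = osc_amp**2 * 1.0 / (1.0 + r)
        for (lo, hi), power in (((8.0, 12.0), p_alpha), ((13.0, 30.0), p_beta)):
            sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
            band = signal.sosfilt(sos, rng.standard_normal(n))
            band /= band.std() + 1e-12
            x = x + np.sqrt(power) * band
    return x


def make_session(
    profile: StressProfile,
    duration_s: float,
    device_rates: dict | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> RawSession:
    """Synthesize one raw multi-device session for a given latent profile."""
    rates = dict(device_rates or {"ppg": 55.0, "ecg": 512.0, "eeg": 512.0})
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_ecg, rng_ppg, rng_eeg = (np.random.default_rng(s) for s in ss.spawn(3))
    ecg, beats = synth_ecg(profile, duration_s, rates["ecg"], rng_ecg)
    ppg = synth_ppg(profile, beats, duration_s, rates["ppg"], rng_ppg)
    eeg = synth_eeg(profile, duration_s, rates["eeg"], rng_eeg)
    return RawSession(
        participant_id=profile.participant_id,
        scenario=profile.scenario,
        difficulty=profile.difficulty,
        score=profile.score,
        duration_s=duration_s,
        rates=rates,
        signals={"ppg": ppg, "ecg": ecg[None, :], "eeg": eeg[None, :]},
    )


def generate_cohort(
    spec: CohortSpec, mode: str = "paper-like"
) -> tuple[list[RawSession], pd.DataFrame]:
    """Generate a full cohort of raw sessions plus a manifest table.

    Each participant keeps one puzzle difficulty across all scenarios; a
    configurable fraction of sessions is truncated below the nominal length
    to emulate early puzzle completion.  Fully reproducible from the spec's
    seed: every session draws from its own spawned random stream.
    """
    spec.validate()
    scores = sample_scores(spec, mode=mode)
    aux_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 8]))
    n_sessions = len(scores)
    n_early = int(round(spec.early_finish_fraction * n_sessions))
    early_idx = set(
        aux_rng.choice(n_sessions, size=n_early, replace=False).tolist()
    )
    # per-participant resting heart-rate offset, constant across scenarios so
    # class ordering stays monotonic within a participant
    hr_bases = {
        f"P{p + 1:02d}": HR_BASE_BPM + float(aux_rng.normal(0.0, HR_PARTICIPANT_SD))
        for p in range(spec.n_participants)
    }
    sessions: list[RawSession] = []
    for i, row in scores.iterrows():
        profile = make_profile(
            row.participant_id,
            int(row.scenario),
            row.difficulty,
            int(row.score),
            hr_base=hr_bases[row.participant_id],
        )
        duration = spec.session_seconds
        if i in early_idx:
            duration = float(
                aux_rng.uniform(spec.early_finish_min_s, spec.session_seconds)
            )
        sess = make_session(
            profile,
            duration,
            spec.device_rates,
            seed=np.random.SeedSequence([spec.seed, 7, int(i)]),
        )
        sessions.append(sess)
    manifest = scores.copy()
    manifest["duration_s"] = [s.duration_s for s in sessions]
    for mod, rate in spec.device_rates.items():
        manifest[f"rate_{mod}"] = rate
    return sessions, manifest


def balanced_recovery_cohort(
    n_per_class: int = 2,
    duration_s: float = 900.0,
    device_rates: dict | None = None,
    seed: int = 0,
) -> list[RawSession]:
    """Small strongly-separated cohort for model-recovery experiments.

    One synthetic participant per session, ``n_per_class`` sessions per stress
    class at the nominal class heart rates (60/90/120 bpm).  Scores are the
    class-representative values 0/6/8.
    """
    rep_score = {0: 0, 1: 6, 2: 8}
    sessions = []
    ss = np.random.SeedSequence([seed, 42])
    seeds = iter(ss.spawn(3 * n_per_class))
    for cls in range(3):
        for j in range(n_per_class):
            profile = make_profile(
                f"R{cls}{j}", 1, "medium", rep_score[cls]
            )
            sessions.append(
                make_session(profile, duration_s, device_rates, seed=next(seeds))
            )
    return sessions
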