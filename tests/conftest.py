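"""Shared fixtures: small synthetic cohorts and segment sets, built once."""

from __future__ import annotations

import numpy as np
import pytest

from stresskit import preprocess, synthgen


@pytest.fixture(scope="session")
def small_cohort():
    """6 participants x 3 scenarios, 1-minute sessions: fast structural tests."""
    spec = synthgen.CohortSpec(
        n_participants=6,
        n_medium=3,
        n_hard=3,
        session_minutes=1.0,
        early_finish_fraction=0.0,
        seed=7,
    )
    sessions, manifest = synthgen.generate_cohort(spec, mode="paper-like")
    return spec, sessions, manifest


@pytest.fixture(scope="session")
def recovery_segments():
    """Balanced ECG segment set with class heart rates 60/90/120 bpm.

    2 full-length sessions per class, every 3rd segment kept: 180 segments,
    60 per class.  Shared by the model-recovery and pretext tests.
    """
    sessions = synthgen.balanced_recovery_cohort(n_per_class=2, duration_s=900.0, seed=0)
    segment_set = preprocess.build_segment_set(sessions, ("ecg",))
    x = segment_set.segments[::3]
    y = segment_set.labels[::3]
    return x, y


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
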