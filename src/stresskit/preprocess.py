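"""Raw-recording preprocessing: fixed-grid resampling, Butterworth band-pass,
10-s segmentation, per-segment normalization, and self-report-to-class labeling.

Every recording, whatever its native rate or actual duration, is mapped onto a
fixed 230,400-sample grid (15 min at 256 Hz).  Sessions cut short by early
puzzle completion are therefore time-normalized rather than padded, and every
session contributes exactly 90 non-overlapping 10-s segments of 2560 samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

#: working sampling rate after resampling, Hz
GRID_RATE = 256.0
#: samples per session on the fixed grid (15 min at 256 Hz)
GRID_LEN = 230_400
#: samples per 10-s analysis segment at the working rate
SEGMENT_LEN = 2560
#: segments per full session (GRID_LEN // SEGMENT_LEN)
SEGMENTS_PER_SESSION = 90

#: channels contributed by each modality, in stacking order
MODALITY_CHANNELS = {
    "ppg": ("PPG1", "PPG2", "PPG3"),
    "ecg": ("ECG",),
    "eeg": ("EEG",),
}


class PreprocessError(ValueError):
    """Raised for invalid preprocessing configuration or inputs."""


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification for one modality at the working rate."""

    modality: str
    low_cut: float
    high_cut: float
    order: int = 4

    def validate(self, rate: float = GRID_RATE) -> None:
        nyq = rate / 2.0
        if not (0.0 < self.low_cut < self.high_cut < nyq):
            raise PreprocessError(
                f"{self.modality}: band [{self.low_cut}, {self.high_cut}] Hz "
                f"must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
            )
        if self.order < 1:
            raise PreprocessError(f"{self.modality}: filter order must be >= 1")


#: per-modality pass bands: PPG keeps the pulse wave (0.5-5 Hz), ECG the QRS
#: energy (5-15 Hz), EEG everything up to low beta (0.1-15 Hz)
DEFAULT_FILTERS = {
    "ppg": FilterSpec("ppg", 0.5, 5.0),
    "ecg": FilterSpec("ecg", 5.0, 15.0),
    "eeg": FilterSpec("eeg", 0.1, 15.0),
}


@dataclass
class SegmentSet:
    """Preprocessed windows ready for model training.

    Attributes
    ----------
    segments : float32 array, shape (n_segments, n_channels, 2560)
    labels : int array of stress classes 0/1/2, one per segment
    provenance : DataFrame with participant_id, scenario, difficulty, score,
        session_index and segment_index per row
    channel_map : channel names in stacking order, e.g. PPG1..PPG3, ECG, EEG
    """

    segments: np.ndarray
    labels: np.ndarray
    provenance: pd.DataFrame
    channel_map: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.segments.shape[0]

    @property
    def n_channels(self) -> int:
        return self.segments.shape[1]

    def save(self, path) -> None:
        prov = {}
        for c in self.provenance:
            arr = self.provenance[c].to_numpy()
            if arr.dtype == object:  # strings: keep the archive pickle-free
                arr = arr.astype(str)
            prov[f"prov_{c}"] = arr
        np.savez(
            path,
            segments=self.segments,
            labels=self.labels,
            channel_map=np.array(self.channel_map),
            **prov,
        )

    @classmethod
    def load(cls, path) -> "SegmentSet":
        with np.load(path, allow_pickle=False) as z:
            prov_cols = {
                k[len("prov_"):]: z[k] for k in z.files if k.startswith("prov_")
            }
            return cls(
                segments=z["segments"],
                labels=z["labels"],
                provenance=pd.DataFrame(prov_cols),
                channel_map=[str(c) for c in z["channel_map"]],
            )


def resample_to_grid(samples: np.ndarray, target_len: int = GRID_LEN) -> np.ndarray:
    """Band-limited resampling of a 1-D recording onto a fixed-length grid.

    The output length is ``target_len`` regardless of the input's length or
    native rate, so recordings that ended early are stretched onto the nominal
    session grid instead of padded.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 1:
        raise PreprocessError("resample_to_grid expects a 1-D channel")
    if samples.size < 2:
        raise PreprocessError("cannot resample a signal with fewer than 2 samples")
    return signal.resample(samples, target_len)


def design_bandpass(spec: FilterSpec, rate: float = GRID_RATE) -> np.ndarray:
    """Second-order-section Butterworth band-pass for `spec` at `rate`."""
    spec.validate(rate)
    return signal.butter(
        spec.order, [spec.low_cut, spec.high_cut], btype="bandpass", fs=rate, output="sos"
    )


def bandpass(samples: np.ndarray, spec: FilterSpec, rate: float = GRID_RATE) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass filtering.

    Forward-backward application cancels phase distortion and squares the
    magnitude response, preserving waveform morphology.
    """
    sos = design_bandpass(spec, rate)
    return signal.sosfiltfilt(sos, np.asarray(samples, dtype=np.float64), axis=-1)


def segment(
    samples: np.ndarray,
    window_s: float = 10.0,
    overlap: float = 0.0,
    rate: float = GRID_RATE,
) -> np.ndarray:
    """Cut a (..., L) signal into non-overlapping fixed windows.

    Returns an array of shape (n_windows, ..., window_len); the trailing
    remainder shorter than one window is dropped.
    """
    samples = np.asarray(samples)
    win = int(round(window_s * rate))
    if win < 1:
        raise PreprocessError("window must contain at least one sample")
    if not (0.0 <= overlap < 1.0):
        raise PreprocessError("overlap must lie in [0, 1)")
    hop = max(1, int(round(win * (1.0 - overlap))))
    length = samples.shape[-1]
    if length < win:
        logger.warning("signal of %d samples shorter than %d-sample window", length, win)
        return np.empty((0,) + samples.shape[:-1] + (win,), dtype=samples.dtype)
    starts = range(0, length - win + 1, hop)
    out = np.stack([samples[..., s : s + win] for s in starts], axis=0)
    return out


def normalize(seg: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Per-channel z-scoring of one (C, L) or (L,) segment.

    A constant channel cannot be scaled to unit variance; it is zero-filled
    with a warning instead of dividing by ~0.
    """
    seg = np.asarray(seg, dtype=np.float64)
    mean = seg.mean(axis=-1, keepdims=True)
    std = seg.std(axis=-1, keepdims=True)
    flat = std < eps
    if np.any(flat):
        logger.warning("constant channel(s) zero-filled during normalization")
    out = np.where(flat, 0.0, (seg - mean) / np.where(flat, 1.0, std))
    return out


def score_to_class(score: int) -> int:
    """Map a 0-8 self-report stress score to a 3-level class.

    0-4 -> 0 (relaxed / little stress), 5-7 -> 1 (medium), 8 -> 2 (high).
    """
    score = int(score)
    if not 0 <= score <= 8:
        raise PreprocessError(f"self-report score {score} outside [0, 8]")
    if score <= 4:
        return 0
    if score <= 7:
        return 1
    return 2


def session_channels(session, modalities: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Resample + filter one session's requested modalities onto the grid.

    Returns a (n_channels, GRID_LEN) stack and the channel names.
    """
    stacks: list[np.ndarray] = []
    names: list[str] = []
    for mod in modalities:
        if mod not in MODALITY_CHANNELS:
            raise PreprocessError(f"unknown modality {mod!r}")
        if mod not in session.signals:
            raise PreprocessError(
                f"session {session.participant_id}/scenario {session.scenario} "
                f"is missing modality {mod!r}"
            )
        raw = np.atleast_2d(session.signals[mod])
        expected = len(MODALITY_CHANNELS[mod])
        if raw.shape[0] != expected:
            raise PreprocessError(
                f"modality {mod!r} has {raw.shape[0]} channels, expected {expected}"
            )
        fspec = DEFAULT_FILTERS[mod]
        for ch_name, ch in zip(MODALITY_CHANNELS[mod], raw):
            gridded = resample_to_grid(ch)
            stacks.append(bandpass(gridded, fspec))
            names.append(ch_name)
    return np.stack(stacks, axis=0), names


def build_segment_set(
    sessions: Iterable,
    modalities: Sequence[str] = ("ppg", "ecg", "eeg"),
    window_s: float = 10.0,
) -> SegmentSet:
    """Run the full preprocessing chain over a cohort of raw sessions.

    Per session: resample each channel to the 230,400-sample grid, band-pass
    per modality, stack the requested channels, cut into 10-s segments, and
    z-score each segment per channel.  The session's stress class is broadcast
    to all of its segments.
    """
    all_segments: list[np.ndarray] = []
    labels: list[int] = []
    prov_rows: list[dict] = []
    channel_map: list[str] = []
    for sess_idx, session in enumerate(sessions):
        stacked, names = session_channels(session, modalities)
        if not channel_map:
            channel_map = names
        segs = segment(stacked, window_s=window_s)
        segs = np.stack([normalize(s) for s in segs], axis=0)
        cls = score_to_class(session.score)
        all_segments.append(segs.astype(np.float32))
        labels.extend([cls] * segs.shape[0])
        for seg_idx in range(segs.shape[0]):
            prov_rows.append(
                {
                    "participant_id": session.participant_id,
                    "scenario": session.scenario,
                    "difficulty": session.difficulty,
                    "score": session.score,
                    "session_index": sess_idx,
                    "segment_index": seg_idx,
                }
            )
    if not all_segments:
        raise PreprocessError("no sessions supplied")
    return SegmentSet(
        segments=np.concatenate(all_segments, axis=0),
        labels=np.asarray(labels, dtype=np.int64),
        provenance=pd.DataFrame(prov_rows),
        channel_map=channel_map,
    )
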