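"""Plain-text session storage emulating the wearables' raw text dumps.

One directory per session holding ``ppg.csv`` (t + 3 channels), ``ecg.csv``
and ``eeg.csv`` (t + 1 channel) and a ``meta`` key-value text file, plus a
cohort-level ``manifest.csv`` listing every session.  CSVs carry a timestamp
column so timestamp monotonicity can be checked on read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .synthgen import RawSession

logger = logging.getLogger(__name__)

_MODALITY_COLUMNS = {
    "ppg": ["PPG1", "PPG2", "PPG3"],
    "ecg": ["ECG"],
    "eeg": ["EEG"],
}


class SessionIOError(ValueError):
    pass


def session_dirname(participant_id: str, scenario: int) -> str:
    return f"{participant_id}_s{scenario}"


def write_session_dir(session: RawSession, path: str | Path) -> Path:
    """Write one session as CSV-per-modality plus a `meta` sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for mod, columns in _MODALITY_COLUMNS.items():
        arr = session.signals[mod]
        rate = session.rates[mod]
        t = np.arange(arr.shape[1]) / rate
        frame = pd.DataFrame({"t": t})
        for name, channel in zip(columns, arr):
            frame[name] = channel
        frame.to_csv(path / f"{mod}.csv", index=False, float_format="%.6f")
    meta_lines = [
        f"participant: {session.participant_id}",
        f"scenario: {session.scenario}",
        f"difficulty: {session.difficulty}",
        f"score: {session.score}",
        f"duration_s: {session.duration_s:.3f}",
    ] + [f"rate_{mod}: {session.rates[mod]}" for mod in _MODALITY_COLUMNS]
    (path / "meta").write_text("\n".join(meta_lines) + "\n")
    return path


def _read_meta(path: Path) -> dict:
    meta = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if ":" not in line:
            raise SessionIOError(f"{path}:{lineno}: malformed meta line {line!r}")
        key, value = line.split(":", 1)
        meta[key.strip()] = value.strip()
    return meta


def _read_modality_csv(path: Path, columns: list[str]) -> np.ndarray:
    if not path.exists():
        raise SessionIOError(f"missing file: {path}")
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # parser errors carry their own line numbers
        raise SessionIOError(f"{path}: {exc}") from exc
    missing = [c for c in ["t", *columns] if c not in frame.columns]
    if missing:
        raise SessionIOError(f"{path}: missing column(s) {missing}")
    bad = frame[frame.isna().any(axis=1)]
    if len(bad):
        # +2: one for the header row, one for 0- vs 1-based indexing
        raise SessionIOError(
            f"{path}: malformed row(s) at line(s) {[int(i) + 2 for i in bad.index[:5]]}"
        )
    t = frame["t"].to_numpy()
    if np.any(np.diff(t) <= 0):
        first = int(np.argmax(np.diff(t) <= 0)) + 2
        raise SessionIOError(f"{path}: non-monotone timestamps near line {first}")
    return frame[columns].to_numpy().T


def read_session_dir(path: str | Path) -> RawSession:
    """Parse one session directory back into a RawSession."""
    path = Path(path)
    meta_path = path / "meta"
    if not meta_path.exists():
        raise SessionIOError(f"missing file: {meta_path}")
    meta = _read_meta(meta_path)
    signals = {}
    rates = {}
    for mod, columns in _MODALITY_COLUMNS.items():
        signals[mod] = _read_modality_csv(path / f"{mod}.csv", columns)
        rates[mod] = float(meta[f"rate_{mod}"])
    return RawSession(
        participant_id=meta["participant"],
        scenario=int(meta["scenario"]),
        difficulty=meta["difficulty"],
        score=int(meta["score"]),
        duration_s=float(meta["duration_s"]),
        rates=rates,
        signals=signals,
    )


def write_cohort(
    sessions: list[RawSession], manifest: pd.DataFrame, out_dir: str | Path
) -> Path:
    """Write every session directory plus the cohort manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dirnames = []
    for session in sessions:
        name = session_dirname(session.participant_id, session.scenario)
        write_session_dir(session, out_dir / name)
        dirnames.append(name)
    manifest = manifest.copy()
    manifest["session_dir"] = dirnames
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir / "manifest.csv"


def read_cohort(manifest_path: str | Path) -> tuple[list[RawSession], pd.DataFrame]:
    """Load every session listed in a cohort manifest."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    root = manifest_path.parent
    sessions = [read_session_dir(root / name) for name in manifest["session_dir"]]
    return sessions, manifest
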