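"""Signal transformations for the self-supervised pretext task.

Five transformations — additive Gaussian noise, amplitude scaling, negation,
horizontal (time) flip, and piecewise permutation — are applied to already
segmented and normalized windows.  The pretext task is to recognize which
variant a window is (6-way: original + 5 transforms).  Time warping is
deliberately not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class TransformError(ValueError):
    pass


@dataclass(frozen=True)
class TransformSpec:
    """Parameters of the five pretext transformations.

    ``piece_len`` defaults to a quarter second at the 256 Hz working rate
    (64 samples); ``permute_pieces`` pieces of that length are relocated.
    ``derange=True`` forces every selected piece to end up at a different
    slot, giving the strongest learnable permutation signal.
    """

    noise_mu: float = 0.0
    noise_sigma: float = 0.01
    scale_factor: float = 1.1
    permute_pieces: int = 20
    piece_len: int = 64
    derange: bool = True

    def validate(self, segment_len: int) -> None:
        if self.noise_sigma <= 0:
            raise TransformError("noise_sigma must be positive")
        if self.scale_factor == 0:
            raise TransformError("scale_factor must be nonzero")
        if self.permute_pieces * self.piece_len > segment_len:
            raise TransformError(
                f"{self.permute_pieces} pieces x {self.piece_len} samples exceed "
                f"segment length {segment_len}"
            )


PRETEXT_LABELS = {
    0: "original",
    1: "noised",
    2: "scaled",
    3: "negated",
    4: "flipped",
    5: "permuted",
}
N_PRETEXT_CLASSES = len(PRETEXT_LABELS)


@dataclass
class TransformBatch:
    """Pretext-task examples: windows plus which-variant labels (0-5)."""

    inputs: np.ndarray  # (n, C, L)
    pretext_labels: np.ndarray  # (n,)

    def __len__(self) -> int:
        return self.inputs.shape[0]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def add_noise(segment: np.ndarray, spec: TransformSpec = TransformSpec(), seed=0) -> np.ndarray:
    """Add iid Gaussian noise (mu, sigma from spec) to every sample."""
    segment = np.asarray(segment)
    spec.validate(segment.shape[-1])
    rng = _rng(seed)
    return segment + rng.normal(spec.noise_mu, spec.noise_sigma, size=segment.shape)


def scale(segment: np.ndarray, spec: TransformSpec = TransformSpec()) -> np.ndarray:
    """Multiply the whole window by the spec's scale factor (default 1.1)."""
    return np.asarray(segment) * spec.scale_factor


def negate(segment: np.ndarray) -> np.ndarray:
    """Sign-flip the window (involution)."""
    return -np.asarray(segment)


def hflip(segment: np.ndarray) -> np.ndarray:
    """Reverse the window along time (involution)."""
    return np.asarray(segment)[..., ::-1]


def _piece_starts(n_pieces: int, piece_len: int, length: int, rng) -> np.ndarray:
    """Uniformly place `n_pieces` non-overlapping pieces: distribute the slack
    before each piece, which guarantees disjointness without rejection."""
    slack = length - n_pieces * piece_len
    cuts = np.sort(rng.integers(0, slack + 1, size=n_pieces))
    return cuts + np.arange(n_pieces) * piece_len


def _derangement(n: int, rng) -> np.ndarray:
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def permute(
    segment: np.ndarray,
    spec: TransformSpec = TransformSpec(),
    seed=0,
    return_info: bool = False,
):
    """Relocate the contents of randomly placed non-overlapping pieces.

    Selects ``spec.permute_pieces`` disjoint windows of ``spec.piece_len``
    samples (same positions for every channel) and rearranges their contents
    by a random derangement of the pieces; samples outside the pieces are
    untouched, so the multiset of values is conserved exactly.
    """
    segment = np.asarray(segment)
    spec.validate(segment.shape[-1])
    rng = _rng(seed)
    starts = _piece_starts(spec.permute_pieces, spec.piece_len, segment.shape[-1], rng)
    if spec.derange and spec.permute_pieces > 1:
        perm = _derangement(spec.permute_pieces, rng)
    else:
        perm = rng.permutation(spec.permute_pieces)
    out = segment.copy()
    for slot, src in enumerate(perm):
        s_dst, s_src = starts[slot], starts[src]
        out[..., s_dst : s_dst + spec.piece_len] = segment[
            ..., s_src : s_src + spec.piece_len
        ]
    if return_info:
        return out, starts, perm
    return out


def make_pretext_batch(
    segments: np.ndarray, spec: TransformSpec = TransformSpec(), seed=0
) -> TransformBatch:
    """Expand windows into a balanced, shuffled 6-way pretext batch.

    Every source window contributes its original (label 0) plus one copy per
    transformation (labels 1-5), so the label histogram is exactly uniform.
    """
    segments = np.asarray(segments)
    if segments.ndim == 2:
        segments = segments[:, None, :]
    if segments.shape[0] == 0:
        raise TransformError("empty segment array")
    rng = _rng(seed)
    inputs, labels = [], []
    for seg in segments:
        variants = (
            seg,
            add_noise(seg, spec, rng),
            scale(seg, spec),
            negate(seg),
            hflip(seg),
            permute(seg, spec, rng),
        )
        for label, v in enumerate(variants):
            inputs.append(np.ascontiguousarray(v, dtype=np.float32))
            labels.append(label)
    inputs = np.stack(inputs, axis=0)
    labels = np.asarray(labels, dtype=np.int64)
    order = rng.permutation(len(labels))
    return TransformBatch(inputs=inputs[order], pretext_labels=labels[order])
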