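"""Classification losses returning (loss, gradient-w.r.t.-logits)."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = float(-np.log(probs[np.arange(n), targets] + 1e-12).mean())
    dlogits = probs
    dlogits[np.arange(n), targets] -= 1.0
    return loss, (dlogits / n).astype(np.float32)
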