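"""The three stress-classification architectures over (C, 2560) segments.

* ``stressnext`` — a 1x1 projection followed by four multi-kernel blocks.
  Each block runs parallel convolutions with kernel sizes 1/3/5/7 at equal
  width and combines them by elementwise addition (not concatenation), then
  batch-norm, ReLU and stride-2 temporal downsampling; global average pooling
  and a dense layer emit the 3 class logits.
* ``lrcn`` — two convolutional layers and max pooling, two residual blocks
  separated by max pooling, then two stacked LSTM layers whose final state
  feeds the classifier (a 1-D adaptation of the long-term recurrent
  convolutional network baseline, without any attention module).
* ``sscnn`` — a three-block convolutional encoder (32/64/128 filters, kernel
  sizes 32/16/8, two convolutions per block, max pool size 8 stride 2) shared
  by reference between a 6-way pretext head and the 3-way classifier head;
  global max pooling reduces the final 128-filter feature maps to a
  128-feature embedding.

All models accept any of the study's signal combinations (1, 3, 4 or 5 input
channels) and emit 3 logits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

N_CLASSES = 3
SEGMENT_LEN = 2560


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class EncoderSpec:
    """Shared-layer spec for the self-supervised CNN.

    Exactly three blocks of (filters, kernel), two convolutions per block,
    each block closed by max pooling of size 8, stride 2.  Convolutions are
    unpadded in blocks 1-2 and length-preserving in block 3; the resulting
    layer lengths are computed, asserted internally, and never hard-coded.
    """

    blocks: tuple[tuple[int, int], ...] = ((32, 32), (64, 16), (128, 8))
    pool_size: int = 8
    pool_stride: int = 2
    paddings: tuple[str, ...] = ("valid", "valid", "same")

    def validate(self) -> None:
        if len(self.blocks) != 3:
            raise ModelError("encoder must have exactly 3 blocks")
        filters = [b[0] for b in self.blocks]
        if not all(a < b for a, b in zip(filters, filters[1:])):
            raise ModelError("encoder filter counts must be strictly increasing")

    @property
    def embedding_dim(self) -> int:
        return self.blocks[-1][0]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture + width knobs for one model instance."""

    model_name: str  # stressnext | lrcn | sscnn
    in_channels: int = 1
    n_classes: int = N_CLASSES
    # stressnext
    width: int = 64
    n_blocks: int = 4
    kernel_sizes: tuple[int, ...] = (1, 3, 5, 7)
    # lrcn
    conv_width: int = 64
    conv_kernel: int = 7
    res_kernel: int = 3
    lstm_hidden: int = 128
    # sscnn
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    pretext_classes: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.in_channels < 1:
            raise ModelError("in_channels must be >= 1")
        if self.n_classes != N_CLASSES:
            raise ModelError(f"n_classes must be {N_CLASSES}")
        if self.model_name not in {"stressnext", "lrcn", "sscnn"}:
            raise ModelError(f"unknown model {self.model_name!r}")


class MultiKernelBlock(nn.Module):
    """Parallel same-width convolutions (k=1/3/5/7) combined by addition,
    then batch-norm, ReLU and stride-2 max pooling."""

    def __init__(self, width: int, kernel_sizes, rng):
        super().__init__()
        self.branches = [
            nn.Conv1d(width, width, k, padding="same", rng=rng) for k in kernel_sizes
        ]
        self.bn = nn.BatchNorm1d(width)
        self.relu = nn.ReLU()
        self.pool = nn.MaxPool1d(2, 2)

    def forward(self, x):
        summed = self.branches[0].forward(x)
        for branch in self.branches[1:]:
            summed = summed + branch.forward(x)
        return self.pool.forward(self.relu.forward(self.bn.forward(summed)))

    def backward(self, dout):
        dsum = self.bn.backward(self.relu.backward(self.pool.backward(dout)))
        dx = self.branches[0].backward(dsum)
        for branch in self.branches[1:]:
            dx = dx + branch.backward(dsum)
        return dx


class ResidualBlock(nn.Module):
    """Two convolutions with an identity skip: y = x + conv2(relu(conv1(x))).

    With all conv weights zero this is exactly the identity map.
    """

    def __init__(self, width: int, kernel: int, rng):
        super().__init__()
        self.conv1 = nn.Conv1d(width, width, kernel, padding="same", rng=rng)
        self.relu = nn.ReLU()
        self.conv2 = nn.Conv1d(width, width, kernel, padding="same", rng=rng)

    def forward(self, x):
        return x + self.conv2.forward(self.relu.forward(self.conv1.forward(x)))

    def backward(self, dout):
        return dout + self.conv1.backward(self.relu.backward(self.conv2.backward(dout)))


class StressNeXt(nn.Module):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__()
        self.in_channels = spec.in_channels
        self.stem = nn.Conv1d(spec.in_channels, spec.width, 1, padding="valid", rng=rng)
        self.blocks = [
            MultiKernelBlock(spec.width, spec.kernel_sizes, rng)
            for _ in range(spec.n_blocks)
        ]
        self.gap = nn.GlobalAvgPool1d()
        self.head = nn.Dense(spec.width, spec.n_classes, rng=rng)

    def forward(self, x):
        x = self.stem.forward(x)
        for block in self.blocks:
            x = block.forward(x)
        return self.head.forward(self.gap.forward(x))

    def backward(self, dout):
        dx = self.gap.backward(self.head.backward(dout))
        for block in reversed(self.blocks):
            dx = block.backward(dx)
        return self.stem.backward(dx)


class LRCN(nn.Module):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__()
        self.in_channels = spec.in_channels
        w, k = spec.conv_width, spec.conv_kernel
        self.body = nn.Sequential(
            nn.Conv1d(spec.in_channels, w, k, padding="same", rng=rng),
            nn.ReLU(),
            nn.Conv1d(w, w, k, padding="same", rng=rng),
            nn.ReLU(),
            nn.MaxPool1d(2, 2),
            ResidualBlock(w, spec.res_kernel, rng),
            nn.MaxPool1d(2, 2),
            ResidualBlock(w, spec.res_kernel, rng),
            nn.MaxPool1d(2, 2),
            nn.ToTimeMajor(),
            nn.LSTM(w, spec.lstm_hidden, rng=rng),
            nn.LSTM(spec.lstm_hidden, spec.lstm_hidden, rng=rng),
            nn.LastStep(),
            nn.Dense(spec.lstm_hidden, spec.n_classes, rng=rng),
        )

    def forward(self, x):
        return self.body.forward(x)

    def backward(self, dout):
        return self.body.backward(dout)


class SSCNNEncoder(nn.Module):
    """Shared convolutional layers of the self-supervised CNN."""

    def __init__(self, spec: EncoderSpec, in_channels: int, rng: np.random.Generator):
        super().__init__()
        spec.validate()
        self.spec = spec
        self.in_channels = in_channels
        layers: list[nn.Module] = []
        prev = in_channels
        for (filters, kernel), padding in zip(spec.blocks, spec.paddings):
            layers += [
                nn.Conv1d(prev, filters, kernel, padding=padding, rng=rng),
                nn.ReLU(),
                nn.Conv1d(filters, filters, kernel, padding=padding, rng=rng),
                nn.ReLU(),
                nn.MaxPool1d(spec.pool_size, spec.pool_stride),
            ]
            prev = filters
        self.body = nn.Sequential(*layers)

    def forward(self, x):
        return self.body.forward(x)

    def backward(self, dout):
        return self.body.backward(dout)

    def feature_lengths(self, length: int = SEGMENT_LEN) -> list[int]:
        """Per-layer output lengths for an input of `length` samples."""
        lengths = []
        for layer in self.body.layers:
            if hasattr(layer, "out_length"):
                length = layer.out_length(length)
            lengths.append(length)
        return lengths


class SSCNNHead(nn.Module):
    """Global max pooling + dense head over a (possibly shared) encoder."""

    def __init__(self, encoder: SSCNNEncoder, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.encoder = encoder
        self.in_channels = encoder.in_channels
        self.gmp = nn.GlobalMaxPool1d()
        self.head = nn.Dense(encoder.spec.embedding_dim, n_out, rng=rng)

    def forward(self, x):
        return self.head.forward(self.gmp.forward(self.encoder.forward(x)))

    def backward(self, dout):
        return self.encoder.backward(self.gmp.backward(self.head.backward(dout)))

    def embed(self, x) -> np.ndarray:
        """Pooled embedding (batch, embedding_dim) without the dense head."""
        return self.gmp.forward(self.encoder.forward(x))


def build_stressnext(spec: ModelSpec) -> StressNeXt:
    spec.validate()
    return StressNeXt(spec, np.random.default_rng(spec.seed))


def build_lrcn(spec: ModelSpec) -> LRCN:
    spec.validate()
    return LRCN(spec, np.random.default_rng(spec.seed))


def build_sscnn_encoder(spec: ModelSpec) -> SSCNNEncoder:
    spec.validate()
    return SSCNNEncoder(spec.encoder, spec.in_channels, np.random.default_rng(spec.seed))


def build_sscnn_heads(
    encoder: SSCNNEncoder, spec: ModelSpec
) -> tuple[SSCNNHead, SSCNNHead]:
    """Pretext (6-way) and classifier (3-way) heads sharing one encoder.

    Sharing is by reference: pretext-stage weight updates are visible to the
    classifier before its own training starts.
    """
    if encoder.in_channels != spec.in_channels:
        raise ModelError("encoder channel count does not match spec")
    rng = np.random.default_rng(spec.seed + 1)
    pretext = SSCNNHead(encoder, spec.pretext_classes, rng)
    classifier = SSCNNHead(encoder, spec.n_classes, rng)
    return pretext, classifier


def build_model(spec: ModelSpec) -> nn.Module:
    """Build the classifier network named by the spec."""
    if spec.model_name == "stressnext":
        return build_stressnext(spec)
    if spec.model_name == "lrcn":
        return build_lrcn(spec)
    if spec.model_name == "sscnn":
        encoder = build_sscnn_encoder(spec)
        _, classifier = build_sscnn_heads(encoder, spec)
        return classifier
    raise ModelError(f"unknown model {spec.model_name!r}")


def forward(model: nn.Module, batch: np.ndarray) -> np.ndarray:
    """Inference-mode forward pass with input validation."""
    batch = np.asarray(batch, dtype=np.float32)
    if batch.ndim != 3:
        raise ModelError("batch must be (n, channels, length)")
    if batch.shape[1] != getattr(model, "in_channels", batch.shape[1]):
        raise ModelError(
            f"batch has {batch.shape[1]} channels, model expects {model.in_channels}"
        )
    if not np.isfinite(batch).all():
        raise ModelError("batch contains NaN or infinite values")
    was_training = model.training
    model.eval()
    out = model.forward(batch)
    if was_training:
        model.train()
    return out
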