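"""Run configuration: one YAML-serializable object tying all stages together.

Stage defaults equal the protocol's stated values (256 Hz / 230,400-sample
grid; 0.5-5, 5-15, 0.1-15 Hz bands; 10-s windows; noise sigma 0.01; scale
1.1; 20 x 64-sample permutation pieces; k=3; Adam lr 0.001; 300/150 epochs).
One global seed fans out to per-stage seeds.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .evalpipe import TrainConfig
from .preprocess import DEFAULT_FILTERS, GRID_LEN, GRID_RATE
from .synthgen import CohortSpec
from .transforms import TransformSpec


class ConfigFileError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    out_dir: str = "runs/default"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    score_mode: str = "paper-like"
    modalities: tuple[str, ...] = ("ppg", "ecg", "eeg")
    transform: TransformSpec = field(default_factory=TransformSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    models: tuple[str, ...] = ("stressnext", "lrcn", "sscnn")
    grid_rate: float = GRID_RATE
    grid_len: int = GRID_LEN
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        self.train.validate()
        for mod in self.modalities:
            if mod not in DEFAULT_FILTERS:
                raise ConfigFileError(f"unknown modality {mod!r}")
            DEFAULT_FILTERS[mod].validate(self.grid_rate)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(
            self,
            seed=seed,
            cohort=replace(self.cohort, seed=seed),
            train=replace(self.train, seed=seed + 1),
        )


def save_config(config: RunConfig, path: str | Path) -> None:
    payload = asdict(config)
    payload["cohort"]["scenarios"] = list(config.cohort.scenarios)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    try:
        cohort = raw.pop("cohort", {})
        cohort["scenarios"] = tuple(cohort.get("scenarios", (1, 2, 3)))
        transform = raw.pop("transform", {})
        train = raw.pop("train", {})
        for key in ("modalities", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        config = RunConfig(
            cohort=CohortSpec(**cohort),
            transform=TransformSpec(**transform),
            train=TrainConfig(**train),
            **raw,
        )
    except TypeError as exc:
        raise ConfigFileError(f"{path}: {exc}") from exc
    config.validate()
    return config
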