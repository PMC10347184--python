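"""End-to-end orchestration: synth -> preprocess -> train/evaluate -> report."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import evalpipe, preprocess, session_io, synthgen
from .config import RunConfig, save_config

logger = logging.getLogger(__name__)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


class PipelineError(RuntimeError):
    pass


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.1fs", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


@_stage("synth")
def stage_synth(config: RunConfig, out_dir: Path):
    sessions, manifest = synthgen.generate_cohort(config.cohort, mode=config.score_mode)
    manifest_path = session_io.write_cohort(sessions, manifest, out_dir / "sessions")
    return sessions, manifest, manifest_path


@_stage("preprocess")
def stage_preprocess(config: RunConfig, sessions, out_dir: Path):
    segment_set = preprocess.build_segment_set(sessions, config.modalities)
    segment_set.save(out_dir / "segments.npz")
    logger.info(
        "segment set: %d segments x %d channels", len(segment_set), segment_set.n_channels
    )
    return segment_set

@_stage("evaluate")
def stage_evaluate(config: RunConfig, segment_set, out_dir: Path, combinations=None,
                   breakdowns: bool = True, model_overrides=None):
    reports = evalpipe.evaluate_suite(
        segment_set,
        model_names=config.models,
        combinations=combinations or evalpipe.SIGNAL_COMBINATIONS,
        config=config.train,
        breakdowns=breakdowns,
        model_overrides=model_overrides,
    )
    table = evalpipe.reports_table(reports)
    table.to_csv(out_dir / "results.csv", index=False)
    for report in reports:
        tag = f"{report.model_name}_{'-'.join(report.combination)}_{report.subset}"
        tag = tag.replace(":", "")
        np.savetxt(out_dir / f"confusion_{tag}.csv", report.confusion, delimiter=",")
    return reports


def run_pipeline(
    config: RunConfig,
    combinations=None,
    breakdowns: bool = True,
    model_overrides=None,
):
    """Run every stage in order, stamping artifacts with the config hash."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(config, out_dir / "config.yaml")
    (out_dir / "config_hash.txt").write_text(config_hash(config) + "\n")
    sessions, manifest, _ = stage_synth(config, out_dir)
    segment_set = stage_preprocess(config, sessions, out_dir)
    summary = evalpipe.selfreport_summary(manifest)
    summary.to_csv(out_dir / "selfreport_summary.csv", index=False)
    reports = stage_evaluate(
        config, segment_set, out_dir,
        combinations=combinations, breakdowns=breakdowns,
        model_overrides=model_overrides,
    )
    return reports
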