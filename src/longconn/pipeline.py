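"""End-to-end orchestration: simulate -> FC -> split/augment/train -> evaluate.

A single :class:`RunConfig` document (YAML or JSON) drives the whole run.
Unknown keys are rejected up front, every artifact carries the config hash
and the global seed, and per-stage seeds are derived deterministically from
the global seed, so re-running an identical config reproduces byte-identical
metrics tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .augment import GANConfig
from .cohort import CohortSpec, simulate_cohort, write_cohort
from .evaluate import METHODS, run_comparison
from .model import CNNConfig, StackConfig, TrainConfig

logger = logging.getLogger("longconn")

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "load_run_config"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % (2**31)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortSection(_Strict):
    roi_count: int = 20
    frames_per_scan: int = 130
    group_sizes: dict[str, int] = Field(
        default_factory=lambda: {"NC": 50, "sMCI": 50, "pMCI": 50, "AD": 50})
    edge_effect: float = 0.25
    progression_rate: float = 0.1
    affected_edge_fraction: float = 0.3
    subject_noise_sd: float = 0.1
    subject_scale_sd: float = 0.0
    trajectory_only: bool = False
    frame_period: float = 3.0


class TrainSection(_Strict):
    epochs: int = 60
    batch_size: int = 16
    learning_rate: float = 1e-3


class CNNSection(_Strict):
    blocks: list[list[int]] = Field(
        default_factory=lambda: [[16, 5, 2], [32, 5, 2], [64, 5, 2]])
    shortcut_pairs: list[list] = Field(default_factory=lambda: [[1, 3], [2, "output"]])
    feature_dim: int = 64


class StackSection(_Strict):
    num_lstm_layers: int = 3
    hidden_size: int = 64
    dropout: float = 0.2


class GANSection(_Strict):
    noise_dim: int = 32
    generator_widths: list[int] = Field(default_factory=lambda: [64, 64])
    discriminator_widths: list[int] = Field(default_factory=lambda: [64, 32])
    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 2e-4
    per_class: bool = True


class EvaluateSection(_Strict):
    methods: list[str] = Field(default_factory=lambda: list(METHODS))
    scope: str = "all"
    k: int = 5
    augment_ratio: float = 0.0
    val_fraction: float = 0.2


class RunConfig(_Strict):
    """Whole-run configuration; round-trips losslessly through YAML/JSON."""

    seed: int = 0
    task: str = "nc-ad"
    output_dir: str = "runs/run"
    cohort: CohortSection = Field(default_factory=CohortSection)
    train: TrainSection = Field(default_factory=TrainSection)
    cnn: CNNSection = Field(default_factory=CNNSection)
    stack: StackSection = Field(default_factory=StackSection)
    gan: GANSection = Field(default_factory=GANSection)
    evaluate: EvaluateSection = Field(default_factory=EvaluateSection)

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig.model_validate(data)


def _cnn_config(section: CNNSection) -> CNNConfig:
    return CNNConfig(blocks=tuple(tuple(b) for b in section.blocks),
                     shortcut_pairs=tuple((p[0], p[1]) for p in section.shortcut_pairs),
                     feature_dim=section.feature_dim)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute every stage in fixed order; returns the run directory.

    Stage failures propagate with the stage name prefixed so partial
    artifacts remain inspectable.
    """
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    record: dict = {"config": config.model_dump(), "config_hash": chash,
                    "seed": config.seed,
                    "stage_seeds": {s: stage_seed(config.seed, s)
                                    for s in ("simulate", "evaluate")}}

    def _stage(name):
        logger.info("stage %s: start (config %s)", name, chash)

    try:
        _stage("simulate")
        spec = CohortSpec(**config.cohort.model_dump(),
                          seed=stage_seed(config.seed, "simulate"))
        cohort = simulate_cohort(spec)
        write_cohort(cohort, out / "cohort")
    except Exception as exc:  # noqa: BLE001 — stage-named rethrow
        raise RuntimeError(f"stage simulate failed: {exc}") from exc

    try:
        _stage("evaluate")
        ev = config.evaluate
        result = run_comparison(
            cohort, task=config.task, methods=tuple(ev.methods), scope=ev.scope,
            k=ev.k, seed=stage_seed(config.seed, "evaluate"),
            augment_ratio=ev.augment_ratio,
            train_config=TrainConfig(epochs=config.train.epochs,
                                     batch_size=config.train.batch_size,
                                     learning_rate=config.train.learning_rate),
            cnn_config=_cnn_config(config.cnn),
            stack_config=StackConfig(**config.stack.model_dump()),
            gan_config=GANConfig(**config.gan.model_dump(),
                                 seed=stage_seed(config.seed, "evaluate")),
            val_fraction=ev.val_fraction)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage evaluate failed: {exc}") from exc

    _stage("report")
    table = result.table.copy()
    table.insert(0, "config_hash", chash)
    table.to_csv(out / "metrics.tsv", sep="\t", index=False)
    record["fold_assignment"] = result.fold_assignment.folds
    loss_rows = []
    for (method, sc), det in result.details.items():
        pts = det.metrics.roc_points
        np.savetxt(out / f"roc_{method}_{sc}.tsv", pts, delimiter="\t",
                   header="fpr\ttpr", comments="")
        for curve in det.loss_curves:
            for epoch, (tr, va) in enumerate(zip(curve["train"], curve["val"])):
                loss_rows.append({"method": method, "timepoint": sc,
                                  "fold": curve["fold"], "epoch": epoch,
                                  "train_loss": tr, "val_loss": va})
    if loss_rows:
        pd.DataFrame(loss_rows).to_csv(out / "loss_curves.tsv", sep="\t",
                                       index=False, float_format="%.8g")
    with open(out / "run_record.json", "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
    logger.info("run complete: %s", out)
    return out
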