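"""Common-tissue warm-up of the language-model classifier.

Before per-tissue few-shot adaptation, the classifier is fine-tuned in full
mode on screening data from *common* tissues only (an 80/20 label-stratified
train/validation split).  After every epoch the validation AUPRC/AUROC are
logged, and the epoch checkpoint with the best selection metric is returned
(a flag selects the final epoch instead).  Rare-tissue rows must never enter
warm-up; an injected rare example raises ``LeakageError``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import LabeledExample
from .kshot import SplitSpec, split_tissue
from .metrics import auprc, auroc
from .model import ClassifierModel, FineTuneConfig, fine_tune
from .textgen import prompt_for_record


class LeakageError(RuntimeError):
    """A rare-tissue example reached common-tissue warm-up."""


@dataclass(frozen=True)
class WarmupConfig:
    train_fraction: float = 0.8
    epochs: int = 4
    learning_rate: float = 5e-5
    weight_decay: float = 0.01
    batch_size: int = 8
    selection_metric: str = "auprc"
    seed: int = 0
    use_final_epoch: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.selection_metric not in ("auprc", "auroc"):
            raise ValueError("selection_metric must be 'auprc' or 'auroc'")


@dataclass
class WarmupResult:
    model: ClassifierModel
    trace: list[dict] = field(default_factory=list)
    best_epoch: int = -1


def warm_up(
    model: ClassifierModel,
    common_examples: Sequence[LabeledExample],
    config: WarmupConfig,
    rare_tissues: Sequence[str] | None = None,
) -> WarmupResult:
    """Full-mode fine-tuning on common tissues with epoch-level selection."""
    if rare_tissues:
        rare = set(rare_tissues)
        leaked = sorted({ex.record.tissue for ex in common_examples} & rare)
        if leaked:
            raise LeakageError(f"rare tissue(s) in warm-up data: {leaked}")
    labels = {ex.y for ex in common_examples}
    if labels != {0, 1}:
        raise ValueError("warm-up requires both classes in the common data")

    train, val = split_tissue(
        common_examples, SplitSpec(1.0 - config.train_fraction, config.seed)
    )
    val_prompts = [prompt_for_record(ex.record) for ex in val]
    val_labels = [ex.y for ex in val]

    trace: list[dict] = []
    best = {"metric": -np.inf, "epoch": -1, "state": None}

    def snapshot() -> dict:
        state = {k: v.data.copy() for k, v in model.backbone.params.items()}
        state["__head_w"] = model.head_w.data.copy()
        state["__head_b"] = model.head_b.data.copy()
        return state

    def on_epoch(epoch: int, train_loss: float) -> None:
        scores = model.predict_proba(val_prompts, batch_size=max(config.batch_size, 32))
        row = {
            "epoch": epoch,
            "train_loss": train_loss,
            "val_auprc": auprc(val_labels, scores),
            "val_auroc": auroc(val_labels, scores),
        }
        trace.append(row)
        metric = row[f"val_{config.selection_metric}"]
        if metric > best["metric"]:
            best.update(metric=metric, epoch=epoch, state=snapshot())

    fine_tune(
        model,
        train,
        FineTuneConfig(
            learning_rate=config.learning_rate,
            weight_decay=config.weight_decay,
            epochs=config.epochs,
            batch_size=config.batch_size,
            seed=config.seed,
            strategy="full",
        ),
        epoch_callback=on_epoch,
    )

    if config.use_final_epoch:
        return WarmupResult(model, trace, best_epoch=config.epochs - 1)
    state = best["state"]
    for name, tensor in model.backbone.params.items():
        tensor.data = state[name]
    model.head_w.data = state["__head_w"]
    model.head_b.data = state["__head_b"]
    return WarmupResult(model, trace, best_epoch=best["epoch"])
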