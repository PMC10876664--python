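"""Per-rare-tissue few-shot protocol.

Each rare tissue is split once into 80% train / 20% test with the binary
labels represented in both sets proportionally.  Nested shot sets S_2 c S_4
c ... c S_128 are drawn from the train side: each set keeps all previously
selected shots and adds new ones, its label composition follows the tissue's
own label proportion, and every set of size >= 2 contains at least one
positive and one negative.  The test set is byte-identical across all k.

``run_grid`` evaluates registered model arms over (tissue, k, seed) cells;
every arm is re-fit from its base state on the full nested shot set (cells
are independent and reproducible), with k = 0 routed to the arm's zero-shot
path.
"""

from __future__ import annotations

import hashlib
import logging
import math
import zlib
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .data import LabeledExample
from .metrics import auprc, auroc, metrics_table

logger = logging.getLogger(__name__)

DEFAULT_SCHEDULE = (0, 2, 4, 8, 16, 32, 64, 128)


class ProtocolError(RuntimeError):
    """A tissue cannot satisfy the split/shot balance constraints."""


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ShotSchedule:
    ks: tuple[int, ...] = DEFAULT_SCHEDULE

    def __post_init__(self) -> None:
        ks = tuple(self.ks)
        object.__setattr__(self, "ks", ks)
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("shot counts must be strictly increasing")
        for pos, k in enumerate(ks):
            if k == 0 and pos != 0:
                raise ValueError("0 is allowed only as the first shot count")
            if k < 0 or (k > 0 and k % 2):
                raise ValueError("nonzero shot counts must be positive and even")

    @property
    def nonzero(self) -> tuple[int, ...]:
        return tuple(k for k in self.ks if k > 0)


@dataclass(frozen=True)
class ShotSet:
    k: int
    examples: tuple[LabeledExample, ...]
    parent: "ShotSet | None" = None

    def __post_init__(self) -> None:
        examples = tuple(self.examples)
        object.__setattr__(self, "examples", examples)
        if len(examples) != self.k:
            raise ValueError(f"shot set size {len(examples)} != k={self.k}")
        labels = {ex.y for ex in examples}
        if self.k >= 2 and labels != {0, 1}:
            raise ValueError("every shot set with k >= 2 must contain both classes")
        if self.parent is not None and not set(self.parent.examples) <= set(examples):
            raise ValueError("shot sets must be nested")


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_tissue(
    examples: Sequence[LabeledExample], spec: SplitSpec
) -> tuple[list[LabeledExample], list[LabeledExample]]:
    """Label-stratified, seeded train/test split of one tissue's examples."""
    rng = np.random.default_rng(spec.seed)
    test_idx: set[int] = set()
    for cls in (0, 1):
        idx = [i for i, ex in enumerate(examples) if ex.y == cls]
        if len(idx) < 2:
            raise ProtocolError(
                f"class {cls} has {len(idx)} example(s); need >= 2 per class"
            )
        n_test = round_half_up(spec.test_fraction * len(idx))
        chosen = rng.permutation(len(idx))[:n_test]
        test_idx.update(idx[i] for i in chosen)
    train = [ex for i, ex in enumerate(examples) if i not in test_idx]
    test = [ex for i, ex in enumerate(examples) if i in test_idx]
    return train, test


def sample_nested_shots(
    train: Sequence[LabeledExample], schedule: ShotSchedule, seed: int
) -> list[ShotSet]:
    """Nested, proportion-preserving shot sets from the training split.

    Per-class quotas are round-half-up of k times the class proportion,
    repaired to keep >= 1 of each class and sum k (majority class absorbs
    the adjustment); shot counts that exceed the training size or whose
    quotas are infeasible are dropped with a warning.
    """
    pos = [ex for ex in train if ex.y == 1]
    neg = [ex for ex in train if ex.y == 0]
    if not pos or not neg:
        raise ProtocolError("training split must contain both classes")
    rng = np.random.default_rng(seed)
    pos = [pos[i] for i in rng.permutation(len(pos))]
    neg = [neg[i] for i in rng.permutation(len(neg))]
    p_pos = len(pos) / len(train)

    sets: list[ShotSet] = []
    prev: ShotSet | None = None
    prev_q1 = 0
    for k in schedule.nonzero:
        if k > len(train):
            logger.warning("dropping k=%d: larger than the training split (%d)", k, len(train))
            break
        q1 = round_half_up(k * p_pos)
        q1 = min(max(q1, 1), k - 1)          # >= 1 of each class
        q1 = max(q1, prev_q1)                # nesting monotonicity
        q1 = min(q1, len(pos))               # pool feasibility
        q0 = k - q1
        if q0 > len(neg):
            q0 = len(neg)
            q1 = k - q0
        if q1 < 1 or q0 < 1 or q1 > len(pos) or q0 > len(neg) or q1 < prev_q1:
            logger.warning("dropping k=%d: per-class quota infeasible", k)
            break
        shot_set = ShotSet(k, tuple(pos[:q1] + neg[:q0]), parent=prev)
        sets.append(shot_set)
        prev, prev_q1 = shot_set, q1
    return sets


def fingerprint(examples: Sequence[LabeledExample]) -> str:
    """Order-sensitive content hash of an example list."""
    digest = hashlib.sha256()
    for ex in examples:
        digest.update(repr((ex.record, ex.y)).encode())
    return digest.hexdigest()


class Arm(Protocol):
    """One model entry in the experiment grid."""

    name: str

    def fit_shots(self, shots: Sequence[LabeledExample], seed: int):
        """Fit a fresh copy of the base model on the shot set."""

    def score(self, fitted, examples: Sequence[LabeledExample]) -> np.ndarray:
        """Positive-class scores for the examples."""

    def zero_shot(self, examples: Sequence[LabeledExample]) -> np.ndarray | None:
        """k = 0 scores, or None when the arm has no zero-shot path."""


def _tissue_seed(seed: int, tissue: str, salt: int) -> int:
    return int((zlib.crc32(tissue.encode()) + 1000003 * seed + salt) % (2**31 - 1))


def run_grid(
    arms: Sequence[Arm],
    tissues: dict[str, Sequence[LabeledExample]],
    schedule: ShotSchedule,
    seeds: Sequence[int],
    test_fraction: float = 0.2,
) -> pd.DataFrame:
    """Evaluate every (model, tissue, k, seed) cell on the fixed test split."""
    rows = []
    for seed in seeds:
        for tissue, examples in tissues.items():
            split_seed = _tissue_seed(seed, tissue, 0)
            try:
                train, test = split_tissue(examples, SplitSpec(test_fraction, split_seed))
            except ProtocolError as err:
                raise ProtocolError(f"tissue {tissue!r}: {err}") from err
            shot_sets = {
                s.k: s
                for s in sample_nested_shots(
                    train, schedule, _tissue_seed(seed, tissue, 1)
                )
            }
            test_examples = set(test)
            for s in shot_sets.values():
                assert not (set(s.examples) & test_examples), "train/test leakage"
            labels = [ex.y for ex in test]
            n_pos = sum(labels)
            for arm in arms:
                for k in schedule.ks:
                    if k == 0:
                        scores = arm.zero_shot(test)
                        if scores is None:
                            rows.append(
                                dict(model=arm.name, tissue=tissue, k=0, seed=seed,
                                     auprc=None, auroc=None, n_test=len(test),
                                     n_pos_test=n_pos)
                            )
                            continue
                    else:
                        if k not in shot_sets:
                            continue
                        fitted = arm.fit_shots(
                            shot_sets[k].examples, _tissue_seed(seed, tissue, 2 + k)
                        )
                        scores = arm.score(fitted, test)
                    rows.append(
                        dict(model=arm.name, tissue=tissue, k=k, seed=seed,
                             auprc=auprc(labels, scores), auroc=auroc(labels, scores),
                             n_test=len(test), n_pos_test=n_pos)
                    )
    return metrics_table(rows)
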