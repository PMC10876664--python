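"""Concrete model arms for the k-shot experiment grid.

Every arm owns a *base state* (a warmed or freshly initialized model, or a
common-tissue-trained baseline) and re-fits a fresh copy of it on each shot
set, so grid cells are independent.  All arms share the identical shot sets
and test splits produced by :mod:`promptsyn.kshot`.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import baselines
from .data import LabeledExample
from .model import ClassifierModel, FineTuneConfig, fine_tune, zero_shot_scores


class LanguageModelArm:
    """Causal-LM classifier arm.

    ``zero_shot_mode`` selects the k = 0 path: ``generative`` scores the
    " Positive" / " Not positive" continuations (the path for a backbone
    whose head was never trained), ``head`` applies the existing head (the
    path for a warmed classifier, whose head was fit on common tissues).
    """

    def __init__(
        self,
        name: str,
        base: ClassifierModel,
        tune: FineTuneConfig,
        zero_shot_mode: str = "generative",
    ):
        if zero_shot_mode not in ("generative", "head"):
            raise ValueError("zero_shot_mode must be 'generative' or 'head'")
        self.name = name
        self.base = base
        self.tune = tune
        self.zero_shot_mode = zero_shot_mode

    def fit_shots(self, shots: Sequence[LabeledExample], seed: int) -> ClassifierModel:
        model = self.base.clone()
        cfg = FineTuneConfig(
            learning_rate=self.tune.learning_rate,
            weight_decay=self.tune.weight_decay,
            epochs=self.tune.epochs,
            batch_size=self.tune.batch_size,
            seed=seed,
            strategy=self.tune.strategy,
        )
        return fine_tune(model, shots, cfg)

    def score(self, fitted: ClassifierModel, examples: Sequence[LabeledExample]) -> np.ndarray:
        from .textgen import prompt_for_record

        prompts = [prompt_for_record(ex.record) for ex in examples]
        return fitted.predict_proba(prompts, batch_size=32)

    def zero_shot(self, examples: Sequence[LabeledExample]) -> np.ndarray:
        if self.zero_shot_mode == "head":
            return self.score(self.base, examples)
        return zero_shot_scores(self.base, [ex.record for ex in examples])


class CFArm:
    """Collaborative-filtering arm; k-shot = warm-started gradient steps."""

    name = "cf"

    def __init__(self, base: baselines.CFModel, kshot_epochs: int = 50):
        self.base = base
        self.kshot_epochs = kshot_epochs

    def fit_shots(self, shots, seed: int) -> baselines.CFModel:
        return baselines.cf_kshot(self.base, shots, seed=seed, epochs=self.kshot_epochs)

    def score(self, fitted, examples) -> np.ndarray:
        return fitted.predict_proba([ex.record for ex in examples])

    def zero_shot(self, examples) -> np.ndarray:
        return self.base.predict_proba([ex.record for ex in examples])


class GBTArm:
    """Boosted-tree arm; k-shot = boosting continuation."""

    name = "xgb"

    def __init__(self, base: baselines.GBTModel, extra_rounds: int = 50):
        self.base = base
        self.extra_rounds = extra_rounds

    def fit_shots(self, shots, seed: int) -> baselines.GBTModel:
        return baselines.gbt_kshot(self.base, shots, extra_rounds=self.extra_rounds, seed=seed)

    def score(self, fitted, examples) -> np.ndarray:
        return fitted.predict_proba([ex.record for ex in examples])

    def zero_shot(self, examples) -> np.ndarray:
        return self.base.predict_proba([ex.record for ex in examples])


class TabArm:
    """Attention-baseline arm; k-shot = exactly one epoch on the shot set."""

    name = "tabtx"

    def __init__(self, base: baselines.TabModel):
        self.base = base

    def fit_shots(self, shots, seed: int) -> baselines.TabModel:
        return baselines.tab_kshot(self.base, shots, seed=seed)

    def score(self, fitted, examples) -> np.ndarray:
        return fitted.predict_proba([ex.record for ex in examples])

    def zero_shot(self, examples) -> np.ndarray:
        return self.base.predict_proba([ex.record for ex in examples])
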