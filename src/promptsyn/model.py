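"""Causal-LM classifier: last-token hidden state -> affine head -> 2 logits.

The prompt always ends with the ``Synergy:`` cue and batches are left-padded,
so the hidden state at the final position summarizes the whole prompt.  Two
fine-tuning strategies are supported: ``full`` updates backbone and head;
``head_only`` freezes the backbone bit-exactly and trains the affine probe
on cached last-token features.  Zero-shot labeling scores the two candidate
continuations (" Positive" / " Not positive") by their total continuation
log-likelihood under the generative head.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .autograd import AdamW, Tensor, constant, cross_entropy, no_grad, parameter
from .backbone import BackboneSpec, ByteTokenizer, TinyCausalLM
from .data import LabeledExample, SynergyRecord
from .textgen import NEGATIVE_ANSWER, POSITIVE_ANSWER, prompt_for_record

STRATEGIES = ("full", "head_only")


@dataclass(frozen=True)
class FineTuneConfig:
    """Optimization settings for (k-shot) fine-tuning.

    The defaults mirror the reference fine-tuning recipe for a pretrained
    GPT-2-small-scale backbone: AdamW, lr 5e-5, decoupled weight decay 0.01,
    4 epochs.  A from-scratch tiny backbone needs a larger learning rate;
    see the methods note.
    """

    learning_rate: float = 5e-5
    weight_decay: float = 0.01
    epochs: int = 4
    batch_size: int = 8
    seed: int = 0
    strategy: str = "full"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")


@dataclass(frozen=True)
class Prediction:
    """Probability of the positive synergy class plus the raw logit pair."""

    p_positive: float
    logits: tuple[float, float]


class ClassifierModel:
    """A causal-LM backbone with an affine classification head (H -> 2).

    The head bias is always zero-initialized; the weights default to zero
    (an untrained model then scores every input at exactly 0.5) but can be
    seeded-random (``head_init_std``) so that full-mode fine-tuning passes
    gradients into the backbone from the first step.  Class index 1 is
    "positive synergy".
    """

    def __init__(self, backbone: TinyCausalLM, mode: str = "full",
                 head_init_std: float = 0.0):
        self.backbone = backbone
        h = backbone.spec.hidden_size
        if head_init_std > 0:
            rng = np.random.default_rng([backbone.seed, 271])
            w = (head_init_std * rng.normal(size=(h, 2))).astype(backbone.dtype)
        else:
            w = np.zeros((h, 2), dtype=backbone.dtype)
        self.head_w = parameter(w)
        self.head_b = parameter(np.zeros(2, dtype=backbone.dtype))
        self.mode = mode

    def clone(self) -> "ClassifierModel":
        other = ClassifierModel(self.backbone.clone(), mode=self.mode)
        other.head_w = parameter(self.head_w.data.copy())
        other.head_b = parameter(self.head_b.data.copy())
        return other

    def head_parameters(self) -> list[Tensor]:
        return [self.head_w, self.head_b]

    # -- encoding ---------------------------------------------------------
    def encode_last_token(self, prompts: Sequence[str], batch_size: int = 8) -> np.ndarray:
        """Final-token hidden vectors, one H-vector per prompt."""
        if len(prompts) == 0:
            raise ValueError("prompts must be non-empty")
        out = []
        max_len = self.backbone.spec.max_context_length
        with no_grad():
            for start in range(0, len(prompts), batch_size):
                ids = ByteTokenizer.batch(list(prompts[start:start + batch_size]), max_len)
                hidden = self.backbone.hidden_states(ids)
                out.append(hidden.data[:, -1, :].copy())
        return np.concatenate(out, axis=0)

    def head_logits(self, features: np.ndarray) -> np.ndarray:
        return features @ self.head_w.data + self.head_b.data

    def predict_proba(self, prompts: Sequence[str], batch_size: int = 8) -> np.ndarray:
        logits = self.head_logits(self.encode_last_token(prompts, batch_size))
        return _softmax2(logits)[:, 1]


def _softmax2(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def encode_last_token(model: ClassifierModel, prompts: Sequence[str], batch_size: int = 8) -> np.ndarray:
    return model.encode_last_token(prompts, batch_size)


def predict(
    model: ClassifierModel,
    records: Sequence[SynergyRecord],
    batch_size: int = 8,
) -> list[Prediction]:
    """Head predictions for records (deterministic given fixed parameters)."""
    prompts = [prompt_for_record(r) for r in records]
    logits = model.head_logits(model.encode_last_token(prompts, batch_size))
    probs = _softmax2(logits)
    return [
        Prediction(float(p[1]), (float(l[0]), float(l[1])))
        for p, l in zip(probs, logits)
    ]


def fine_tune(
    model: ClassifierModel,
    examples: Sequence[LabeledExample],
    config: FineTuneConfig,
    epoch_callback: Callable[[int, float], None] | None = None,
) -> ClassifierModel:
    """Minibatch AdamW on the cross-entropy of head logits vs labels.

    ``head_only`` trains the affine head on cached last-token features and
    leaves the backbone bit-identical; ``full`` backpropagates through the
    transformer.  ``epoch_callback(epoch, mean_loss)`` fires after each
    epoch; per-epoch mean losses are kept on ``model.train_loss_history``.
    """
    if not examples:
        raise ValueError("examples must be non-empty")
    labels = np.array([ex.y for ex in examples], dtype=int)
    if labels.min() == labels.max():
        warnings.warn("fine-tuning on a single-class example set", stacklevel=2)
    prompts = [prompt_for_record(ex.record) for ex in examples]
    model.mode = config.strategy
    rng = np.random.default_rng(config.seed)

    if config.strategy == "head_only":
        features = model.encode_last_token(prompts, batch_size=max(config.batch_size, 32))
        params = model.head_parameters()
    else:
        features = None
        params = model.backbone.parameters() + model.head_parameters()
    optimizer = AdamW(params, lr=config.learning_rate, weight_decay=config.weight_decay)

    max_len = model.backbone.spec.max_context_length
    history: list[float] = []
    n = len(examples)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            if config.strategy == "head_only":
                feats = constant(features[batch])
            else:
                ids = ByteTokenizer.batch([prompts[i] for i in batch], max_len)
                feats = model.backbone.hidden_states(ids)[:, -1, :]
            logits = feats @ model.head_w + model.head_b
            loss = cross_entropy(logits, labels[batch])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data) * len(batch))
        mean_loss = float(np.sum(losses) / n)
        history.append(mean_loss)
        if epoch_callback is not None:
            epoch_callback(epoch, mean_loss)
    model.train_loss_history = history
    return model


def zero_shot_label(model: ClassifierModel, prompt: str) -> Prediction:
    """Generative zero-shot labeling without the classification head.

    Computes the backbone's total log-likelihood of the continuations
    " Positive" and " Not positive" appended to the prompt; ``p_positive``
    is the two-way softmax over the two continuation log-likelihoods.
    """
    ll_pos = _continuation_loglik(model.backbone, prompt, POSITIVE_ANSWER)
    ll_neg = _continuation_loglik(model.backbone, prompt, NEGATIVE_ANSWER)
    p = _softmax2(np.array([[ll_neg, ll_pos]]))[0, 1]
    return Prediction(float(p), (float(ll_neg), float(ll_pos)))


def zero_shot_scores(
    model: ClassifierModel, records: Sequence[SynergyRecord]
) -> np.ndarray:
    return np.array(
        [zero_shot_label(model, prompt_for_record(r)).p_positive for r in records]
    )


def _continuation_loglik(backbone: TinyCausalLM, prompt: str, continuation: str) -> float:
    tok = ByteTokenizer
    cont_ids = tok.encode(continuation)
    max_prompt = backbone.spec.max_context_length - len(cont_ids)
    prompt_ids = tok.encode(prompt)[-max_prompt:]
    ids = np.concatenate([prompt_ids, cont_ids])[None, :]
    with no_grad():
        hidden = backbone.hidden_states(ids)
        logits = backbone.lm_logits(hidden).data[0]
    z = logits - logits.max(axis=-1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    total = 0.0
    offset = len(prompt_ids)
    for t in range(len(cont_ids)):
        total += float(log_probs[offset + t - 1, cont_ids[t]])
    return total


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(model: ClassifierModel, directory) -> None:
    """Backbone weights, head weights and a JSON config in one directory."""
    directory = Path(directory)
    model.backbone.save(directory)
    np.savez(directory / "head.npz", w=model.head_w.data, b=model.head_b.data)
    meta = {
        "hidden_size": model.backbone.spec.hidden_size,
        "mode": model.mode,
        "seed": model.backbone.seed,
    }
    (directory / "classifier.json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(directory) -> ClassifierModel:
    directory = Path(directory)
    backbone = TinyCausalLM.load(directory)
    meta = json.loads((directory / "classifier.json").read_text())
    model = ClassifierModel(backbone, mode=meta["mode"])
    with np.load(directory / "head.npz") as arrays:
        model.head_w.data = arrays["w"]
        model.head_b.data = arrays["b"]
    return model


def tiny_classifier(seed: int = 0, **spec_kwargs) -> ClassifierModel:
    """Convenience constructor for the trainable tiny-backbone classifier."""
    return ClassifierModel(TinyCausalLM(BackboneSpec.tiny(**spec_kwargs), seed=seed))
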