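"""Decoder-only causal language-model backbone over raw bytes.

The backbone contract is: a prompt string is tokenized, batches are padded
on the *left* (so the last position of every row is the prompt's own final
token — the ``Synergy:`` cue), and the model exposes the final-layer hidden
state at every position plus tied-embedding language-model logits.

The reference configuration mirrors a GPT-2-small-shaped model (hidden size
768, 12 layers); the shipped trainable instance is a small random-initialized
transformer over a byte vocabulary, which exercises the full method — the
contribution is the training/evaluation protocol, not pretrained weights.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._transformer import apply_block, init_block
from .autograd import Tensor, embedding, layer_norm, parameter

PAD_ID = 256
VOCAB_SIZE = 257  # 256 raw bytes + PAD


class ByteTokenizer:
    """UTF-8 byte tokenizer: no vocabulary to fit, fully deterministic."""

    vocab_size = VOCAB_SIZE
    pad_id = PAD_ID

    @staticmethod
    def encode(text: str) -> np.ndarray:
        if not text:
            raise ValueError("cannot encode an empty prompt")
        return np.frombuffer(text.encode("utf-8"), dtype=np.uint8).astype(np.int64)

    @classmethod
    def batch(cls, prompts: list[str], max_len: int) -> np.ndarray:
        """Left-truncate to ``max_len`` (keeping the suffix) and left-pad."""
        encoded = [cls.encode(p)[-max_len:] for p in prompts]
        width = max(len(e) for e in encoded)
        ids = np.full((len(encoded), width), PAD_ID, dtype=np.int64)
        for row, e in enumerate(encoded):
            ids[row, width - len(e):] = e
        return ids


@dataclass(frozen=True)
class BackboneSpec:
    """Architecture of a decoder-only backbone; padding is always left."""

    identifier: str = "tiny-random"
    hidden_size: int = 768
    n_layers: int = 12
    n_heads: int = 12
    max_context_length: int = 1024
    vocab_size: int = VOCAB_SIZE
    pad_side: str = "left"

    def __post_init__(self) -> None:
        if self.hidden_size <= 0 or self.hidden_size % self.n_heads:
            raise ValueError("hidden_size must be positive and divisible by n_heads")
        if self.pad_side != "left":
            raise ValueError("the backbone contract requires left padding")

    @classmethod
    def tiny(
        cls,
        hidden_size: int = 32,
        n_layers: int = 2,
        n_heads: int = 2,
        max_context_length: int = 384,
    ) -> "BackboneSpec":
        """The test/simulation configuration: small enough to train on a CPU."""
        return cls(
            identifier="tiny-random",
            hidden_size=hidden_size,
            n_layers=n_layers,
            n_heads=n_heads,
            max_context_length=max_context_length,
        )


class TinyCausalLM:
    """A randomly initialized causal transformer with tied LM embeddings."""

    def __init__(self, spec: BackboneSpec, seed: int = 0, dtype=np.float32,
                 init_std: float = 0.02):
        self.spec = spec
        self.seed = seed
        self.dtype = dtype
        self.init_std = init_std
        self.tokenizer = ByteTokenizer()
        rng = np.random.default_rng(seed)
        h = spec.hidden_size
        self.params: dict[str, Tensor] = {
            "tok_emb": parameter((init_std * rng.normal(size=(spec.vocab_size, h))).astype(dtype)),
            "pos_emb": parameter((init_std * rng.normal(size=(spec.max_context_length, h))).astype(dtype)),
        }
        for layer in range(spec.n_layers):
            init_block(self.params, rng, f"l{layer}", h, 4 * h, dtype=dtype, init_std=init_std)
        self.params["lnf.g"] = parameter(np.ones(h, dtype=dtype))
        self.params["lnf.b"] = parameter(np.zeros(h, dtype=dtype))

    # -- parameters -------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def checksum(self) -> str:
        """SHA-256 over all parameter bytes, in sorted name order."""
        digest = hashlib.sha256()
        for name in sorted(self.params):
            digest.update(name.encode())
            digest.update(np.ascontiguousarray(self.params[name].data).tobytes())
        return digest.hexdigest()

    def clone(self) -> "TinyCausalLM":
        other = TinyCausalLM.__new__(TinyCausalLM)
        other.spec = self.spec
        other.seed = self.seed
        other.dtype = self.dtype
        other.init_std = self.init_std
        other.tokenizer = self.tokenizer
        other.params = {k: parameter(v.data.copy()) for k, v in self.params.items()}
        return other

    # -- forward ----------------------------------------------------------
    def _attn_mask(self, ids: np.ndarray) -> np.ndarray:
        b, length = ids.shape
        causal = np.tril(np.ones((length, length), dtype=bool))
        key_ok = ids != PAD_ID  # (B, L) keys that are real tokens
        allowed = causal[None, :, :] & key_ok[:, None, :]
        return allowed[:, None, :, :]

    def hidden_states(self, ids: np.ndarray) -> Tensor:
        """Final-layer hidden state at every position, shape (B, L, H).

        Positions are counted per row from the first *real* token, so a
        left-padded prompt gets exactly the hidden states it would get when
        encoded alone.
        """
        real = ids != PAD_ID
        pos = np.maximum(np.cumsum(real, axis=1) - 1, 0)
        x = embedding(self.params["tok_emb"], ids) + embedding(self.params["pos_emb"], pos)
        mask = self._attn_mask(ids)
        for layer in range(self.spec.n_layers):
            x = apply_block(x, self.params, f"l{layer}", self.spec.n_heads, attn_mask=mask)
        return layer_norm(x, self.params["lnf.g"], self.params["lnf.b"])

    def lm_logits(self, hidden: Tensor) -> Tensor:
        """Next-token logits via the tied token-embedding matrix."""
        return hidden @ self.params["tok_emb"].T

    # -- persistence ------------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "backbone.npz", **{k: v.data for k, v in self.params.items()})
        meta = {"spec": asdict(self.spec), "seed": self.seed,
                "dtype": np.dtype(self.dtype).name, "init_std": self.init_std}
        (directory / "backbone.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "TinyCausalLM":
        directory = Path(directory)
        meta = json.loads((directory / "backbone.json").read_text())
        model = cls(BackboneSpec(**meta["spec"]), seed=meta["seed"],
                    dtype=np.dtype(meta["dtype"]), init_std=meta.get("init_std", 0.02))
        with np.load(directory / "backbone.npz") as arrays:
            for name in model.params:
                model.params[name].data = arrays[name]
        return model
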