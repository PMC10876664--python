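"""Shared pre-LN transformer block used by the causal backbone and the
tabular attention baseline.  Parameters live in a flat ``dict[str, Tensor]``
keyed by a per-block prefix, which keeps checkpointing and checksumming
trivial."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, gelu, layer_norm, masked_softmax, parameter


def init_block(
    params: dict[str, Tensor],
    rng: np.random.Generator,
    prefix: str,
    hidden: int,
    ff_hidden: int,
    dtype=np.float32,
    init_std: float = 0.02,
) -> None:
    def w(shape):
        return parameter((init_std * rng.normal(size=shape)).astype(dtype))

    def zeros(shape):
        return parameter(np.zeros(shape, dtype=dtype))

    def ones(shape):
        return parameter(np.ones(shape, dtype=dtype))

    params[f"{prefix}.ln1.g"] = ones(hidden)
    params[f"{prefix}.ln1.b"] = zeros(hidden)
    for name in ("wq", "wk", "wv", "wo"):
        params[f"{prefix}.{name}"] = w((hidden, hidden))
        params[f"{prefix}.{name[1]}b"] = zeros(hidden)
    params[f"{prefix}.ln2.g"] = ones(hidden)
    params[f"{prefix}.ln2.b"] = zeros(hidden)
    params[f"{prefix}.w1"] = w((hidden, ff_hidden))
    params[f"{prefix}.b1"] = zeros(ff_hidden)
    params[f"{prefix}.w2"] = w((ff_hidden, hidden))
    params[f"{prefix}.b2"] = zeros(hidden)


def _heads(t: Tensor, n_heads: int) -> Tensor:
    b, length, hidden = t.shape
    return t.reshape(b, length, n_heads, hidden // n_heads).transpose((0, 2, 1, 3))


def apply_block(
    x: Tensor,
    params: dict[str, Tensor],
    prefix: str,
    n_heads: int,
    attn_mask: np.ndarray | None = None,
) -> Tensor:
    """One pre-LN block: multi-head self-attention + GELU MLP, residual both.

    ``attn_mask`` is a boolean array broadcastable to (B, heads, L, L);
    False entries (future positions, padding keys) receive zero attention.
    """
    b, length, hidden = x.shape
    head_dim = hidden // n_heads

    h = layer_norm(x, params[f"{prefix}.ln1.g"], params[f"{prefix}.ln1.b"])
    q = _heads(h @ params[f"{prefix}.wq"] + params[f"{prefix}.qb"], n_heads)
    k = _heads(h @ params[f"{prefix}.wk"] + params[f"{prefix}.kb"], n_heads)
    v = _heads(h @ params[f"{prefix}.wv"] + params[f"{prefix}.vb"], n_heads)
    attn = masked_softmax(q @ k.transpose((0, 1, 3, 2)), attn_mask, 1.0 / np.sqrt(head_dim)) @ v
    attn = attn.transpose((0, 2, 1, 3)).reshape(b, length, hidden)
    x = x + attn @ params[f"{prefix}.wo"] + params[f"{prefix}.ob"]

    h = layer_norm(x, params[f"{prefix}.ln2.g"], params[f"{prefix}.ln2.b"])
    return x + gelu(h @ params[f"{prefix}.w1"] + params[f"{prefix}.b1"]) @ params[f"{prefix}.w2"] + params[f"{prefix}.b2"]
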