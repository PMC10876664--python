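"""Data-driven comparator models: logistic matrix factorization (CF),
gradient-boosted trees, and a TabTransformer-style attention classifier.

All three consume exactly (drug1, drug2, cell line, ri1, ri2).  The tissue
name is deliberately absent from every feature set: the models are evaluated
on tissues unseen in training, where a tissue indicator carries no signal.

* CF: p = sigmoid(<u_d1 + u_d2, v_c> + b_d1 + b_d2 + b_c + b_0).  Additive
  drug embeddings make the prediction exactly symmetric under swapping the
  pair.  Unseen drugs/cells at predict time fall back to the mean embedding
  (and mean bias) of their entity type.
* GBT: one-hot drug1 | one-hot drug2 | one-hot cell | ri1 | ri2, boosted
  trees with the reference configuration (eta 0.3, 1000 rounds, depth 20);
  k-shot adaptation continues boosting on the shot set.
* Tab: per-entity embeddings contextualized by a stack of multi-head
  self-attention layers, concatenated with the standardized sensitivities
  (statistics frozen from the common-tissue fit), then a feed-forward
  classifier; k-shot adaptation runs exactly 1 epoch with the same lr/decay.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import xgboost as xgb

from ._transformer import apply_block, init_block
from .autograd import AdamW, Tensor, concat, constant, cross_entropy, embedding, no_grad, parameter, relu
from .data import LabeledExample, SynergyRecord
from .metrics import auprc, auroc

logger = logging.getLogger(__name__)

#: Record fields the baselines may consume.  "tissue" is intentionally absent.
FEATURE_FIELDS = ("drug1", "drug2", "cell_line", "ri1", "ri2")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _check_two_classes(examples: Sequence[LabeledExample]) -> np.ndarray:
    y = np.array([ex.y for ex in examples], dtype=float)
    if y.size == 0 or y.min() == y.max():
        raise ValueError("fitting requires both classes to be present")
    return y


# ---------------------------------------------------------------------------
# Collaborative filtering
# ---------------------------------------------------------------------------

@dataclass
class CFModel:
    """Logistic matrix-factorization state."""

    drug_index: dict[str, int]
    cell_index: dict[str, int]
    U: np.ndarray            # (n_drugs, d)
    V: np.ndarray            # (n_cells, d)
    b_drug: np.ndarray
    b_cell: np.ndarray
    b0: float
    d: int = 32

    def _drug_rows(self, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        mean_u, mean_b = self.U.mean(axis=0), self.b_drug.mean()
        rows = np.empty((len(names), self.d))
        biases = np.empty(len(names))
        for i, name in enumerate(names):
            j = self.drug_index.get(name)
            rows[i] = self.U[j] if j is not None else mean_u
            biases[i] = self.b_drug[j] if j is not None else mean_b
        return rows, biases

    def _cell_rows(self, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        mean_v, mean_b = self.V.mean(axis=0), self.b_cell.mean()
        rows = np.empty((len(names), self.d))
        biases = np.empty(len(names))
        for i, name in enumerate(names):
            j = self.cell_index.get(name)
            rows[i] = self.V[j] if j is not None else mean_v
            biases[i] = self.b_cell[j] if j is not None else mean_b
        return rows, biases

    def predict_proba(self, records: Sequence[SynergyRecord]) -> np.ndarray:
        u1, bd1 = self._drug_rows([r.drug1 for r in records])
        u2, bd2 = self._drug_rows([r.drug2 for r in records])
        v, bc = self._cell_rows([r.cell_line for r in records])
        # drug terms are combined first so the swap symmetry is bit-exact
        z = np.einsum("nd,nd->n", u1 + u2, v) + (bd1 + bd2) + bc + self.b0
        return _sigmoid(z)


def fit_cf(
    examples: Sequence[LabeledExample],
    d: int = 32,
    seed: int = 0,
    epochs: int = 300,
    lr: float = 0.05,
    l2: float = 1e-4,
    model: CFModel | None = None,
) -> CFModel:
    """Fit (or warm-start) the logistic MF by full-batch Adam on cross-entropy."""
    y = _check_two_classes(examples)
    rng = np.random.default_rng(seed)
    if model is None:
        drugs = sorted({r for ex in examples for r in (ex.record.drug1, ex.record.drug2)})
        cells = sorted({ex.record.cell_line for ex in examples})
        if len(drugs) < 2 or len(cells) < 2:
            raise ValueError("need at least 2 distinct drugs and 2 distinct cell lines")
        model = CFModel(
            drug_index={n: i for i, n in enumerate(drugs)},
            cell_index={n: i for i, n in enumerate(cells)},
            U=0.1 * rng.normal(size=(len(drugs), d)),
            V=0.1 * rng.normal(size=(len(cells), d)),
            b_drug=np.zeros(len(drugs)),
            b_cell=np.zeros(len(cells)),
            b0=0.0,
            d=d,
        )
    else:
        model = copy.deepcopy(model)
        _extend_cf(model, examples, rng)

    i1 = np.array([model.drug_index[ex.record.drug1] for ex in examples])
    i2 = np.array([model.drug_index[ex.record.drug2] for ex in examples])
    ic = np.array([model.cell_index[ex.record.cell_line] for ex in examples])
    n = len(examples)

    params = [model.U, model.V, model.b_drug, model.b_cell, np.array([model.b0])]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    b1, b2, eps = 0.9, 0.999, 1e-8
    for t in range(1, epochs + 1):
        z = (
            np.einsum("nd,nd->n", model.U[i1] + model.U[i2], model.V[ic])
            + model.b_drug[i1] + model.b_drug[i2] + model.b_cell[ic] + params[4][0]
        )
        g = (_sigmoid(z) - y) / n
        gU = np.zeros_like(model.U)
        np.add.at(gU, i1, g[:, None] * model.V[ic])
        np.add.at(gU, i2, g[:, None] * model.V[ic])
        gV = np.zeros_like(model.V)
        np.add.at(gV, ic, g[:, None] * (model.U[i1] + model.U[i2]))
        gbd = np.zeros_like(model.b_drug)
        np.add.at(gbd, i1, g)
        np.add.at(gbd, i2, g)
        gbc = np.zeros_like(model.b_cell)
        np.add.at(gbc, ic, g)
        grads = [gU + l2 * model.U, gV + l2 * model.V, gbd, gbc, np.array([g.sum()])]
        for p, mm, vv, gg in zip(params, m, v, grads):
            mm *= b1
            mm += (1 - b1) * gg
            vv *= b2
            vv += (1 - b2) * gg * gg
            p -= lr * (mm / (1 - b1**t)) / (np.sqrt(vv / (1 - b2**t)) + eps)
    model.b0 = float(params[4][0])
    return model


def _extend_cf(model: CFModel, examples: Sequence[LabeledExample], rng) -> None:
    """Add mean-initialized slots for entities unseen by the base model."""
    for ex in examples:
        for drug in (ex.record.drug1, ex.record.drug2):
            if drug not in model.drug_index:
                model.drug_index[drug] = len(model.drug_index)
                model.U = np.vstack([model.U, model.U.mean(axis=0)])
                model.b_drug = np.append(model.b_drug, model.b_drug.mean())
        cell = ex.record.cell_line
        if cell not in model.cell_index:
            model.cell_index[cell] = len(model.cell_index)
            model.V = np.vstack([model.V, model.V.mean(axis=0)])
            model.b_cell = np.append(model.b_cell, model.b_cell.mean())


def cf_kshot(
    model: CFModel,
    shots: Sequence[LabeledExample],
    seed: int = 0,
    epochs: int = 50,
    lr: float = 0.05,
) -> CFModel:
    """Warm-started gradient adaptation of a fitted CF model on a shot set."""
    return fit_cf(shots, d=model.d, seed=seed, epochs=epochs, lr=lr, model=model)


# ---------------------------------------------------------------------------
# Gradient-boosted trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GBTConfig:
    learning_rate: float = 0.3
    n_trees: int = 1000
    max_depth: int = 20

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.n_trees <= 0 or self.max_depth <= 0:
            raise ValueError("GBT config values must be positive")


@dataclass(frozen=True)
class FeatureSpace:
    """One-hot dictionary shared by common-tissue and shot data.

    Feature layout: [one-hot drug1 | one-hot drug2 | one-hot cell | ri1, ri2].
    Entities outside the dictionary map to an all-zero block.
    """

    drugs: tuple[str, ...]
    cells: tuple[str, ...]

    @classmethod
    def from_examples(cls, examples: Sequence[LabeledExample]) -> "FeatureSpace":
        drugs = sorted({r for ex in examples for r in (ex.record.drug1, ex.record.drug2)})
        cells = sorted({ex.record.cell_line for ex in examples})
        return cls(tuple(drugs), tuple(cells))

    @property
    def n_features(self) -> int:
        return 2 * len(self.drugs) + len(self.cells) + 2

    def transform(self, records: Sequence[SynergyRecord]) -> sp.csr_matrix:
        drug_idx = {n: i for i, n in enumerate(self.drugs)}
        cell_idx = {n: i for i, n in enumerate(self.cells)}
        nd, nc = len(self.drugs), len(self.cells)
        rows, cols, vals = [], [], []
        for i, r in enumerate(records):
            for offset, key, index in (
                (0, r.drug1, drug_idx),
                (nd, r.drug2, drug_idx),
                (2 * nd, r.cell_line, cell_idx),
            ):
                j = index.get(key)
                if j is not None:
                    rows.append(i)
                    cols.append(offset + j)
                    vals.append(1.0)
            rows.extend([i, i])
            cols.extend([2 * nd + nc, 2 * nd + nc + 1])
            vals.extend([r.ri1, r.ri2])
        return sp.csr_matrix((vals, (rows, cols)), shape=(len(records), self.n_features))


@dataclass
class GBTModel:
    booster: xgb.Booster
    feature_space: FeatureSpace
    config: GBTConfig

    def predict_proba(self, records: Sequence[SynergyRecord]) -> np.ndarray:
        dmat = xgb.DMatrix(self.feature_space.transform(records))
        return self.booster.predict(dmat)


def _xgb_params(config: GBTConfig, seed: int) -> dict:
    return {
        "eta": config.learning_rate,
        "max_depth": config.max_depth,
        "objective": "binary:logistic",
        "tree_method": "hist",
        "nthread": 1,
        "seed": seed,
        "verbosity": 0,
    }


def fit_gbt(
    examples: Sequence[LabeledExample],
    config: GBTConfig = GBTConfig(),
    seed: int = 0,
    feature_space: FeatureSpace | None = None,
) -> GBTModel:
    y = _check_two_classes(examples)
    space = feature_space or FeatureSpace.from_examples(examples)
    dtrain = xgb.DMatrix(space.transform([ex.record for ex in examples]), label=y)
    booster = xgb.train(_xgb_params(config, seed), dtrain, num_boost_round=config.n_trees)
    return GBTModel(booster, space, config)


def gbt_kshot(
    model: GBTModel,
    shots: Sequence[LabeledExample],
    extra_rounds: int = 50,
    seed: int = 0,
) -> GBTModel:
    """Boosting continuation on the shot set from the common-tissue model."""
    y = np.array([ex.y for ex in shots], dtype=float)
    dtrain = xgb.DMatrix(
        model.feature_space.transform([ex.record for ex in shots]), label=y
    )
    booster = xgb.train(
        _xgb_params(model.config, seed),
        dtrain,
        num_boost_round=extra_rounds,
        xgb_model=model.booster.copy(),
    )
    return GBTModel(booster, model.feature_space, model.config)


# ---------------------------------------------------------------------------
# TabTransformer-style attention model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TabConfig:
    embed_dim: int = 32
    n_layers: int = 6
    n_heads: int = 8
    ff_hidden: int = 64
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    epochs: int = 50
    batch_size: int = 64
    seed: int = 0


class TabModel:
    """Categorical embeddings + self-attention + feed-forward classifier."""

    def __init__(self, examples: Sequence[LabeledExample], config: TabConfig):
        self.config = config
        drugs = sorted({r for ex in examples for r in (ex.record.drug1, ex.record.drug2)})
        cells = sorted({ex.record.cell_line for ex in examples})
        self.drug_index = {n: i for i, n in enumerate(drugs)}
        self.cell_index = {n: i for i, n in enumerate(cells)}
        ri = np.array([[ex.record.ri1, ex.record.ri2] for ex in examples], dtype=np.float64)
        # standardization statistics frozen from the fitting data
        self.ri_mean = ri.mean(axis=0)
        self.ri_sd = np.maximum(ri.std(axis=0), 1e-8)

        rng = np.random.default_rng(config.seed)
        e, dtype = config.embed_dim, np.float64
        self.params: dict[str, Tensor] = {
            "drug_emb": parameter(0.1 * rng.normal(size=(len(drugs), e)).astype(dtype)),
            "cell_emb": parameter(0.1 * rng.normal(size=(len(cells), e)).astype(dtype)),
            "col_emb": parameter(0.1 * rng.normal(size=(3, e)).astype(dtype)),
        }
        for layer in range(config.n_layers):
            init_block(self.params, rng, f"t{layer}", e, config.ff_hidden, dtype=dtype)
        fan_in = 3 * e + 2
        self.params["ff_w1"] = parameter(
            (rng.normal(size=(fan_in, config.ff_hidden)) / np.sqrt(fan_in)).astype(dtype)
        )
        self.params["ff_b1"] = parameter(np.zeros(config.ff_hidden, dtype=dtype))
        self.params["ff_w2"] = parameter(
            (rng.normal(size=(config.ff_hidden, 2)) / np.sqrt(config.ff_hidden)).astype(dtype)
        )
        self.params["ff_b2"] = parameter(np.zeros(2, dtype=dtype))

    def clone(self) -> "TabModel":
        other = TabModel.__new__(TabModel)
        other.config = self.config
        other.drug_index = dict(self.drug_index)
        other.cell_index = dict(self.cell_index)
        other.ri_mean = self.ri_mean.copy()
        other.ri_sd = self.ri_sd.copy()
        other.params = {k: parameter(v.data.copy()) for k, v in self.params.items()}
        return other

    def checksum(self) -> str:
        import hashlib

        digest = hashlib.sha256()
        for name in sorted(self.params):
            digest.update(np.ascontiguousarray(self.params[name].data).tobytes())
        return digest.hexdigest()

    def ensure_entities(self, records: Sequence[SynergyRecord]) -> None:
        """Mean-initialize embedding slots for unseen drugs/cells (logged)."""
        for r in records:
            for drug in (r.drug1, r.drug2):
                if drug not in self.drug_index:
                    logger.info("new drug embedding slot for %s (mean init)", drug)
                    self.drug_index[drug] = len(self.drug_index)
                    mean = self.params["drug_emb"].data.mean(axis=0, keepdims=True)
                    self.params["drug_emb"] = parameter(
                        np.vstack([self.params["drug_emb"].data, mean])
                    )
            if r.cell_line not in self.cell_index:
                logger.info("new cell embedding slot for %s (mean init)", r.cell_line)
                self.cell_index[r.cell_line] = len(self.cell_index)
                mean = self.params["cell_emb"].data.mean(axis=0, keepdims=True)
                self.params["cell_emb"] = parameter(
                    np.vstack([self.params["cell_emb"].data, mean])
                )

    def _logits(self, records: Sequence[SynergyRecord]) -> Tensor:
        self.ensure_entities(records)
        i1 = np.array([self.drug_index[r.drug1] for r in records])
        i2 = np.array([self.drug_index[r.drug2] for r in records])
        ic = np.array([self.cell_index[r.cell_line] for r in records])
        ri = np.array([[r.ri1, r.ri2] for r in records], dtype=np.float64)
        ri = (ri - self.ri_mean) / self.ri_sd

        tokens = [
            embedding(self.params["drug_emb"], i1),
            embedding(self.params["drug_emb"], i2),
            embedding(self.params["cell_emb"], ic),
        ]
        n, e = len(records), self.config.embed_dim
        x = concat([t.reshape(n, 1, e) for t in tokens], axis=1)
        x = x + self.params["col_emb"].reshape(1, 3, e)
        for layer in range(self.config.n_layers):
            x = apply_block(x, self.params, f"t{layer}", self.config.n_heads)
        flat = concat([x.reshape(n, 3 * e), constant(ri)], axis=-1)
        h = relu(flat @ self.params["ff_w1"] + self.params["ff_b1"])
        return h @ self.params["ff_w2"] + self.params["ff_b2"]

    def predict_proba(self, records: Sequence[SynergyRecord]) -> np.ndarray:
        with no_grad():
            logits = self._logits(records).data
        z = logits - logits.max(axis=-1, keepdims=True)
        ez = np.exp(z)
        return (ez / ez.sum(axis=-1, keepdims=True))[:, 1]

    def _train_epochs(
        self, examples: Sequence[LabeledExample], epochs: int, rng: np.random.Generator
    ) -> None:
        y = np.array([ex.y for ex in examples], dtype=int)
        records = [ex.record for ex in examples]
        self.ensure_entities(records)
        optimizer = AdamW(
            list(self.params.values()),
            lr=self.config.learning_rate,
            weight_decay=self.config.weight_decay,
        )
        n = len(examples)
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.config.batch_size):
                batch = order[start:start + self.config.batch_size]
                loss = cross_entropy(self._logits([records[i] for i in batch]), y[batch])
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()


def fit_tab(
    examples_common: Sequence[LabeledExample],
    val: Sequence[LabeledExample],
    config: TabConfig = TabConfig(),
) -> tuple[TabModel, list[dict]]:
    """Train on common tissues, return the best-validation-AUPRC checkpoint."""
    _check_two_classes(examples_common)
    model = TabModel(examples_common, config)
    rng = np.random.default_rng(config.seed)
    val_records = [ex.record for ex in val]
    val_labels = [ex.y for ex in val]
    trace: list[dict] = []
    best_metric, best_state = -np.inf, None
    for epoch in range(config.epochs):
        model._train_epochs(examples_common, 1, rng)
        scores = model.predict_proba(val_records)
        row = {
            "epoch": epoch,
            "val_auprc": auprc(val_labels, scores),
            "val_auroc": auroc(val_labels, scores),
        }
        trace.append(row)
        if row["val_auprc"] > best_metric:
            best_metric = row["val_auprc"]
            best_state = {k: v.data.copy() for k, v in model.params.items()}
    for name, data in best_state.items():
        model.params[name].data = data
    return model, trace


def tab_kshot(model: TabModel, shots: Sequence[LabeledExample], seed: int = 0) -> TabModel:
    """Exactly one epoch on the shot set with the training lr/decay."""
    adapted = model.clone()
    adapted._train_epochs(shots, 1, np.random.default_rng(seed))
    return adapted
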