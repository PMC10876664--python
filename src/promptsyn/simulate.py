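"""Synthetic drug-pair synergy screens with a latent-factor mechanism.

The generator emits DrugComb-shaped tables so every pipeline stage — record
parsing, prompt serialization, model fitting, the k-shot protocol — runs
without any external download.  Each drug i carries a latent vector a_i and
each cell line c a latent vector b_c; the pre-clamp synergy score is

    s = scale * (alpha * interaction(a_i, a_j, b_c) + eps) + offset,
    eps ~ N(0, sigma^2),

clamped to the Loewe scale [-100, 75].  Three interaction mechanisms are
available:

* ``product``  — <a_i * a_j, b_c> (element-wise product): pair-specific
  synergy that an additive-embedding collaborative filter can only
  approximate (misspecified-but-correlated, the realistic regime).
* ``additive`` — <a_i + a_j, b_c>: exactly the functional form of the
  logistic matrix-factorization baseline (recoverable regime).
* ``ri_linear`` — synergy depends only on the two written sensitivities
  (ri1 + ri2), an easy planted rule for tree learners.

Cell latents cluster around a shared base direction; a per-tissue *shift
angle* rotates that tissue's cell latents in a fixed coordinate plane,
turning the tissue out-of-distribution relative to the others while leaving
its marginal score scale intact.  Angle 0 keeps the tissue in-distribution.

Single-drug sensitivities are bounded monotone transforms of <a_i, b_c>
mapped into [0, 100], matching relative-inhibition magnitudes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DEFAULT_COLUMNS, SynergyRecord

_MECHANISMS = ("product", "additive", "ri_linear")


@dataclass(frozen=True)
class TissueSpec:
    """Per-tissue simulation block: cell-line count, row count, OOD angle."""

    n_cells: int
    n_samples: int
    shift_deg: float = 0.0


def default_tissues() -> dict[str, TissueSpec]:
    """Common tissues with thousands of rows, rare tissues with tens-hundreds."""
    return {
        "lung": TissueSpec(6, 3000),
        "breast": TissueSpec(6, 3000),
        "bone": TissueSpec(3, 400),
        "liver": TissueSpec(2, 200),
        "pancreas": TissueSpec(1, 40),
    }


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic screen."""

    n_drugs: int = 20
    latent_dim: int = 4
    alpha: float = 1.0           # interaction strength
    sigma: float = 0.5           # score noise sd (pre-scale)
    scale: float = 20.0
    offset: float = 0.0
    clamp: tuple[float, float] = (-100.0, 75.0)
    threshold: float = 5.0
    cell_spread: float = 0.25    # sd of cell latents around the base direction
    ri_noise: float = 0.25
    mechanism: str = "product"
    tissues: dict[str, TissueSpec] = field(default_factory=default_tissues)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.clamp
        if not lo < self.threshold < hi:
            raise ValueError("clamp bounds must bracket the label threshold")
        if self.alpha < 0 or self.sigma < 0 or self.cell_spread < 0:
            raise ValueError("alpha, sigma and cell_spread must be nonnegative")
        if self.mechanism not in _MECHANISMS:
            raise ValueError(f"mechanism must be one of {_MECHANISMS}")
        if self.n_drugs < 2 or self.latent_dim < 1:
            raise ValueError("need at least 2 drugs and latent_dim >= 1")
        if not self.tissues:
            raise ValueError("at least one tissue required")
        for name, spec in self.tissues.items():
            if spec.n_cells < 1 or spec.n_samples < 1:
                raise ValueError(f"infeasible counts for tissue {name!r}")
            if spec.shift_deg != 0.0 and self.latent_dim < 2:
                raise ValueError("shift rotation needs latent_dim >= 2")


def with_tissues(config: SimConfig, tissues: dict[str, TissueSpec], **kw) -> SimConfig:
    """Copy of a config with a different tissue layout (and other overrides)."""
    return dataclasses.replace(config, tissues=tissues, **kw)


def _rotate(b: np.ndarray, degrees: float) -> np.ndarray:
    """Givens rotation of the (0, 1) coordinate plane."""
    if degrees == 0.0:
        return b
    theta = np.deg2rad(degrees)
    out = b.copy()
    out[..., 0] = np.cos(theta) * b[..., 0] - np.sin(theta) * b[..., 1]
    out[..., 1] = np.sin(theta) * b[..., 0] + np.cos(theta) * b[..., 1]
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class _World:
    """Latent state drawn once per config: drug and cell latents, names."""

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.config = config
        d = config.latent_dim
        self.drug_latents = rng.normal(size=(config.n_drugs, d))
        self.drug_names = [f"DRUG-{i + 1:03d}" for i in range(config.n_drugs)]
        base = np.ones(d) / np.sqrt(d)
        self.cell_latents: list[np.ndarray] = []
        self.cell_names: list[str] = []
        self.cells_by_tissue: dict[str, list[int]] = {}
        idx = 0
        for tissue, spec in config.tissues.items():
            members = []
            for _ in range(spec.n_cells):
                b = base + config.cell_spread * rng.normal(size=d)
                self.cell_latents.append(_rotate(b, spec.shift_deg))
                self.cell_names.append(f"CELL-{idx + 1:03d}")
                members.append(idx)
                idx += 1
            self.cells_by_tissue[tissue] = members
        self.cell_latents_arr = np.asarray(self.cell_latents)

    def draw_rows(
        self, tissue: str, n: int, rng: np.random.Generator
    ) -> dict[str, np.ndarray]:
        cfg = self.config
        cells = np.asarray(self.cells_by_tissue[tissue])
        i = rng.integers(cfg.n_drugs, size=n)
        j = (i + 1 + rng.integers(cfg.n_drugs - 1, size=n)) % cfg.n_drugs
        c = cells[rng.integers(len(cells), size=n)]
        a_i = self.drug_latents[i]
        a_j = self.drug_latents[j]
        b = self.cell_latents_arr[c]
        u1 = np.einsum("nd,nd->n", a_i, b)
        u2 = np.einsum("nd,nd->n", a_j, b)
        ri1 = 100.0 * _sigmoid(u1 + cfg.ri_noise * rng.normal(size=n))
        ri2 = 100.0 * _sigmoid(u2 + cfg.ri_noise * rng.normal(size=n))
        raw = pair_interaction(cfg.mechanism, a_i, a_j, b, ri1, ri2)
        eps = rng.normal(size=n)
        s = cfg.scale * (cfg.alpha * raw + cfg.sigma * eps) + cfg.offset
        loewe = np.clip(s, cfg.clamp[0], cfg.clamp[1])
        return {"i": i, "j": j, "c": c, "ri1": ri1, "ri2": ri2, "loewe": loewe}


def pair_interaction(
    mechanism: str,
    a_i: np.ndarray,
    a_j: np.ndarray,
    b: np.ndarray,
    ri1: np.ndarray,
    ri2: np.ndarray,
) -> np.ndarray:
    """Latent interaction term; symmetric under exchanging the drug pair."""
    if mechanism == "product":
        return np.einsum("nd,nd->n", a_i * a_j, b)
    if mechanism == "additive":
        return np.einsum("nd,nd->n", a_i + a_j, b)
    if mechanism == "ri_linear":
        return (ri1 + ri2) / 100.0 - 1.0
    raise ValueError(f"unknown mechanism {mechanism!r}")


def generate(config: SimConfig) -> list[SynergyRecord]:
    """Draw a full synthetic screen as typed records (seed-deterministic)."""
    rng = np.random.default_rng(config.seed)
    world = _World(config, rng)
    records: list[SynergyRecord] = []
    for tissue, spec in config.tissues.items():
        rows = world.draw_rows(tissue, spec.n_samples, rng)
        for k in range(spec.n_samples):
            ri1_text = f"{rows['ri1'][k]:.3f}"
            ri2_text = f"{rows['ri2'][k]:.3f}"
            records.append(
                SynergyRecord(
                    drug1=world.drug_names[rows["i"][k]],
                    drug2=world.drug_names[rows["j"][k]],
                    cell_line=world.cell_names[rows["c"][k]],
                    tissue=tissue,
                    ri1=float(ri1_text),
                    ri2=float(ri2_text),
                    loewe=float(rows["loewe"][k]),
                    ri1_text=ri1_text,
                    ri2_text=ri2_text,
                )
            )
    return records


def generate_frame(config: SimConfig) -> pd.DataFrame:
    """The same screen as a DataFrame with the canonical column names."""
    recs = generate(config)
    return pd.DataFrame(
        {
            DEFAULT_COLUMNS["drug1"]: [r.drug1 for r in recs],
            DEFAULT_COLUMNS["drug2"]: [r.drug2 for r in recs],
            DEFAULT_COLUMNS["cell_line"]: [r.cell_line for r in recs],
            DEFAULT_COLUMNS["tissue"]: [r.tissue for r in recs],
            DEFAULT_COLUMNS["ri1"]: [r.ri1_text for r in recs],
            DEFAULT_COLUMNS["ri2"]: [r.ri2_text for r in recs],
            DEFAULT_COLUMNS["loewe"]: [r.loewe for r in recs],
        }
    )


def planted_prevalence(config: SimConfig, n_draws: int = 100_000) -> float:
    """Monte-Carlo estimate of P(loewe > threshold) under the config.

    Draws rows from the same latent world (tissues weighted by their sample
    counts) with an independent stream, for calibrating test fixtures.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    world = _World(config, np.random.default_rng(config.seed))
    names = list(config.tissues)
    weights = np.array([config.tissues[t].n_samples for t in names], dtype=float)
    weights /= weights.sum()
    per_tissue = np.maximum((weights * n_draws).astype(int), 1)
    hits = 0
    total = 0
    for tissue, n in zip(names, per_tissue):
        rows = world.draw_rows(tissue, int(n), rng)
        hits += int(np.sum(rows["loewe"] > config.threshold))
        total += int(n)
    return hits / total
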