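"""Shared fixtures.

The heavy simulation studies (warm-up benefit, null calibration,
distribution shift, CF recovery) are computed once per session and shared
between the module tests and the acceptance tests that assert on them.
"""

from __future__ import annotations

import numpy as np
import pytest

from promptsyn import experiments
from promptsyn.data import LabeledExample, SynergyRecord

SEEDS = (0, 1, 2, 3, 4)


def make_record(
    drug1="DRUG-001",
    drug2="DRUG-002",
    cell_line="CELL-001",
    tissue="bone",
    ri1=0.568,
    ri2=28.871,
    loewe=10.0,
    **kw,
):
    return SynergyRecord(drug1, drug2, cell_line, tissue, ri1, ri2, loewe, **kw)


@pytest.fixture
def paper_record():
    """The worked serialization example from the prompt-template study."""
    return make_record(
        "AZD1775", "AZACITIDINE", "SF-295", "bone",
        0.568, 28.871, 46.82, ri1_text="0.568", ri2_text="28.871",
    )


def random_examples(n, prevalence=0.3, seed=0, tissue="bone") -> list[LabeledExample]:
    """Labeled examples with iid labels and distinct drug pairs."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        y = int(rng.random() < prevalence)
        rec = make_record(
            drug1=f"DRUG-{i % 37 + 1:03d}",
            drug2=f"DRUG-{(i * 11) % 37 + 2:03d}",
            cell_line=f"CELL-{i % 5 + 1:03d}",
            tissue=tissue,
            ri1=float(rng.uniform(0, 100)),
            ri2=float(rng.uniform(0, 100)),
            loewe=30.0 if y else -10.0,
        )
        out.append(LabeledExample(rec, y))
    return out


@pytest.fixture(scope="session")
def warmup_results():
    """Warm-up benefit study: test AUROC per k for warmed vs unwarmed arms."""
    return experiments.warmup_benefit(seeds=SEEDS, ks=(0, 8, 32))


@pytest.fixture(scope="session")
def null_results():
    return experiments.null_signal(seeds=SEEDS)


@pytest.fixture(scope="session")
def shift_results():
    return experiments.distribution_shift(seeds=SEEDS)


@pytest.fixture(scope="session")
def cf_recovery_results():
    return [experiments.cf_recovery(seed) for seed in SEEDS]
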