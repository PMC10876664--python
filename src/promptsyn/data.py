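"""Typed screening records, binary synergy labels, and tissue partitioning.

A drug-pair synergy screen row carries two drug names, the cell line and its
tissue of origin, the two single-drug sensitivities (relative inhibition),
and a Loewe synergy score.  The Loewe score quantifies the excess over the
response expected if the two drugs were the same compound; on the scale used
here it runs from -100 (antagonism) to 75 (strong synergy).  A pair is
called synergistic (label 1) when its Loewe score strictly exceeds a
threshold, 5 by default.

Tissues are split into *rare* (< 4000 screened rows) and *common* tissues;
the few-shot protocol trains on common tissues and adapts per rare tissue.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Default mapping from record field -> CSV column name (DrugComb-style export).
DEFAULT_COLUMNS: dict[str, str] = {
    "drug1": "drug_row",
    "drug2": "drug_col",
    "cell_line": "cell_line_name",
    "tissue": "tissue_name",
    "ri1": "ri_row",
    "ri2": "ri_col",
    "loewe": "synergy_loewe",
}

#: Default Loewe-score threshold for calling a pair synergistic.
DEFAULT_LOEWE_THRESHOLD: float = 5.0

#: Default sample-count threshold below which a tissue is "rare".
DEFAULT_RARE_THRESHOLD: int = 4000


@dataclass(frozen=True)
class SynergyRecord:
    """One drug-pair screening row.

    ``ri1_text`` / ``ri2_text`` preserve the source textual representation of
    the sensitivities when the record was read from a file, so that prompts
    render the numbers exactly as the screen reported them.
    """

    drug1: str
    drug2: str
    cell_line: str
    tissue: str
    ri1: float
    ri2: float
    loewe: float
    ri1_text: str | None = None
    ri2_text: str | None = None

    def __post_init__(self) -> None:
        for name in ("drug1", "drug2", "cell_line", "tissue"):
            value = getattr(self, name)
            if not isinstance(value, str) or not value:
                raise ValueError(f"{name} must be a non-empty string, got {value!r}")
        for name in ("ri1", "ri2", "loewe"):
            value = getattr(self, name)
            if not math.isfinite(float(value)):
                raise ValueError(f"{name} must be finite, got {value!r}")

    def swapped(self) -> "SynergyRecord":
        """The same row with the drug order (and sensitivities) exchanged."""
        return replace(
            self,
            drug1=self.drug2,
            drug2=self.drug1,
            ri1=self.ri2,
            ri2=self.ri1,
            ri1_text=self.ri2_text,
            ri2_text=self.ri1_text,
        )


@dataclass(frozen=True)
class LabeledExample:
    """A screening record plus its binary synergy class."""

    record: SynergyRecord
    y: int

    def __post_init__(self) -> None:
        if self.y not in (0, 1):
            raise ValueError(f"y must be 0 or 1, got {self.y!r}")


@dataclass(frozen=True)
class TissuePartition:
    """Disjoint rare/common tissue sets under a sample-count threshold."""

    rare: frozenset[str]
    common: frozenset[str]
    threshold: int = DEFAULT_RARE_THRESHOLD

    def __post_init__(self) -> None:
        if self.rare & self.common:
            raise ValueError("rare and common tissue sets overlap")


def binarize_loewe(score: float, threshold: float = DEFAULT_LOEWE_THRESHOLD) -> int:
    """Binary synergy class of a Loewe score: 1 iff ``score > threshold``.

    The comparison is strict, so a score exactly at the threshold is negative.
    """
    score = float(score)
    if not math.isfinite(score):
        raise ValueError(f"Loewe score must be finite, got {score!r}")
    return int(score > threshold)


def label_records(
    records: Sequence[SynergyRecord], threshold: float = DEFAULT_LOEWE_THRESHOLD
) -> list[LabeledExample]:
    """Label each record by the strict Loewe threshold rule, preserving order."""
    return [LabeledExample(r, binarize_loewe(r.loewe, threshold)) for r in records]


def partition_tissues(
    counts: Mapping[str, int], threshold: int = DEFAULT_RARE_THRESHOLD
) -> TissuePartition:
    """Split tissues into rare (< threshold rows) and common (>= threshold)."""
    if not counts:
        raise ValueError("counts must be non-empty")
    rare, common = set(), set()
    for tissue, n in counts.items():
        n = int(n)
        if n < 0:
            raise ValueError(f"negative sample count for tissue {tissue!r}: {n}")
        (rare if n < threshold else common).add(tissue)
    return TissuePartition(frozenset(rare), frozenset(common), threshold)


def _parse_finite(text: str) -> float | None:
    try:
        value = float(text)
    except (TypeError, ValueError):
        return None
    return value if math.isfinite(value) else None


def read_synergy_csv(
    path,
    column_map: Mapping[str, str] | None = None,
) -> list[SynergyRecord]:
    """Read a DrugComb-style CSV into records, dropping incomplete rows.

    A row is kept only if all seven mapped fields are present and the three
    numeric fields parse to finite reals; dropped rows are counted and logged.
    The source text of the two sensitivities is preserved verbatim in
    ``ri1_text`` / ``ri2_text``.
    """
    columns = dict(DEFAULT_COLUMNS)
    if column_map:
        columns.update(column_map)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns.values() if c not in frame.columns]
    if missing:
        raise KeyError(f"CSV {path} is missing mapped column(s): {missing}")

    records: list[SynergyRecord] = []
    n_dropped = 0
    for row in frame.itertuples(index=False):
        values = {field: getattr(row, col) for field, col in columns.items()}
        if any(values[f] == "" for f in ("drug1", "drug2", "cell_line", "tissue")):
            n_dropped += 1
            continue
        ri1 = _parse_finite(values["ri1"])
        ri2 = _parse_finite(values["ri2"])
        loewe = _parse_finite(values["loewe"])
        if ri1 is None or ri2 is None or loewe is None:
            n_dropped += 1
            continue
        records.append(
            SynergyRecord(
                drug1=values["drug1"],
                drug2=values["drug2"],
                cell_line=values["cell_line"],
                tissue=values["tissue"],
                ri1=ri1,
                ri2=ri2,
                loewe=loewe,
                ri1_text=values["ri1"],
                ri2_text=values["ri2"],
            )
        )
    if n_dropped:
        logger.warning("dropped %d incomplete/unparseable row(s) from %s", n_dropped, path)
    return records


def write_synergy_csv(records: Iterable[SynergyRecord], path) -> None:
    """Re-export records with the canonical column names.

    Sensitivities are written from their preserved source text when present,
    so a read -> write -> read cycle is bit-identical on the mapped fields.
    """
    rows = []
    for r in records:
        rows.append(
            {
                DEFAULT_COLUMNS["drug1"]: r.drug1,
                DEFAULT_COLUMNS["drug2"]: r.drug2,
                DEFAULT_COLUMNS["cell_line"]: r.cell_line,
                DEFAULT_COLUMNS["tissue"]: r.tissue,
                DEFAULT_COLUMNS["ri1"]: r.ri1_text if r.ri1_text is not None else repr(r.ri1),
                DEFAULT_COLUMNS["ri2"]: r.ri2_text if r.ri2_text is not None else repr(r.ri2),
                DEFAULT_COLUMNS["loewe"]: repr(r.loewe),
            }
        )
    pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS.values())).to_csv(path, index=False)


def tissue_counts(records: Iterable[SynergyRecord]) -> dict[str, int]:
    """Number of screening rows per tissue."""
    counts: dict[str, int] = {}
    for r in records:
        counts[r.tissue] = counts.get(r.tissue, 0) + 1
    return counts
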