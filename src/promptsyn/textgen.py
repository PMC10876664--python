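"""Serialization of screening records to natural-language prompts.

A tabular row is rendered as a fixed six-sentence textual enumeration of its
features ("Text Template") and wrapped in a task instruction that asks for a
one-word binary answer.  The prompt always ends with the literal cue
``Synergy:`` so that a causal language model's last token sits at the
decision point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

from .data import LabeledExample, SynergyRecord

TEMPLATE = (
    "The first drug is {drug1}. "
    "The second drug is {drug2}. "
    "The cell line is {cell_line}. "
    "Tissue is {tissue}. "
    "The first drug's sensitivity using relative inhibition is {ri1}. "
    "The second drug's sensitivity using relative inhibition is {ri2}."
)

PROMPT_INSTRUCTION = (
    "Decide in a single word if the synergy of the drug combination "
    "in the cell line is positive or not."
)
PROMPT_SUFFIX = "Synergy:"

#: Continuations scored in the generative zero-shot mode.
POSITIVE_ANSWER = " Positive"
NEGATIVE_ANSWER = " Not positive"


@dataclass(frozen=True)
class PromptedExample:
    """Serialized text plus full task prompt, optionally with the label."""

    serialized: str
    prompt: str
    label: int | None = None

    def __post_init__(self) -> None:
        if self.serialized not in self.prompt:
            raise ValueError("prompt must contain the serialized block")
        if not self.prompt.endswith(PROMPT_SUFFIX):
            raise ValueError(f"prompt must end with {PROMPT_SUFFIX!r}")


def _render_ri(value: float, text: str | None) -> str:
    # Prefer the source text to avoid float-repr drift; otherwise the
    # shortest decimal that round-trips.
    return text if text is not None else repr(float(value))


def serialize_record(record: SynergyRecord) -> str:
    """Render a record as the six-sentence feature enumeration.

    Names are inserted verbatim (no case change); sensitivities render from
    their preserved source text when available.
    """
    return TEMPLATE.format(
        drug1=record.drug1,
        drug2=record.drug2,
        cell_line=record.cell_line,
        tissue=record.tissue,
        ri1=_render_ri(record.ri1, record.ri1_text),
        ri2=_render_ri(record.ri2, record.ri2_text),
    )


def build_prompt(serialized: str) -> str:
    """Wrap a serialized block in the task instruction and answer cue.

    The serialized block already ends in a period, so the template's own
    trailing period before ``Synergy:`` is not duplicated.
    """
    if not serialized:
        raise ValueError("serialized block must be non-empty")
    return f"{PROMPT_INSTRUCTION} {serialized} {PROMPT_SUFFIX}"


def prompt_for_record(record: SynergyRecord) -> str:
    """Full prompt for one record."""
    return build_prompt(serialize_record(record))


def make_prompted(
    examples: Sequence[LabeledExample | SynergyRecord],
) -> list[PromptedExample]:
    """Build PromptedExamples from records or labeled examples."""
    out = []
    for ex in examples:
        if isinstance(ex, LabeledExample):
            record, label = ex.record, ex.y
        else:
            record, label = ex, None
        serialized = serialize_record(record)
        out.append(PromptedExample(serialized, build_prompt(serialized), label))
    return out


def write_jsonl(prompted: Iterable[PromptedExample], path) -> None:
    """Export prompts (and labels when present) as JSON lines for inspection."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in prompted:
            fh.write(json.dumps({"prompt": p.prompt, "label": p.label}) + "\n")
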