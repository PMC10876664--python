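"""Ranking metrics for imbalanced binary classification.

Both metrics are defined in brute-force-verifiable form:

* AUROC via the Mann-Whitney statistic — the probability that a random
  positive outscores a random negative, with half credit for ties.
* AUPRC as average precision — the sum over ranked positives of
  (recall step x precision at that rank), with tied scores processed as a
  single group using the precision after the whole group.

Average precision is used rather than trapezoidal interpolation of the PR
curve because interpolation is optimistically biased at low prevalence.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

METRICS_COLUMNS = ["model", "tissue", "k", "seed", "auprc", "auroc", "n_test", "n_pos_test"]


class UndefinedMetricError(ValueError):
    """Raised when a ranking metric is requested with a single-class label set."""


def _validate(labels: Sequence[int], scores: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError(f"labels and scores must be equal-length 1-D, got {y.shape} vs {s.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise UndefinedMetricError("both classes must be present")
    return y.astype(int), s


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """P(score_pos > score_neg) + 0.5 * P(tie) over all positive/negative pairs."""
    y, s = _validate(labels, scores)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = rankdata(s)  # average ranks implement the half-credit tie rule
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Average precision in descending-score order with tie-group handling.

    Tied scores form one group; the group contributes its recall increment
    times the precision evaluated after the entire group is admitted.
    """
    y, s = _validate(labels, scores)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    n_pos = int(y.sum())

    ap = 0.0
    seen = 0
    seen_pos = 0
    i = 0
    n = y.size
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        group_pos = int(y_sorted[i:j].sum())
        seen += j - i
        seen_pos += group_pos
        if group_pos:
            ap += (group_pos / n_pos) * (seen_pos / seen)
        i = j
    return float(ap)


def metrics_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Assemble and validate a tidy (model, tissue, k, seed) results table."""
    frame = pd.DataFrame(list(rows), columns=METRICS_COLUMNS)
    finite = frame.dropna(subset=["auprc", "auroc"])
    for col in ("auprc", "auroc"):
        bad = finite[(finite[col] < 0) | (finite[col] > 1)]
        if len(bad):
            raise ValueError(f"{col} outside [0, 1] in rows {bad.index.tolist()}")
    if len(finite):
        if (finite["n_pos_test"] < 1).any() or ((finite["n_test"] - finite["n_pos_test"]) < 1).any():
            raise ValueError("every evaluated test set must contain both classes")
    return frame


def tissue_summary(frame: pd.DataFrame) -> str:
    """Per-tissue Markdown summary of the mean metrics across seeds."""
    lines = []
    for tissue, sub in frame.groupby("tissue"):
        lines.append(f"### {tissue}\n")
        pivot = sub.groupby(["model", "k"])[["auprc", "auroc"]].mean().round(3)
        lines.append(pivot.to_markdown())
        lines.append("")
    return "\n".join(lines)
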