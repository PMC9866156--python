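"""Discrimination metrics for presence/absence scores: ROC-AUC and the
true skill statistic (TSS) maximized over thresholds.

AUC uses the Mann-Whitney formulation (ties count one half). TSS(t) =
sensitivity(t) + specificity(t) - 1 with "positive iff score >= t";
candidate thresholds are the distinct observed scores plus +inf, and ties
in the maximum break toward the smallest cutoff — the most inclusive
predicted range, the conservative choice for invasion early warning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["EvalResult", "roc_auc", "max_tss", "evaluate_scores", "summarize"]


@dataclass
class EvalResult:
    family: str
    replicate: int
    auc: float
    tss_max: float
    cutoff: float
    sensitivity: float
    specificity: float
    failed: bool = False
    message: str = ""


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def roc_auc(labels, scores) -> float:
    """Mann-Whitney AUC: P(score_presence > score_absence) + 0.5 P(tie)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    _check_two_classes(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def max_tss(labels, scores) -> tuple[float, float, float, float]:
    """Maximize TSS over thresholds; returns (tss, cutoff, sens, spec).

    Evaluated at every distinct observed score (prediction positive iff
    score >= t) plus +inf; ties toward the smallest maximizing threshold.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    _check_two_classes(labels)
    thresholds = np.append(np.unique(scores), np.inf)  # ascending, +inf = predict all absent
    n1 = labels.sum()
    n0 = labels.size - n1
    # at threshold t: positives are scores >= t
    order = np.argsort(scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = labels[order]
    # cumulative counts of labels among scores < t
    idx = np.searchsorted(s_sorted, thresholds, side="left")
    cum_pos = np.concatenate([[0], np.cumsum(y_sorted)])
    tp = n1 - cum_pos[idx]          # presences with score >= t
    fp = (labels.size - idx) - tp   # absences with score >= t
    sens = tp / n1
    spec = (n0 - fp) / n0
    tss = sens + spec - 1.0
    best = int(np.argmax(tss))  # argmax returns first (smallest t) on ties
    return float(tss[best]), float(thresholds[best]), float(sens[best]), float(spec[best])


def evaluate_scores(labels, scores, family: str = "", replicate: int = 0) -> EvalResult:
    """Bundle AUC and max-TSS for one holdout evaluation."""
    auc = roc_auc(labels, scores)
    tss, cutoff, sens, spec = max_tss(labels, scores)
    return EvalResult(family, replicate, auc, tss, cutoff, sens, spec)


def summarize(evals: list[EvalResult]) -> pd.DataFrame:
    """Per-family arithmetic mean AUC and TSS over (non-failed) replicates."""
    ok = [e for e in evals if not e.failed]
    n_failed = len(evals) - len(ok)
    if n_failed:
        import logging

        logging.getLogger(__name__).warning("summarize: excluded %d failed replicates", n_failed)
    df = pd.DataFrame(
        {"family": [e.family for e in ok], "auc": [e.auc for e in ok], "tss": [e.tss_max for e in ok]}
    )
    out = df.groupby("family", as_index=True)[["auc", "tss"]].mean()
    out["n_reps"] = df.groupby("family").size()
    return out
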