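"""Ensemble construction: top-k member selection, committee scoring on the
0-1000 suitability scale, TSS-based binarization, four-class mapping,
permutation variable importance and response curves.

The committee is the unweighted mean over all replicate models of the k
families with the highest mean (AUC + TSS)/2 (a TSS-weighted mean is
available behind a flag). Continuous member scores are averaged first and
rounding to the integer 0-1000 scale happens once, at ensemble output.
The binarization cutoff is the TSS-maximizing threshold recomputed from
the pooled holdout predictions of the ensemble itself, and that single
cutoff is reused for every scenario projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from .evaluate import EvalResult, max_tss, roc_auc, summarize
from .models import FittedModel, predict
from .prep import SampleMatrix

__all__ = [
    "EnsembleModel",
    "ClassificationScheme",
    "select_top_k",
    "build_ensemble",
    "ensemble_predict",
    "binarize",
    "classify4",
    "variable_importance",
    "response_curve",
    "suitable_range",
]


@dataclass
class ClassificationScheme:
    """Four suitability classes on the 0-1000 scale.

    The lower cutoff ``c`` is the data-derived max-TSS threshold; the 400
    and 600 boundaries are fixed. Classes: unsuitable [0, c), low [c, 400),
    moderate [400, 600), high [600, 1000].
    """

    cutoff: float
    bounds: tuple[float, float] = (400.0, 600.0)
    labels: tuple[str, ...] = ("unsuitable", "low", "moderate", "high")

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < self.bounds[0]:
            raise ValueError(
                f"cutoff {self.cutoff} must lie in (0, {self.bounds[0]}) for the "
                "four-class scheme to be well-formed"
            )
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError("class boundaries must be strictly increasing")


@dataclass
class EnsembleModel:
    members: list[FittedModel]
    rule: str = "mean"  # or "tss_weighted"
    weights: np.ndarray | None = None
    cutoff: float = 500.0
    scheme: ClassificationScheme | None = None
    families: list[str] = field(default_factory=list)
    auc: float = float("nan")
    tss: float = float("nan")

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member model")
        if not self.families:
            self.families = sorted({m.spec.family for m in self.members})

    @property
    def variables(self) -> list[str]:
        return self.members[0].variables

    def predict(self, features) -> np.ndarray:
        return ensemble_predict(self, features)


def select_top_k(summary: pd.DataFrame, k: int = 3) -> list[str]:
    """Rank families by mean (AUC + TSS)/2, descending; return the top k.

    Ties break by TSS, then by family name. ``summary`` is the per-family
    table from :func:`nichekit.evaluate.summarize` (index = family, columns
    auc, tss).
    """
    if k > len(summary):
        raise ValueError(f"k={k} exceeds {len(summary)} summarized families")
    df = summary.copy()
    df["score"] = (df["auc"] + df["tss"]) / 2.0
    order = sorted(df.index, key=lambda f: (-df.loc[f, "score"], -df.loc[f, "tss"], f))
    return list(order[:k])


def _member_scores(em: EnsembleModel, features) -> np.ndarray:
    return np.column_stack([predict(m, features) for m in em.members])


def ensemble_predict(em: EnsembleModel, features) -> np.ndarray:
    """Committee score on the integer 0-1000 scale."""
    scores = _member_scores(em, features)
    if em.rule == "tss_weighted" and em.weights is not None:
        w = np.asarray(em.weights, dtype=float)
        mean = scores @ (w / w.sum())
    else:
        mean = scores.mean(axis=1)
    return np.rint(mean * 1000.0)


def build_ensemble(
    models: list[FittedModel],
    evals: list[EvalResult],
    data: SampleMatrix,
    k: int = 3,
    split: float = 0.75,
    seed: int = 0,
    rule: str = "mean",
    bounds: tuple[float, float] = (400.0, 600.0),
) -> EnsembleModel:
    """Select the top-k families and derive the ensemble cutoff.

    Holdout folds are regenerated deterministically from ``seed`` (the same
    stratified-split stream used at fit time), each fold is scored by that
    fold's member models, and the pooled holdout predictions give the
    ensemble's AUC, max-TSS and the TSS-maximizing cutoff on the 0-1000
    scale.
    """
    summary = summarize(evals)
    top = select_top_k(summary, k)
    members = [m for m in models if m is not None and m.spec.family in top]
    if not members:
        raise ValueError("no member models for selected families")
    reps = max(m.fold_id for m in members) + 1
    weights = None
    if rule == "tss_weighted":
        tss_by = {(e.family, e.replicate): e.tss_max for e in evals if not e.failed}
        weights = np.array([tss_by.get((m.spec.family, m.fold_id), 0.0) for m in members])
    splitter = StratifiedShuffleSplit(n_splits=reps, train_size=split, random_state=seed)
    pooled_scores, pooled_labels = [], []
    for rep, (_, te) in enumerate(splitter.split(data.X, data.y)):
        fold_members = [m for m in members if m.fold_id == rep]
        if not fold_members:
            continue
        scores = np.column_stack(
            [predict(m, data.data.iloc[te]) for m in fold_members]
        ).mean(axis=1)
        pooled_scores.append(scores)
        pooled_labels.append(data.y[te])
    sc = np.concatenate(pooled_scores) * 1000.0
    lab = np.concatenate(pooled_labels)
    tss, cutoff, _, _ = max_tss(lab, sc)
    auc = roc_auc(lab, sc)
    cutoff = float(np.clip(cutoff, 1.0, bounds[0] - 1.0))
    em = EnsembleModel(
        members=members,
        rule=rule,
        weights=weights,
        cutoff=cutoff,
        families=top,
        auc=auc,
        tss=tss,
    )
    em.scheme = ClassificationScheme(cutoff=cutoff, bounds=bounds)
    return em


def binarize(p: np.ndarray, cutoff: float) -> np.ndarray:
    """1 where p >= cutoff, 0 below; NaN (nodata) preserved."""
    if not 0 < cutoff < 1000:
        raise ValueError("cutoff must be in (0, 1000)")
    p = np.asarray(p, dtype=float)
    out = np.where(p >= cutoff, 1.0, 0.0)
    out[~np.isfinite(p)] = np.nan
    return out


def classify4(p: np.ndarray, scheme: ClassificationScheme) -> np.ndarray:
    """Class codes 0-3 (unsuitable/low/moderate/high); NaN cells -> -1."""
    p = np.asarray(p, dtype=float)
    b1, b2 = scheme.bounds
    edges = [scheme.cutoff, b1, b2]
    out = np.digitize(np.nan_to_num(p, nan=-1.0), edges).astype(int)
    out[~np.isfinite(p)] = -1
    return out


def variable_importance(
    em: EnsembleModel,
    data: SampleMatrix | pd.DataFrame,
    n_perm: int = 3,
    seed: int = 0,
) -> pd.Series:
    """Permutation importance: 1 - Pearson r(original, permuted) per variable.

    Averaged over ``n_perm`` independent permutations; a negative
    correlation is clamped so importance never exceeds 1. A model with
    constant predictions gets importance 0 everywhere (with a warning).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    df = data.data if isinstance(data, SampleMatrix) else pd.DataFrame(data)
    base = ensemble_predict(em, df) / 1000.0
    out = pd.Series(0.0, index=em.variables)
    if np.std(base) == 0:
        warnings.warn("constant ensemble predictions; importance is 0 everywhere", stacklevel=2)
        return out
    rng = np.random.default_rng(seed)
    for var in em.variables:
        vals = []
        for _ in range(n_perm):
            perm = df.copy()
            perm[var] = rng.permutation(perm[var].to_numpy())
            pp = ensemble_predict(em, perm) / 1000.0
            if np.std(pp) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(base, pp)[0, 1])
            vals.append(1.0 - max(min(r, 1.0), -1.0))
        out[var] = float(np.mean(np.clip(vals, 0.0, 1.0)))
    return out


def response_curve(
    em: EnsembleModel,
    variable: str,
    grid: np.ndarray,
    background: SampleMatrix | pd.DataFrame,
) -> pd.DataFrame:
    """Evaluation-strip response: vary one variable, hold others at the
    background mean; returns columns (value, suitability) with suitability
    on the 0-1 scale."""
    if variable not in em.variables:
        raise ValueError(f"unknown variable {variable!r}")
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    df = background.data if isinstance(background, SampleMatrix) else pd.DataFrame(background)
    means = df[em.variables].mean()
    strip = pd.DataFrame({v: np.full(grid.size, means[v]) for v in em.variables})
    strip[variable] = grid
    p = ensemble_predict(em, strip) / 1000.0
    return pd.DataFrame({"value": grid, "suitability": p})


def suitable_range(curve: pd.DataFrame, level: float = 0.6) -> list[tuple[float, float]]:
    """Maximal grid intervals where the response curve is >= ``level``."""
    vals = curve["value"].to_numpy()
    suit = curve["suitability"].to_numpy() >= level
    ranges: list[tuple[float, float]] = []
    start = None
    for i, ok in enumerate(suit):
        if ok and start is None:
            start = vals[i]
        if not ok and start is not None:
            ranges.append((start, vals[i - 1]))
            start = None
    if start is not None:
        ranges.append((start, vals[-1]))
    return ranges
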