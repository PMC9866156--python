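"""The eight single SDM families behind one fit/predict contract.

Families: ANN (one-hidden-layer perceptron), CTA (classification tree),
FDA (discriminant analysis on a hinge-basis expansion), GBM (stagewise
boosted trees), GLM (binomial regression with linear + quadratic terms),
MAXENT (penalized presence-background logistic on linear + quadratic +
hinge features, the infinitely-weighted-logistic-regression form), RF
(bagged tree ensemble) and SRE (per-variable percentile envelope on
presences only).

Every family exposes ``fit(spec, train)`` -> :class:`FittedModel` whose
``predict`` returns scores in [0, 1]. Defaults are fixed and documented;
the contract is the interface and its invariants, not bit-compatibility
with any other toolchain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .evaluate import EvalResult, evaluate_scores
from .prep import SampleMatrix

logger = logging.getLogger(__name__)

FAMILIES = ("ANN", "CTA", "FDA", "GBM", "GLM", "MAXENT", "RF", "SRE")

__all__ = ["FAMILIES", "ModelSpec", "FittedModel", "fit", "predict", "run_replicates"]


@dataclass
class ModelSpec:
    family: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        fam = self.family.upper()
        if fam not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        self.family = fam


@dataclass
class FittedModel:
    spec: ModelSpec
    variables: list[str]
    state: dict
    fold_id: int = 0

    def predict(self, features) -> np.ndarray:
        return predict(self, features)


# -- feature expansions ------------------------------------------------------


def _quadratic(X: np.ndarray) -> np.ndarray:
    return np.hstack([X, X**2])


def _hinge_knots(X: np.ndarray, quantiles=(0.25, 0.5, 0.75)) -> np.ndarray:
    return np.quantile(X, quantiles, axis=0)  # (n_knots, n_vars)


def _hinge(X: np.ndarray, knots: np.ndarray) -> np.ndarray:
    feats = []
    for j in range(X.shape[1]):
        for k in knots[:, j]:
            feats.append(np.maximum(X[:, j] - k, 0.0))
            feats.append(np.maximum(k - X[:, j], 0.0))
    return np.column_stack(feats)


def _as_array(features, variables: list[str]) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [v for v in variables if v not in features.columns]
        if missing:
            raise ValueError(f"missing variables {missing}")
        return features[variables].to_numpy(dtype=float)
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(variables):
        raise ValueError(f"expected {len(variables)} columns, got {X.shape[1]}")
    return X


# -- fitting -----------------------------------------------------------------


def fit(spec: ModelSpec, train: SampleMatrix) -> FittedModel:
    """Fit one family replicate on a presence/pseudo-absence matrix."""
    X, y = train.X, train.y
    fam = spec.family
    hp = spec.hyperparams
    seed = spec.seed
    if fam not in ("SRE",) and (y.min() == y.max()):
        raise ValueError(f"{fam} requires both classes in the training data")
    state: dict = {}

    if fam == "SRE":
        pres = X[y == 1]
        if len(pres) < 5:
            raise ValueError("SRE needs at least 5 presences")
        lo_q = hp.get("lower", 0.025)
        hi_q = hp.get("upper", 0.975)
        state["lo"] = np.quantile(pres, lo_q, axis=0)
        state["hi"] = np.quantile(pres, hi_q, axis=0)

    elif fam == "GLM":
        scaler = StandardScaler().fit(X)
        clf = LogisticRegression(C=np.inf, max_iter=2000)
        clf.fit(_quadratic(scaler.transform(X)), y)
        state.update(scaler=scaler, clf=clf)

    elif fam == "CTA":
        clf = DecisionTreeClassifier(
            min_samples_leaf=hp.get("min_samples_leaf", 5), random_state=seed
        )
        clf.fit(X, y)
        state["clf"] = clf

    elif fam == "RF":
        clf = RandomForestClassifier(
            n_estimators=hp.get("n_trees", 500),
            min_samples_leaf=hp.get("min_samples_leaf", 1),
            random_state=seed,
            n_jobs=1,
        )
        clf.fit(X, y)
        state["clf"] = clf

    elif fam == "GBM":
        clf = GradientBoostingClassifier(
            n_estimators=hp.get("n_trees", 2500),
            max_depth=hp.get("depth", 3),
            learning_rate=hp.get("shrinkage", 0.01),
            validation_fraction=0.1,
            n_iter_no_change=hp.get("patience", 10),
            random_state=seed,
        )
        clf.fit(X, y)
        state["clf"] = clf

    elif fam == "ANN":
        from sklearn.exceptions import ConvergenceWarning

        scaler = StandardScaler().fit(X)
        Xs = scaler.transform(X)
        alphas = hp.get("alphas", (1e-3, 1e-1))
        best_alpha, best_score = alphas[0], -np.inf
        with warnings.catch_warnings():
            # a fixed iteration budget is the documented default; an
            # unconverged optimizer plateau is acceptable, not an error
            warnings.simplefilter("ignore", ConvergenceWarning)
            if len(alphas) > 1:
                cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
                for alpha in alphas:
                    scores = []
                    for tr, te in cv.split(Xs, y):
                        m = MLPClassifier(
                            hidden_layer_sizes=(hp.get("hidden", 5),),
                            alpha=alpha,
                            max_iter=hp.get("max_iter", 300),
                            random_state=seed,
                        )
                        m.fit(Xs[tr], y[tr])
                        scores.append(m.score(Xs[te], y[te]))
                    mean = float(np.mean(scores))
                    if mean > best_score:
                        best_alpha, best_score = alpha, mean
            clf = MLPClassifier(
                hidden_layer_sizes=(hp.get("hidden", 5),),
                alpha=best_alpha,
                max_iter=hp.get("max_iter", 300),
                random_state=seed,
            )
            clf.fit(Xs, y)
        state.update(scaler=scaler, clf=clf, alpha=best_alpha)

    elif fam == "FDA":
        knots = _hinge_knots(X)
        scaler = StandardScaler().fit(_hinge(X, knots))
        clf = LinearDiscriminantAnalysis()
        clf.fit(scaler.transform(_hinge(X, knots)), y)
        state.update(knots=knots, scaler=scaler, clf=clf)

    elif fam == "MAXENT":
        # presence-background logistic with heavy background weighting (IWLR)
        knots = _hinge_knots(X)
        feats = np.hstack([_quadratic(X), _hinge(X, knots)])
        scaler = StandardScaler().fit(feats)
        w = np.where(y == 1, 1.0, hp.get("background_weight", 100.0))
        clf = LogisticRegression(C=hp.get("C", 1.0), max_iter=2000)
        clf.fit(scaler.transform(feats), y, sample_weight=w)
        state.update(knots=knots, scaler=scaler, clf=clf)

    else:  # pragma: no cover
        raise AssertionError(fam)

    return FittedModel(spec=spec, variables=list(train.variables), state=state)


def predict(model: FittedModel, features) -> np.ndarray:
    """Continuous suitability scores in [0, 1]; SRE returns {0, 1} membership."""
    X = _as_array(features, model.variables)
    fam = model.spec.family
    st = model.state
    if fam == "SRE":
        inside = np.all((X >= st["lo"]) & (X <= st["hi"]), axis=1)
        return inside.astype(float)
    if fam == "GLM":
        Z = _quadratic(st["scaler"].transform(X))
    elif fam == "ANN":
        Z = st["scaler"].transform(X)
    elif fam == "FDA":
        Z = st["scaler"].transform(_hinge(X, st["knots"]))
    elif fam == "MAXENT":
        Z = st["scaler"].transform(np.hstack([_quadratic(X), _hinge(X, st["knots"])]))
    else:
        Z = X
    p = st["clf"].predict_proba(Z)[:, 1]
    return np.clip(p, 0.0, 1.0)


def run_replicates(
    families: list[str],
    data: SampleMatrix,
    split: float = 0.75,
    reps: int = 10,
    seed: int = 0,
) -> tuple[list[FittedModel], list[EvalResult]]:
    """The replicate design: stratified random splits x families.

    ``reps`` independent stratified train/test splits (training fraction
    ``split``); every family is fitted on each training fold and evaluated
    on its holdout, giving ``len(families) * reps`` fitted models. A family
    failing on a fold is recorded as a failed EvalResult, never silently
    dropped.
    """
    splitter = StratifiedShuffleSplit(
        n_splits=reps, train_size=split, random_state=seed
    )
    models: list[FittedModel] = []
    evals: list[EvalResult] = []
    for rep, (tr, te) in enumerate(splitter.split(data.X, data.y)):
        train = SampleMatrix(data.data.iloc[tr].reset_index(drop=True), data.y[tr], data.variables)
        test_X = data.data.iloc[te]
        test_y = data.y[te]
        for famname in families:
            spec = ModelSpec(family=famname, seed=(seed * 1000 + rep) % (2**31))
            try:
                m = fit(spec, train)
                m.fold_id = rep
                scores = predict(m, test_X)
                ev = evaluate_scores(test_y, scores, family=spec.family, replicate=rep)
            except Exception as exc:  # noqa: BLE001 - record, don't drop
                logger.warning("family %s replicate %d failed: %s", famname, rep, exc)
                ev = EvalResult(famname, rep, np.nan, np.nan, np.nan, np.nan, np.nan,
                                failed=True, message=str(exc))
                evals.append(ev)
                continue
            models.append(m)
            evals.append(ev)
    return models, evals
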