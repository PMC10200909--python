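"""Cancer-vs-control classification: per-feature base models, a stacked
combination model, a specificity-anchored decision cutoff, and held-out
evaluation.

For each feature family (GWM, CNA, EM) three algorithms are considered:
logistic regression, random forest and gradient-boosted trees. Hyperparameters
are chosen by stratified 10-fold cross-validation maximizing ROC AUC; feature
selection keeps tree-model features with importance >= 1e-4, and for logistic
regression picks the best of L1/L2/no penalty. The combination model is an
unpenalized logistic regression on the three base probability scores; by
default the stacker is trained on OUT-OF-FOLD base scores (each training
sample scored by a model that never saw it) to avoid optimistic leakage, with
a ``naive`` switch for in-sample stacking. The decision cutoff is the smallest
score threshold reaching the requested specificity (>= 0.90 or 0.95) on the
training cohort; the frozen cutoff is then applied unchanged to validation
data. Fragment length is extracted and tested but is not a base model by
default (no breast-vs-control length difference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectFromModel
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    cross_val_predict,
    cross_val_score,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .stats import auc as auc_of
from .stats import delong_ci

ALGORITHMS = ("lr", "rf", "xgb")
DEFAULT_FAMILIES = ("GWM", "CNA", "EM")
IMPORTANCE_THRESHOLD = 1e-4

DEFAULT_GRIDS = {
    "lr": {"clf__C": [0.1, 1.0, 10.0]},
    "rf": {"clf__n_estimators": [200], "clf__max_depth": [None, 5]},
    "xgb": {"clf__max_depth": [2, 3], "clf__learning_rate": [0.1, 0.3]},
}


def labels_to_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        return (y == "cancer").astype(int)
    return y.astype(int)


def make_estimator(algorithm: str, seed: int, penalty: str = "l2"):
    """Imputation (training-mean) + algorithm pipeline."""
    steps = [("impute", SimpleImputer(strategy="mean"))]
    if algorithm == "lr":
        steps.append(("scale", StandardScaler()))
        if penalty == "none":
            clf = LogisticRegression(C=np.inf, max_iter=5000)
        else:
            clf = LogisticRegression(
                l1_ratio=1 if penalty == "l1" else 0, solver="liblinear",
                max_iter=5000, random_state=seed,
            )
    elif algorithm == "rf":
        clf = RandomForestClassifier(
            n_estimators=200, random_state=seed, n_jobs=1
        )
    elif algorithm == "xgb":
        clf = XGBClassifier(
            n_estimators=100, max_depth=3, learning_rate=0.1,
            random_state=seed, n_jobs=1, eval_metric="logloss",
            tree_method="hist",
        )
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    steps.append(("clf", clf))
    return Pipeline(steps)


@dataclass
class BaseModel:
    """One tuned, fitted per-feature-family classifier."""

    family: str
    algorithm: str
    params: dict
    feature_names: list[str]
    pipeline: Pipeline
    cv_auc: float

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.pipeline.predict_proba(X[self.feature_names])[:, 1]


def _cv(seed: int, n_splits: int, y=None) -> StratifiedKFold:
    """Stratified shuffled folds; fold count is clamped so every fold sees
    both classes (small synthetic cohorts)."""
    if y is not None:
        n_splits = max(2, min(n_splits, int(np.bincount(y, minlength=2).min())))
    return StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)


def tune_base_model(
    X: pd.DataFrame, y, algorithm: str, seed: int = 0, cv: int = 10,
    grid: dict | None = None, family: str = "",
) -> BaseModel:
    """Grid-search one algorithm by stratified ``cv``-fold CV on ROC AUC,
    apply its feature-selection rule, and report the post-selection mean CV
    AUC of the refit model.

    LR: the penalty in {l1, l2, none} with the best CV AUC wins. RF/XGB:
    features with importance >= 1e-4 are kept and the model refit on them.
    """
    y = labels_to_binary(y)
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("need at least 2 samples per class")
    cv_splitter = _cv(seed, cv, y)
    grid = grid if grid is not None else DEFAULT_GRIDS[algorithm]

    if algorithm == "lr":
        best = None
        for penalty in ("l1", "l2", "none"):
            pipe = make_estimator("lr", seed, penalty=penalty)
            gs = GridSearchCV(pipe, grid, scoring="roc_auc", cv=cv_splitter, n_jobs=1)
            gs.fit(X, y)
            if best is None or gs.best_score_ > best[0]:
                best = (gs.best_score_, penalty, gs.best_params_)
        score, penalty, params = best
        pipe = make_estimator("lr", seed, penalty=penalty).set_params(**params)
        pipe.fit(X, y)
        return BaseModel(family, "lr", {**params, "penalty": penalty},
                         list(X.columns), pipe, float(score))

    pipe = make_estimator(algorithm, seed)
    gs = GridSearchCV(pipe, grid, scoring="roc_auc", cv=cv_splitter, n_jobs=1)
    gs.fit(X, y)
    fitted = gs.best_estimator_
    selector = SelectFromModel(
        fitted.named_steps["clf"], threshold=IMPORTANCE_THRESHOLD, prefit=True
    )
    keep = np.asarray(selector.get_support())
    if not keep.any():
        keep = np.ones(X.shape[1], dtype=bool)
    selected = list(X.columns[keep])
    refit = make_estimator(algorithm, seed).set_params(**gs.best_params_)
    score = cross_val_score(
        refit, X[selected], y, scoring="roc_auc", cv=cv_splitter, n_jobs=1
    ).mean()
    refit.fit(X[selected], y)
    return BaseModel(family, algorithm, dict(gs.best_params_), selected,
                     refit, float(score))


def select_base_model(
    X: pd.DataFrame, y, seed: int = 0, cv: int = 10,
    algorithms=ALGORITHMS, family: str = "",
) -> BaseModel:
    """Tune every candidate algorithm and keep the best mean CV AUC."""
    models = [
        tune_base_model(X, y, alg, seed=seed, cv=cv, family=family)
        for alg in algorithms
    ]
    return max(models, key=lambda m: m.cv_auc)


@dataclass
class StackedModel:
    """Three base models plus a logistic-regression combiner on their
    probability scores, with a frozen decision cutoff."""

    base_models: dict[str, BaseModel]
    combiner: LogisticRegression
    families: list[str]
    seed: int
    cutoff: float | None = None
    min_specificity: float | None = None
    meta: dict = field(default_factory=dict)

    def base_scores(self, features: dict[str, pd.DataFrame]) -> pd.DataFrame:
        cols = {}
        index = None
        for fam in self.families:
            X = features[fam]
            index = X.index if index is None else index
            cols[fam] = self.base_models[fam].predict_proba(X)
        return pd.DataFrame(cols, index=index)

    def predict_proba(self, features: dict[str, pd.DataFrame]) -> np.ndarray:
        S = self.base_scores(features)
        return self.combiner.predict_proba(S.to_numpy())[:, 1]

    def predict(self, features: dict[str, pd.DataFrame]) -> np.ndarray:
        if self.cutoff is None:
            raise ValueError("no cutoff set; call choose_cutoff first")
        return (self.predict_proba(features) >= self.cutoff).astype(int)


def fit_stacked(
    features: dict[str, pd.DataFrame],
    y,
    seed: int = 0,
    cv: int = 10,
    algorithms: dict[str, str] | str = "xgb",
    tune: bool = False,
    naive_stacking: bool = False,
) -> StackedModel:
    """Fit base models per feature family and a logistic combiner.

    By default the combiner is trained on out-of-fold base probabilities
    (``naive_stacking=True`` uses in-sample scores instead — optimistic, kept
    for comparison). ``algorithms`` maps family -> algorithm name, or one
    name for all; ``tune=True`` runs the full per-family algorithm search.
    """
    y = labels_to_binary(y)
    families = list(features)
    if isinstance(algorithms, str):
        algorithms = {fam: algorithms for fam in families}

    base_models: dict[str, BaseModel] = {}
    oof = np.empty((len(y), len(families)))
    cv_splitter = _cv(seed, cv, y)
    for j, fam in enumerate(families):
        X = features[fam]
        if tune:
            model = select_base_model(X, y, seed=seed, cv=cv, family=fam)
        else:
            pipe = make_estimator(algorithms[fam], seed)
            pipe.fit(X, y)
            model = BaseModel(fam, algorithms[fam], {}, list(X.columns), pipe,
                              float("nan"))
        base_models[fam] = model
        if naive_stacking:
            oof[:, j] = model.predict_proba(X)
        else:
            refit = make_estimator(model.algorithm, seed)
            if model.params:
                refit.set_params(**{k: v for k, v in model.params.items()
                                    if k.startswith("clf__")})
            oof[:, j] = cross_val_predict(
                refit, X[model.feature_names], y, cv=cv_splitter,
                method="predict_proba", n_jobs=1,
            )[:, 1]
        if np.ptp(oof[:, j]) == 0:
            warnings.warn(
                f"degenerate (constant) base scores for {fam}; the combiner "
                "will ignore this family", stacklevel=2,
            )
    if np.ptp(oof, axis=0).max() == 0:
        raise ValueError("degenerate (constant) base scores for every family")

    combiner = LogisticRegression(C=np.inf, max_iter=5000)
    combiner.fit(oof, y)
    return StackedModel(
        base_models=base_models, combiner=combiner, families=families,
        seed=seed, meta={"naive_stacking": naive_stacking, "cv": cv},
    )


def choose_cutoff(scores, labels, min_specificity: float = 0.90) -> float:
    """Smallest threshold with specificity >= ``min_specificity`` on the
    given (training) scores; a sample is called positive when its score is
    >= the cutoff. Since specificity is nondecreasing and sensitivity
    nonincreasing in the threshold, the smallest qualifying threshold also
    maximizes sensitivity."""
    scores = np.asarray(scores, float)
    y = labels_to_binary(labels)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    if np.ptp(scores) == 0:
        raise ValueError("all scores identical; specificity target unattainable")
    controls = scores[y == 0]
    candidates = np.unique(scores)
    candidates = np.append(candidates, np.nextafter(candidates[-1], np.inf))
    for c in candidates:
        specificity = np.mean(controls < c)
        if specificity >= min_specificity:
            return float(c)
    raise ValueError("unreachable")  # last candidate always has specificity 1


def confusion_at_cutoff(scores, labels, cutoff: float) -> dict:
    y = labels_to_binary(labels)
    pred = np.asarray(scores) >= cutoff
    tp = int((pred & (y == 1)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def evaluate(
    model: StackedModel,
    features: dict[str, pd.DataFrame],
    manifest: pd.DataFrame,
    strata: tuple[str, ...] = ("stage", "subtype"),
    allow_train_overlap: bool = False,
    train_sample_ids=None,
) -> dict:
    """Evaluation report: overall and per-stratum AUC with DeLong 95% CI,
    detection rate (fraction of a stratum's cancers at/above the frozen
    cutoff), and specificity from all controls.

    Per-stratum ROC compares the stratum's cancers against ALL controls.
    Strata with no samples are reported as missing; CIs on < 5 cancers are
    flagged unreliable. Evaluating on training samples raises unless
    ``allow_train_overlap`` (then a warning flag is set in the report).
    """
    manifest = manifest.set_index("sample_id", drop=False)
    ids = list(features[model.families[0]].index)
    manifest = manifest.loc[ids]
    overlap = bool(
        train_sample_ids is not None and set(ids) & set(train_sample_ids)
    )
    if overlap and not allow_train_overlap:
        raise ValueError("evaluation samples overlap the training cohort")

    scores = model.predict_proba(features)
    y = labels_to_binary(manifest["label"])
    base = model.base_scores(features)

    a, lo, hi = delong_ci(scores, y)
    report: dict = {
        "n_cancer": int(y.sum()),
        "n_control": int((1 - y).sum()),
        "auc": a, "auc_ci": [lo, hi],
        "cutoff": model.cutoff,
        "train_overlap_warning": overlap,
        "base_auc": {fam: auc_of(base[fam], y) for fam in model.families},
        "scores": dict(zip(ids, map(float, scores))),
    }
    if model.cutoff is not None:
        report.update(confusion_at_cutoff(scores, y, model.cutoff))

    control_mask = y == 0
    for stratum in strata:
        per = {}
        for value, grp in manifest[y == 1].groupby(stratum):
            if value == "NA":
                continue
            mask = control_mask | manifest["sample_id"].isin(grp["sample_id"]).to_numpy()
            ys, ss = y[mask], scores[mask]
            sa, slo, shi = delong_ci(ss, ys)
            entry = {
                "n": int(len(grp)),
                "auc": sa, "auc_ci": [slo, shi],
                "ci_unreliable": len(grp) < 5,
                "base_auc": {
                    fam: auc_of(base[fam][mask], ys) for fam in model.families
                },
            }
            if model.cutoff is not None:
                gs = scores[manifest["sample_id"].isin(grp["sample_id"]).to_numpy()]
                entry["detection_rate"] = float(np.mean(gs >= model.cutoff))
            per[str(value)] = entry
        report[f"by_{stratum}"] = per
    return report


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve as a (threshold, sensitivity, specificity) table."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels_to_binary(labels), scores)
    return pd.DataFrame(
        {"threshold": thr, "sensitivity": tpr, "specificity": 1 - fpr}
    )
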