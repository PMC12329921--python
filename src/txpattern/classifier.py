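"""Random-forest training and evaluation primitives.

Features are log2(TPM+1).  F1 is computed with the wild-type class as the
positive class by default (configurable).  All randomness flows through an
explicit integer seed; forests run single-threaded so results are bit-stable
across machines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split

POSITIVE_CLASS = "wildtype"
CLASSES = ("mutant", "wildtype")


class FoldError(ValueError):
    """Cross-validation is infeasible for the given class sizes."""


@dataclass(frozen=True)
class RFParams:
    """Forest hyperparameters.  The defaults favour robustness; tests and the
    acceptance harness shrink ``n_estimators`` for speed."""

    n_estimators: int = 1000
    max_features: "str | float" = "sqrt"
    max_depth: int | None = None
    min_samples_leaf: int = 1
    class_weight: str | None = None
    n_jobs: int = 1

    def build(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            class_weight=self.class_weight,
            n_jobs=self.n_jobs,
            random_state=seed,
        )

    def to_dict(self) -> dict:
        return {
            "n_estimators": self.n_estimators,
            "max_features": self.max_features,
            "max_depth": self.max_depth,
            "min_samples_leaf": self.min_samples_leaf,
            "class_weight": self.class_weight,
        }


@dataclass
class CVResult:
    fold_f1: list[float]
    mean_f1: float
    oof_predictions: pd.Series  # out-of-fold predicted class per sample
    y_true: pd.Series  # the labels the folds were built from
    importances: pd.Series  # mean Gini importance per feature over folds
    positive_class: str
    seed: int
    params: RFParams

    @property
    def sd_f1(self) -> float:
        return float(np.std(self.fold_f1, ddof=1)) if len(self.fold_f1) > 1 else 0.0


@dataclass
class FittedModel:
    forest: RandomForestClassifier
    feature_ids: pd.Index
    importances: pd.Series
    positive_class: str
    seed: int
    params: RFParams
    cv_f1: float | None = None  # final F1 reported from CV, not resubstitution

    def _check_features(self, X: pd.DataFrame) -> None:
        if not X.columns.equals(self.feature_ids):
            extra = X.columns.difference(self.feature_ids)
            missing = self.feature_ids.difference(X.columns)
            raise ValueError(
                f"feature mismatch: {len(missing)} missing (e.g. {list(missing[:3])}), "
                f"{len(extra)} unexpected (e.g. {list(extra[:3])})"
            )

    def predict(self, X: pd.DataFrame) -> pd.Series:
        self._check_features(X)
        return pd.Series(self.forest.predict(X.to_numpy()), index=X.index)

    def predict_proba_positive(self, X: pd.DataFrame) -> pd.Series:
        """Probability of the positive (wild-type by default) class."""
        self._check_features(X)
        idx = list(self.forest.classes_).index(self.positive_class)
        return pd.Series(self.forest.predict_proba(X.to_numpy())[:, idx], index=X.index)


def safe_f1(y_true, y_pred, positive_class: str = POSITIVE_CLASS) -> float:
    """F1 for the positive class; 0 (with a warning) on empty denominators."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if not (y_pred == positive_class).any() or not (y_true == positive_class).any():
        warnings.warn("F1 undefined (no positive predictions or truths); reporting 0")
        return 0.0
    return float(f1_score(y_true, y_pred, pos_label=positive_class))


def _validate(X: pd.DataFrame, y: pd.Series, k: int) -> pd.Series:
    y = y.reindex(X.index)
    if y.isna().any():
        raise ValueError("labels missing for some samples in X")
    counts = y.value_counts()
    if len(counts) < 2:
        raise FoldError("both classes must be present")
    if counts.min() < k:
        raise FoldError(
            f"minority class has {counts.min()} samples < k={k} folds; "
            "use a smaller k or balance classes"
        )
    return y


def run_cv(
    X: pd.DataFrame,
    y: pd.Series,
    k: int = 5,
    seed: int = 0,
    params: RFParams = RFParams(),
    positive_class: str = POSITIVE_CLASS,
) -> CVResult:
    """Stratified k-fold cross-validation; forest refit per fold.

    ``X``: log2(TPM+1) features restricted to labeled (mutant/wildtype)
    samples; ``y``: class label per sample.  Deterministic given ``seed``.
    """
    y = _validate(X, y, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    Xv = X.to_numpy()
    yv = y.to_numpy()
    fold_f1: list[float] = []
    oof = pd.Series(index=X.index, dtype=object)
    importance_sum = np.zeros(X.shape[1])
    for fold, (train, test) in enumerate(skf.split(Xv, yv)):
        forest = params.build(seed + fold)
        forest.fit(Xv[train], yv[train])
        pred = forest.predict(Xv[test])
        oof.iloc[test] = pred
        fold_f1.append(safe_f1(yv[test], pred, positive_class))
        importance_sum += forest.feature_importances_
    return CVResult(
        fold_f1=fold_f1,
        mean_f1=float(np.mean(fold_f1)),
        oof_predictions=oof,
        y_true=y,
        importances=pd.Series(importance_sum / k, index=X.columns),
        positive_class=positive_class,
        seed=seed,
        params=params,
    )


def holdout_check(
    X: pd.DataFrame,
    y: pd.Series,
    train_frac: float = 0.9,
    k: int = 5,
    seed: int = 0,
    params: RFParams = RFParams(),
    positive_class: str = POSITIVE_CLASS,
) -> tuple[float, float]:
    """90/10 stratified split overfit screen: (CV F1 on train, held-out F1)."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    y = _validate(X, y, k)
    train_idx, test_idx = train_test_split(
        np.arange(len(X)),
        train_size=train_frac,
        stratify=y.to_numpy(),
        random_state=seed,
    )
    X_train, X_test = X.iloc[train_idx], X.iloc[test_idx]
    y_train, y_test = y.iloc[train_idx], y.iloc[test_idx]
    cv = run_cv(X_train, y_train, k=k, seed=seed, params=params, positive_class=positive_class)
    forest = params.build(seed)
    forest.fit(X_train.to_numpy(), y_train.to_numpy())
    test_f1 = safe_f1(y_test.to_numpy(), forest.predict(X_test.to_numpy()), positive_class)
    return cv.mean_f1, test_f1


def per_type_f1(cvresult: CVResult, metadata: pd.DataFrame) -> pd.DataFrame:
    """Out-of-fold F1 per tumour type.

    Returns a DataFrame indexed by tumour type with columns ``f1`` (NaN when
    a type holds a single class — never reported as 0), ``ratio`` = minor /
    major class size, ``n_mutant``, ``n_wildtype``, ``n``.
    """
    oof = cvresult.oof_predictions
    truth = cvresult.y_true
    types = metadata.loc[oof.index, "tumour_type"]
    rows = []
    for t in sorted(types.unique()):
        members = types.index[types == t]
        y_t = truth.loc[members]
        n_mut = int((y_t == "mutant").sum())
        n_wt = int((y_t == "wildtype").sum())
        if n_mut == 0 or n_wt == 0:
            f1 = float("nan")
        else:
            f1 = safe_f1(y_t.to_numpy(), oof.loc[members].to_numpy(), cvresult.positive_class)
        ratio = min(n_mut, n_wt) / max(n_mut, n_wt) if max(n_mut, n_wt) else float("nan")
        rows.append(
            {
                "tumour_type": t,
                "f1": f1,
                "ratio": ratio,
                "n_mutant": n_mut,
                "n_wildtype": n_wt,
                "n": len(members),
            }
        )
    return pd.DataFrame(rows).set_index("tumour_type")


def fit_final(
    X: pd.DataFrame,
    y: pd.Series,
    seed: int = 0,
    params: RFParams = RFParams(),
    positive_class: str = POSITIVE_CLASS,
    k: int = 5,
    cv: CVResult | None = None,
) -> FittedModel:
    """Fit one forest on all labeled samples; final F1 comes from CV."""
    if cv is None:
        cv = run_cv(X, y, k=k, seed=seed, params=params, positive_class=positive_class)
    y = _validate(X, y, k=2)
    forest = params.build(seed)
    forest.fit(X.to_numpy(), y.to_numpy())
    return FittedModel(
        forest=forest,
        feature_ids=X.columns,
        importances=pd.Series(forest.feature_importances_, index=X.columns),
        positive_class=positive_class,
        seed=seed,
        params=params,
        cv_f1=cv.mean_f1,
    )


def grid_search(
    X: pd.DataFrame,
    y: pd.Series,
    grid: dict[str, list] | None = None,
    k: int = 5,
    seed: int = 0,
    base: RFParams = RFParams(),
    positive_class: str = POSITIVE_CLASS,
) -> tuple[RFParams, pd.DataFrame]:
    """Small hyperparameter sweep by mean CV F1 (the tuning helper)."""
    grid = grid or {"max_features": ["sqrt", 0.1], "min_samples_leaf": [1, 3]}
    keys = list(grid)
    rows = []
    best, best_f1 = base, -1.0
    from itertools import product

    for combo in product(*(grid[k_] for k_ in keys)):
        params = replace(base, **dict(zip(keys, combo)))
        f1 = run_cv(X, y, k=k, seed=seed, params=params, positive_class=positive_class).mean_f1
        rows.append({**dict(zip(keys, combo)), "mean_f1": f1})
        if f1 > best_f1:
            best, best_f1 = params, f1
    return best, pd.DataFrame(rows)
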