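"""Stacking-ensemble prediction of BRDF parameters from phenotypic traits.

One model per target parameter (σ, k or n).  Pipeline:

1. 8:2 train/test split (seeded).
2. z-score standardization fitted on the training split only.
3. Recursive feature elimination down to 5 of the 9 trait features, ranked
   by random-forest importance.
4. Per-base-learner hyperparameter grid search (SVR, random forest,
   gradient boosting) minimizing 10-fold cross-validated MSE on the
   training split.
5. A stacking ensemble whose linear-regression meta-learner is trained on
   out-of-fold base predictions (no leakage), evaluated on the held-out 20%.

Everything is deterministic given the split seed and learner seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.feature_selection import RFE
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.ensemble import StackingRegressor

from .traits import TRAIT_FEATURES

DEFAULT_GRIDS: dict[str, dict] = {
    "svr": {"C": [0.1, 1.0, 10.0], "epsilon": [0.01, 0.1], "gamma": ["scale"]},
    "rfr": {"n_estimators": [100, 300], "min_samples_leaf": [1, 3]},
    "gbrt": {"n_estimators": [200], "max_depth": [2, 3], "learning_rate": [0.05, 0.1]},
}


@dataclass
class EvalReport:
    mse: float
    r_squared: float
    split: tuple[int, int]
    cv_folds: int
    best_params: dict[str, dict] = field(default_factory=dict)
    base_test_mse: dict[str, float] = field(default_factory=dict)


@dataclass
class ELModel:
    target: str
    selected_features: list[str]
    scaler: StandardScaler
    stack: StackingRegressor
    feature_names: list[str]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xs = pd.DataFrame(
            self.scaler.transform(X[self.feature_names].to_numpy(float)),
            columns=self.feature_names,
        )
        return self.stack.predict(Xs[self.selected_features].to_numpy())


def standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, StandardScaler]:
    """z-score each column; returns the transformed frame and the fitted transform.

    Zero-variance columns cannot be standardized and are reported by name.
    """
    sds = X.std(ddof=0)
    bad = list(sds.index[sds <= 0])
    if bad:
        raise ValueError(f"zero-variance columns cannot be standardized: {bad}")
    scaler = StandardScaler().fit(X.to_numpy(float))
    Xs = pd.DataFrame(scaler.transform(X.to_numpy(float)), columns=X.columns, index=X.index)
    return Xs, scaler


def rfe_select(
    X: pd.DataFrame, y: np.ndarray, n_keep: int = 5, seed: int = 0, n_trees: int = 200
) -> list[str]:
    """Recursive feature elimination to ``n_keep`` features.

    The internal ranker is a seeded random forest; elimination drops the
    least important feature each round, so the result is deterministic for a
    fixed seed.
    """
    if n_keep >= X.shape[1]:
        raise ValueError(f"n_keep={n_keep} must be smaller than {X.shape[1]} features")
    est = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    rfe = RFE(est, n_features_to_select=n_keep, step=1).fit(X.to_numpy(), np.asarray(y))
    return [c for c, keep in zip(X.columns, rfe.support_) if keep]


def _base_learners(seed: int) -> dict[str, object]:
    return {
        "svr": SVR(),
        "rfr": RandomForestRegressor(random_state=seed),
        "gbrt": GradientBoostingRegressor(random_state=seed),
    }


def train_el(
    X: pd.DataFrame,
    y: np.ndarray,
    target: str = "sigma",
    split_seed: int = 42,
    learner_seed: int = 0,
    cv_folds: int = 10,
    grids: dict[str, dict] | None = None,
    n_keep: int = 5,
    features: tuple[str, ...] = TRAIT_FEATURES,
) -> tuple[ELModel, EvalReport]:
    """Train the stacking ensemble for one BRDF parameter and evaluate it.

    Test rows never touch the scaler, the feature selection, or the grid
    search.  Returns the fitted model and a held-out evaluation report.
    """
    feats = [f for f in features if f in X.columns]
    if len(feats) < n_keep + 1:
        raise ValueError("not enough trait features present")
    X = X[feats]
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 50:
        raise ValueError("need at least 50 samples")
    grids = grids or DEFAULT_GRIDS

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.2, random_state=split_seed
    )
    if len(y_tr) < cv_folds:
        raise ValueError("too few training samples for the requested folds")

    X_trs, scaler = standardize(X_tr)
    X_tes = pd.DataFrame(scaler.transform(X_te.to_numpy(float)), columns=feats)

    selected = rfe_select(X_trs, y_tr, n_keep=n_keep, seed=learner_seed)
    A_tr = X_trs[selected].to_numpy()
    A_te = X_tes[selected].to_numpy()

    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=split_seed)
    best: dict[str, object] = {}
    best_params: dict[str, dict] = {}
    for name, learner in _base_learners(learner_seed).items():
        gs = GridSearchCV(
            learner, grids[name], cv=cv, scoring="neg_mean_squared_error", n_jobs=1
        ).fit(A_tr, y_tr)
        best[name] = gs.best_estimator_
        best_params[name] = dict(gs.best_params_)

    stack = StackingRegressor(
        estimators=list(best.items()),
        final_estimator=LinearRegression(),
        cv=cv,
        n_jobs=1,
    ).fit(A_tr, y_tr)

    pred = stack.predict(A_te)
    base_mse = {
        name: float(mean_squared_error(y_te, est.fit(A_tr, y_tr).predict(A_te)))
        for name, est in best.items()
    }
    report = EvalReport(
        mse=float(mean_squared_error(y_te, pred)),
        r_squared=float(r2_score(y_te, pred)),
        split=(int(len(y_tr)), int(len(y_te))),
        cv_folds=cv_folds,
        best_params=best_params,
        base_test_mse=base_mse,
    )
    model = ELModel(
        target=target,
        selected_features=selected,
        scaler=scaler,
        stack=stack,
        feature_names=feats,
    )
    return model, report


def feature_importance(model: ELModel) -> pd.Series:
    """Normalized random-forest importances of the selected features, descending."""
    try:
        rfr = model.stack.named_estimators_["rfr"]
    except (AttributeError, KeyError) as exc:
        raise ValueError("model has no fitted random-forest base learner") from exc
    imp = np.asarray(rfr.feature_importances_, dtype=float)
    imp = imp / imp.sum()
    s = pd.Series(imp, index=model.selected_features)
    return s.sort_values(ascending=False)
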