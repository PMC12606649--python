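"""Feature attribution and feature-target correlation analysis.

Attributions are exact tree-path (TreeSHAP) values computed natively by
xgboost (``pred_contribs``); per-feature importance is the mean absolute
attribution over the rows scored. Local accuracy (attributions plus base
value equal the prediction) is enforced on every row. The cross-model
heatmap normalizes importances per model (each model's importances sum to
one) and orders features by their average across models.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "shap_importance",
    "shap_attributions",
    "cv_shap_importance",
    "importance_heatmap",
    "spearman_feature_rp",
]


def _get_booster(model):
    import xgboost
    if isinstance(model, xgboost.Booster):
        return model
    if hasattr(model, "get_booster"):
        return model.get_booster()
    raise TypeError(f"unsupported model type {type(model).__name__}: "
                    "attributions require a gradient-boosted tree model")


def shap_attributions(model, X, check_local_accuracy: bool = True,
                      tol: float = 1e-3) -> tuple:
    """Per-row additive attributions and base values.

    Returns (attributions (n, p), base_values (n,)). ``tol`` bounds the
    allowed |sum(attributions) + base - prediction| per row (mV); the check
    runs in the model's single-precision arithmetic, hence the default of
    1e-3 mV on targets of order 100 mV.
    """
    import xgboost
    booster = _get_booster(model)
    if isinstance(X, pd.DataFrame) and booster.feature_names is not None \
            and set(booster.feature_names) == set(X.columns):
        X = X[booster.feature_names]  # align to training column order
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    dm = xgboost.DMatrix(arr, feature_names=booster.feature_names)
    contrib = booster.predict(dm, pred_contribs=True).astype(float)
    attributions, base = contrib[:, :-1], contrib[:, -1]
    if check_local_accuracy:
        pred = booster.predict(dm).astype(float)
        gap = np.abs(attributions.sum(axis=1) + base - pred)
        if gap.max() > tol:
            raise AssertionError(
                f"local accuracy violated: max |sum(attr)+base-pred| = {gap.max():.3g} mV")
    return attributions, base


def shap_importance(model, X, check_local_accuracy: bool = True,
                    tol: float = 1e-3) -> pd.Series:
    """Mean absolute attribution per feature (model units, mV)."""
    if isinstance(X, pd.DataFrame):
        booster = _get_booster(model)
        if booster.feature_names is not None \
                and set(booster.feature_names) == set(X.columns):
            X = X[booster.feature_names]
    attributions, _ = shap_attributions(model, X, check_local_accuracy, tol)
    names = list(X.columns) if isinstance(X, pd.DataFrame) \
        else [f"f{i}" for i in range(attributions.shape[1])]
    return pd.Series(np.mean(np.abs(attributions), axis=0), index=names,
                     name="mean_abs_attribution")


def cv_shap_importance(matrix, model_kind: str = "gbt", grid=None,
                       cv=None, check_local_accuracy: bool = True) -> pd.Series:
    """Importance averaged over outer-fold models, each attributed on its own
    test fold."""
    from sklearn.model_selection import KFold

    from .mlcore import CVConfig, _make_model, _tune_and_fit
    cv = cv or CVConfig(repeats=1)
    if model_kind != "gbt":
        raise TypeError("attributions require the gradient-boosted model")
    X = matrix.X
    y = matrix.y.to_numpy(float)
    pieces = []
    for rep in range(cv.repeats):
        seed = cv.base_seed + rep
        outer = KFold(n_splits=cv.outer_folds, shuffle=True, random_state=seed)
        for tr, te in outer.split(X):
            model, _ = _tune_and_fit(X.iloc[tr].to_numpy(float), y[tr], model_kind,
                                     grid, cv.inner_folds, seed)
            pieces.append(shap_importance(model, X.iloc[te],
                                          check_local_accuracy=check_local_accuracy))
    return pd.concat(pieces, axis=1).mean(axis=1).rename("mean_abs_attribution")


def importance_heatmap(importances: Mapping, top_k: int = 20) -> pd.DataFrame:
    """Feature x model table of per-model-normalized importances.

    ``importances`` maps a model key (e.g. an (r1, r2) pair) to a per-feature
    importance Series. Each column is normalized to sum to one; rows are the
    ``top_k`` features by cross-model mean, in descending order.
    """
    if not importances:
        raise ValueError("no models given")
    cols = {}
    for key, imp in importances.items():
        total = float(imp.sum())
        cols[key] = imp / total if total > 0 else imp
    table = pd.DataFrame(cols)
    order = table.mean(axis=1).sort_values(ascending=False).index
    return table.loc[order[:top_k]]


def spearman_feature_rp(X: pd.DataFrame, y: Sequence[float]) -> pd.Series:
    """Spearman correlation of every feature with RP; constant features NaN."""
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 rows")
    out = {}
    for name in X.columns:
        col = X[name].to_numpy(dtype=float)
        if np.all(col == col[0]):
            out[name] = float("nan")
        else:
            out[name] = float(stats.spearmanr(col, y).statistic)
    return pd.Series(out, name="spearman_rp")
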