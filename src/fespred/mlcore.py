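"""Training and evaluation protocol for the RP regressors.

Implements the full protocol: MAE-minimizing grid search in a 10-fold inner
loop nested inside a 5-fold outer loop, the whole procedure repeated (10x
by default) with fresh fold assignments; radii scans over the (r1, r2)
grid; spatial-scale ablations; leave-protein-out and leave-mutant-set-out
generalization tests; and the pairwise Mann-Whitney comparison of model
variants. Fold assignment is random at the entry level (mutants of one
protein may straddle folds) -- the group-aware regime lives only in
``leave_proteins_out``.

Every outer split is checked for train/test overlap at run time, and all
randomness derives from ``CVConfig.base_seed`` so a rerun with the same
seed reproduces fold assignments, selected hyperparameters and metrics
bit-identically.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.model_selection import KFold

from . import descriptors as D
from .datasetio import DesignMatrix, FeaturizerConfig, build_design_matrix

__all__ = [
    "HyperGrid",
    "CVConfig",
    "ScaleMask",
    "Metrics",
    "EvalResult",
    "enumerate_grid",
    "metrics",
    "nested_cv",
    "scan_radii",
    "ablate",
    "leave_proteins_out",
    "leave_mutants_out",
    "compare_models_mannwhitney",
    "error_vs_resolution",
    "DEFAULT_MASKS",
]


@dataclass(frozen=True)
class HyperGrid:
    """The fixed hyperparameter grid (3 x 3 x 4 x 3 = 108 configurations)."""

    max_depth: tuple = (3, 4, 5)
    n_estimators: tuple = (100, 150, 200)
    learning_rate: tuple = (0.01, 0.1, 0.2, 0.4)
    min_child_weight: tuple = (1, 5, 10)


def enumerate_grid(grid: HyperGrid) -> list:
    """All configurations, lexicographic over the documented field order."""
    fields = ("max_depth", "n_estimators", "learning_rate", "min_child_weight")
    values = [getattr(grid, f) for f in fields]
    if any(len(v) == 0 for v in values):
        raise ValueError("empty hyperparameter grid")
    return [dict(zip(fields, combo)) for combo in itertools.product(*values)]


@dataclass(frozen=True)
class CVConfig:
    outer_folds: int = 5
    inner_folds: int = 10
    repeats: int = 10
    base_seed: int = 0

    def __post_init__(self):
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class ScaleMask:
    """Which structural scales enter the model; pH (and the other condition
    features) are always retained -- they are experimental conditions, not
    structural scales."""

    include_long: bool = True
    include_medium: bool = True
    include_short: bool = True
    name: str = "full"

    def __post_init__(self):
        if not (self.include_long or self.include_medium or self.include_short):
            raise ValueError("at least one scale must be on")

    def scale_tags(self) -> list:
        tags = ["condition"]
        if self.include_long:
            tags.append("long")
        if self.include_medium:
            tags.append("medium")
        if self.include_short:
            tags.append("short")
        return tags


DEFAULT_MASKS = (
    ScaleMask(True, True, True, "full"),
    ScaleMask(False, True, True, "no_long"),
    ScaleMask(True, False, True, "no_medium"),
    ScaleMask(True, True, False, "no_short"),
    ScaleMask(False, False, True, "short_only"),
    ScaleMask(False, True, False, "medium_only"),
    ScaleMask(True, False, False, "long_only"),
)


@dataclass
class Metrics:
    mae: float
    rmse: float
    r2: float
    sc: float
    r2_defined: bool = True
    sc_defined: bool = True

    def as_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "r2": self.r2, "sc": self.sc}


def metrics(y_true, y_pred) -> Metrics:
    """MAE, RMSE, R2 and Spearman correlation; R2/SC flagged undefined for a
    constant target."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if len(y_true) < 2:
        raise ValueError("need at least 2 points")
    delta = y_pred - y_true
    mae = float(np.mean(np.abs(delta)))
    rmse = float(np.sqrt(np.mean(delta ** 2)))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0.0:
        return Metrics(mae, rmse, float("nan"), float("nan"),
                       r2_defined=False, sc_defined=False)
    r2 = 1.0 - float(np.sum(delta ** 2)) / sst
    if np.std(y_pred) == 0.0:
        return Metrics(mae, rmse, r2, float("nan"), sc_defined=False)
    sc = float(stats.spearmanr(y_true, y_pred).statistic)
    return Metrics(mae, rmse, r2, sc)


@dataclass
class EvalResult:
    metrics_mean: dict  # metric -> mean over outer folds x repeats
    metrics_sd: dict
    fold_metrics: pd.DataFrame  # one row per (repeat, fold)
    oof_predictions: pd.DataFrame  # entry x repeat out-of-fold predictions
    per_class_mae: dict
    chosen_params: list  # per (repeat, fold)
    wall_time_s: float

    def __post_init__(self):
        for _, row in self.fold_metrics.iterrows():
            assert row["rmse"] >= row["mae"] - 1e-9


def _make_model(model_kind: str, params: Mapping | None, seed: int,
                n_rows: int, n_cols: int):
    if model_kind == "gbt":
        from xgboost import XGBRegressor
        return XGBRegressor(**(dict(params) if params else {}),
                            random_state=seed, n_jobs=1,
                            tree_method="hist", verbosity=0)
    if model_kind == "linear":
        # plain least squares is ill-posed when columns >= rows
        if n_cols >= n_rows:
            return Ridge(alpha=1.0)
        return LinearRegression()
    raise ValueError(f"unknown model kind {model_kind!r}")


def _inner_select(X: np.ndarray, y: np.ndarray, model_kind: str,
                  configs: Sequence[Mapping], inner_folds: int, seed: int) -> dict:
    """MAE-minimizing grid search over the inner folds (training rows only)."""
    if len(configs) == 1:
        return dict(configs[0])
    kf = KFold(n_splits=min(inner_folds, len(X)), shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    best = None
    for ci, cfg in enumerate(configs):
        maes = []
        for tr, va in splits:
            model = _make_model(model_kind, cfg, seed, len(tr), X.shape[1])
            model.fit(X[tr], y[tr])
            maes.append(float(np.mean(np.abs(model.predict(X[va]) - y[va]))))
        score = float(np.mean(maes))
        if best is None or score < best[0]:
            best = (score, ci)
    return dict(configs[best[1]])


def nested_cv(matrix: DesignMatrix, model_kind: str = "gbt",
              grid: HyperGrid | Sequence[Mapping] | None = None,
              cv: CVConfig = CVConfig()) -> EvalResult:
    """Nested cross-validation with out-of-fold prediction of every entry.

    The inner MAE-minimizing grid search sees only the outer-training rows;
    metrics are aggregated as mean +- sd over all outer folds x repeats.
    """
    t0 = time.time()
    configs = enumerate_grid(grid) if isinstance(grid, HyperGrid) else \
        (list(grid) if grid is not None else enumerate_grid(HyperGrid()))
    X = matrix.X.to_numpy(dtype=float)
    y = matrix.y.to_numpy(dtype=float)
    n = len(X)
    if n < cv.outer_folds:
        raise ValueError(f"{n} rows < {cv.outer_folds} outer folds")

    fold_rows, chosen, oof = [], [], {}
    for rep in range(cv.repeats):
        seed = cv.base_seed + rep
        outer = KFold(n_splits=cv.outer_folds, shuffle=True, random_state=seed)
        preds = np.full(n, np.nan)
        for fold, (tr, te) in enumerate(outer.split(X)):
            if len(te) < 1 or len(tr) < 2:
                raise ValueError("degenerate outer fold")
            assert len(np.intersect1d(tr, te)) == 0, "train/test row overlap"
            params = _inner_select(X[tr], y[tr], model_kind, configs,
                                   cv.inner_folds, seed)
            model = _make_model(model_kind, params if model_kind == "gbt" else None,
                                seed, len(tr), X.shape[1])
            model.fit(X[tr], y[tr])
            p = model.predict(X[te]).astype(float)
            preds[te] = p
            m = metrics(y[te], p) if len(te) >= 2 else None
            if m is not None:
                fold_rows.append({"repeat": rep, "fold": fold, **m.as_dict(),
                                  "r2_defined": m.r2_defined,
                                  "sc_defined": m.sc_defined})
            chosen.append({"repeat": rep, "fold": fold, "model_kind": model_kind,
                           **(params if model_kind == "gbt" else {})})
        assert not np.any(np.isnan(preds)), "some entry never predicted out-of-fold"
        oof[f"repeat_{rep}"] = preds

    fold_df = pd.DataFrame(fold_rows)
    means = {k: float(fold_df[k].mean()) for k in ("mae", "rmse", "r2", "sc")}
    sds = {k: float(fold_df[k].std(ddof=1)) if len(fold_df) > 1 else 0.0
           for k in ("mae", "rmse", "r2", "sc")}
    oof_df = pd.DataFrame(oof, index=matrix.X.index)

    per_class = {}
    if len(matrix.meta) and "protein_class" in matrix.meta:
        mean_pred = oof_df.mean(axis=1)
        for cls, idx in matrix.meta.groupby("protein_class").groups.items():
            per_class[cls] = float(np.mean(np.abs(mean_pred.loc[idx] - matrix.y.loc[idx])))

    return EvalResult(metrics_mean=means, metrics_sd=sds, fold_metrics=fold_df,
                      oof_predictions=oof_df, per_class_mae=per_class,
                      chosen_params=chosen, wall_time_s=time.time() - t0)


def scan_radii(entries, structures=None, structure_dir=None,
               model_kind: str = "gbt", grid=None, cv: CVConfig = CVConfig(),
               r1_grid: Sequence[float] = D.R1_GRID,
               r2_grid: Sequence[float] = D.R2_GRID,
               table: D.ResiduePropertyTable = D.DEFAULT_PROPERTY_TABLE):
    """Strategy-A evaluation per (r1, r2); returns (results dict, summary frame,
    best cell by mean MAE)."""
    results = {}
    for r1 in r1_grid:
        for r2 in r2_grid:
            if r2 >= r1:
                continue
            cfg = FeaturizerConfig(strategy="A", r1=float(r1), r2=float(r2))
            matrix = build_design_matrix(entries, cfg, structures=structures,
                                         structure_dir=structure_dir, table=table)
            results[(r1, r2)] = nested_cv(matrix, model_kind, grid, cv)
    summary = pd.DataFrame([
        {"r1": r1, "r2": r2, "mae_mean": res.metrics_mean["mae"],
         "mae_sd": res.metrics_sd["mae"], "r2_mean": res.metrics_mean["r2"],
         "sc_mean": res.metrics_mean["sc"]}
        for (r1, r2), res in results.items()])
    best = min(results, key=lambda k: results[k].metrics_mean["mae"])
    return results, summary, best


def ablate(matrix: DesignMatrix, masks: Sequence[ScaleMask] = DEFAULT_MASKS,
           model_kind: str = "gbt", grid=None, cv: CVConfig = CVConfig()):
    """One nested-CV evaluation per scale mask, in the given order."""
    out = {}
    for mask in masks:
        cols = matrix.schema.names_by_scale(mask.scale_tags())
        cols = [c for c in cols if c in matrix.X.columns]
        if not cols:
            raise ValueError(f"mask {mask.name!r} removes all features")
        out[mask.name] = nested_cv(matrix.subset_columns(cols), model_kind, grid, cv)
    return out


def _tune_and_fit(X_tr, y_tr, model_kind, grid, inner_folds, seed):
    configs = enumerate_grid(grid) if isinstance(grid, HyperGrid) else \
        (list(grid) if grid is not None else enumerate_grid(HyperGrid()))
    params = _inner_select(X_tr, y_tr, model_kind, configs, inner_folds, seed)
    model = _make_model(model_kind, params if model_kind == "gbt" else None,
                        seed, len(X_tr), X_tr.shape[1])
    model.fit(X_tr, y_tr)
    return model, params


def leave_proteins_out(matrix: DesignMatrix, held_out_protein_ids: Sequence[str],
                       model_kind: str = "gbt", grid=None, inner_folds: int = 10,
                       seed: int = 0):
    """Exclude whole proteins (all their entries, mutants included) from
    training and predict them de novo.

    Returns (per-protein MAE dict, overall MAE, predictions Series).
    """
    held = set(held_out_protein_ids)
    if not held:
        raise ValueError("held-out set is empty")
    unknown = held - set(matrix.groups.unique())
    if unknown:
        raise ValueError(f"held-out proteins not in data set: {sorted(unknown)}")
    test_mask = matrix.groups.isin(held)
    if test_mask.all():
        raise ValueError("cannot hold out every protein")
    train_ids = matrix.X.index[~test_mask]
    test_ids = matrix.X.index[test_mask]
    assert set(train_ids).isdisjoint(test_ids)
    assert not matrix.groups.loc[train_ids].isin(held).any(), "held-out leakage"

    model, _ = _tune_and_fit(matrix.X.loc[train_ids].to_numpy(float),
                             matrix.y.loc[train_ids].to_numpy(float),
                             model_kind, grid, inner_folds, seed)
    preds = pd.Series(model.predict(matrix.X.loc[test_ids].to_numpy(float))
                      .astype(float), index=test_ids)
    abs_err = (preds - matrix.y.loc[test_ids]).abs()
    per_protein = {pid: float(abs_err[matrix.groups.loc[test_ids] == pid].mean())
                   for pid in sorted(held)}
    return per_protein, float(abs_err.mean()), preds


def leave_mutants_out(matrix: DesignMatrix, mutant_entry_ids: Sequence[str],
                      model_kind: str = "gbt", grid=None, inner_folds: int = 10,
                      seed: int = 0, dead_band: float = 5.0):
    """Hold out selected mutants, predict their RP and the direction of the
    shift relative to the wild type.

    Each mutant's wild type must remain in training. Experimental shifts with
    |dRP| <= dead_band count as "unchanged"; predicted shifts are classified
    with the same dead-band. Returns a result frame plus (MAE over mutants,
    sign-agreement rate).
    """
    mutants = list(mutant_entry_ids)
    if not mutants:
        raise ValueError("no mutants selected")
    wt_by_group = {}
    for eid in matrix.X.index:
        if matrix.meta.loc[eid, "mutation_label"].upper() == "WT":
            wt_by_group.setdefault(matrix.groups.loc[eid], eid)
    train_ids = [eid for eid in matrix.X.index if eid not in set(mutants)]
    for eid in mutants:
        g = matrix.groups.loc[eid]
        if g not in wt_by_group or wt_by_group[g] not in train_ids:
            raise ValueError(f"mutant {eid}: wild type of {g} missing from training")

    model, _ = _tune_and_fit(matrix.X.loc[train_ids].to_numpy(float),
                             matrix.y.loc[train_ids].to_numpy(float),
                             model_kind, grid, inner_folds, seed)

    def classify(delta):
        if abs(delta) <= dead_band:
            return "unchanged"
        return "up" if delta > 0 else "down"

    rows = []
    for eid in mutants:
        wt = wt_by_group[matrix.groups.loc[eid]]
        pred_m = float(model.predict(matrix.X.loc[[eid]].to_numpy(float))[0])
        pred_wt = float(model.predict(matrix.X.loc[[wt]].to_numpy(float))[0])
        d_pred = pred_m - pred_wt
        d_exp = float(matrix.y.loc[eid] - matrix.y.loc[wt])
        rows.append({"entry_id": eid, "wt_entry_id": wt, "pred_mv": pred_m,
                     "exp_mv": float(matrix.y.loc[eid]),
                     "abs_err_mv": abs(pred_m - float(matrix.y.loc[eid])),
                     "delta_pred_mv": d_pred, "delta_exp_mv": d_exp,
                     "direction_pred": classify(d_pred),
                     "direction_exp": classify(d_exp)})
    frame = pd.DataFrame(rows)
    mae = float(frame["abs_err_mv"].mean())
    agree = float((frame["direction_pred"] == frame["direction_exp"]).mean())
    return frame, mae, agree


def compare_models_mannwhitney(results: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Two-sided Mann-Whitney U p-values between fold-level MAE samples.

    Symmetric matrix with unit diagonal; exact p-values for small samples
    without ties.
    """
    names = list(results)
    if len(names) < 2:
        raise ValueError("need at least two result sets")
    for name in names:
        if len(results[name]) < 3:
            raise ValueError(f"{name}: need >= 3 fold-level MAEs")
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        x, y = np.asarray(results[a], float), np.asarray(results[b], float)
        method = "exact" if (len(x) <= 25 and len(y) <= 25
                             and len(np.unique(np.concatenate([x, y])))
                             == len(x) + len(y)) else "auto"
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method=method).pvalue)
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def error_vs_resolution(abs_errors: pd.Series, resolutions: pd.Series):
    """Spearman correlation of |prediction error| with crystallographic
    resolution over the entries where resolution is known."""
    joined = pd.concat([abs_errors.rename("err"), resolutions.rename("res")],
                       axis=1).dropna()
    if len(joined) < 3:
        raise ValueError(f"only {len(joined)} entries with resolution (< 3)")
    if joined["err"].nunique() == 1 or joined["res"].nunique() == 1:
        return {"sc": float("nan"), "p_value": float("nan"),
                "n": len(joined), "defined": False}
    sc = stats.spearmanr(joined["err"], joined["res"])
    return {"sc": float(sc.statistic), "p_value": float(sc.pvalue),
            "n": len(joined), "defined": True}
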