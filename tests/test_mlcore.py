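"""Training/evaluation protocol: grids, metrics, nested CV, holdout tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fespred import mlcore as M
from fespred.datasetio import DesignMatrix
from fespred.descriptors import build_schema


class TestGrid:
    def test_default_grid_is_108(self):
        assert len(M.enumerate_grid(M.HyperGrid())) == 108

    def test_single_value_grid(self):
        g = M.HyperGrid(max_depth=(3,), n_estimators=(100,),
                        learning_rate=(0.1,), min_child_weight=(1,))
        assert len(M.enumerate_grid(g)) == 1

    def test_two_by_four(self):
        g = M.HyperGrid(max_depth=(3, 4), n_estimators=(100, 200),
                        learning_rate=(0.1, 0.2), min_child_weight=(1, 5))
        assert len(M.enumerate_grid(g)) == 16

    def test_pure_function_deterministic_order(self):
        g = M.HyperGrid()
        a, b = M.enumerate_grid(g), M.enumerate_grid(g)
        assert a == b
        assert a[0] == {"max_depth": 3, "n_estimators": 100,
                        "learning_rate": 0.01, "min_child_weight": 1}


def _reference_metrics(y_true, y_pred):
    """Independent reimplementation from the definitions."""
    y_true, y_pred = np.asarray(y_true, float), np.asarray(y_pred, float)
    mae = np.abs(y_pred - y_true).mean()
    rmse = np.sqrt(((y_pred - y_true) ** 2).mean())
    r2 = 1 - ((y_pred - y_true) ** 2).sum() / ((y_true - y_true.mean()) ** 2).sum()

    def ranks(v):
        order = np.argsort(v)
        r = np.empty(len(v))
        r[order] = np.arange(1, len(v) + 1)
        return r

    rx, ry = ranks(y_true), ranks(y_pred)  # valid without ties
    sc = np.corrcoef(rx, ry)[0, 1]
    return mae, rmse, r2, sc


class TestMetrics:
    def test_identity(self):
        m = M.metrics([1.0, 2, 3], [1.0, 2, 3])
        assert (m.mae, m.rmse, m.r2, m.sc) == (0, 0, 1, 1)

    def test_symmetric_fifty(self):
        m = M.metrics([50.0, 50.0001], [0.0, 100.0])
        assert m.mae == pytest.approx(50.0, abs=1e-3)

    def test_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=20)
        p = y + rng.normal(size=20)
        m = M.metrics(y, p)
        ref = _reference_metrics(y, p)
        np.testing.assert_allclose([m.mae, m.rmse, m.r2, m.sc], ref, atol=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            M.metrics([1, 2], [1, 2, 3])

    def test_constant_target_flagged(self):
        m = M.metrics([5.0, 5.0, 5.0], [4.0, 5.0, 6.0])
        assert not m.r2_defined and not m.sc_defined


def _linear_matrix(n=60, p=4, sigma=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    w = np.arange(1, p + 1) * 10.0
    y = X @ w + rng.normal(0, sigma, size=n)
    ids = [f"e{i}" for i in range(n)]
    schema = build_schema()
    Xdf = pd.DataFrame(X, index=ids, columns=schema.names[:p])
    return DesignMatrix(X=Xdf, y=pd.Series(y, index=ids),
                        groups=pd.Series([f"g{i // 3}" for i in range(n)], index=ids),
                        schema=schema,
                        meta=pd.DataFrame({"mutation_label": ["WT"] * n,
                                           "protein_class": ["ferredoxin"] * n},
                                          index=ids))


class TestNestedCV:
    def test_noiseless_linear_recovered(self, fast_cv):
        mx = _linear_matrix(sigma=0.0)
        res = M.nested_cv(mx, "linear", None, fast_cv)
        assert res.metrics_mean["r2"] >= 0.999

    def test_constant_target(self, one_config, fast_cv):
        mx = _linear_matrix()
        mx = DesignMatrix(X=mx.X, y=pd.Series(7.0, index=mx.X.index),
                          groups=mx.groups, schema=mx.schema, meta=mx.meta)
        res = M.nested_cv(mx, "gbt", one_config, fast_cv)
        assert res.metrics_mean["mae"] == pytest.approx(0.0, abs=1e-3)
        assert not res.fold_metrics["r2_defined"].any()

    def test_permutation_null(self, one_config, fast_cv):
        mx = _linear_matrix(n=80, sigma=0.0, seed=3)
        rng = np.random.default_rng(0)
        y_perm = pd.Series(rng.permutation(mx.y.to_numpy()), index=mx.X.index)
        mx = DesignMatrix(X=mx.X, y=y_perm, groups=mx.groups, schema=mx.schema,
                          meta=mx.meta)
        res = M.nested_cv(mx, "gbt", one_config, fast_cv)
        assert res.metrics_mean["r2"] < 0.25  # no real signal to find

    def test_reproducibility_bit_identical(self, tiny_grid, fast_cv):
        mx = _linear_matrix(sigma=5.0)
        a = M.nested_cv(mx, "gbt", tiny_grid, fast_cv)
        b = M.nested_cv(mx, "gbt", tiny_grid, fast_cv)
        assert a.metrics_mean == b.metrics_mean
        pd.testing.assert_frame_equal(a.oof_predictions, b.oof_predictions)
        assert a.chosen_params == b.chosen_params

    def test_different_seed_changes_folds(self, one_config):
        mx = _linear_matrix(sigma=5.0)
        a = M.nested_cv(mx, "gbt", one_config,
                        M.CVConfig(5, 3, repeats=1, base_seed=0))
        b = M.nested_cv(mx, "gbt", one_config,
                        M.CVConfig(5, 3, repeats=1, base_seed=99))
        assert not a.oof_predictions.equals(b.oof_predictions)

    def test_rmse_at_least_mae_every_fold(self, one_config, fast_cv):
        mx = _linear_matrix(sigma=10.0)
        res = M.nested_cv(mx, "gbt", one_config, fast_cv)
        assert (res.fold_metrics["rmse"] >= res.fold_metrics["mae"]).all()

    def test_every_entry_predicted_once_per_repeat(self, one_config):
        mx = _linear_matrix()
        res = M.nested_cv(mx, "gbt", one_config,
                          M.CVConfig(5, 3, repeats=2, base_seed=0))
        assert res.oof_predictions.shape == (60, 2)
        assert not res.oof_predictions.isna().any().any()

    def test_too_few_rows(self, one_config):
        mx = _linear_matrix(n=3)
        with pytest.raises(ValueError, match="outer folds"):
            M.nested_cv(mx, "gbt", one_config, M.CVConfig(5, 3, 1, 0))


class TestScanAndAblate:
    def test_reduced_scan_has_two_cells(self, small_dataset, one_config, fast_cv):
        results, summary, best = M.scan_radii(
            small_dataset.entries, structures=small_dataset.structures,
            model_kind="gbt", grid=one_config, cv=fast_cv,
            r1_grid=(8, 9), r2_grid=(3,))
        assert set(results) == {(8, 3), (9, 3)}
        assert len(summary) == 2
        assert best in results

    def test_full_mask_equals_plain_nested_cv(self, small_matrix, one_config,
                                              fast_cv):
        full = M.ablate(small_matrix, [M.ScaleMask(name="full")], "gbt",
                        one_config, fast_cv)["full"]
        plain = M.nested_cv(small_matrix, "gbt", one_config, fast_cv)
        assert full.metrics_mean == plain.metrics_mean

    def test_short_only_column_bookkeeping(self, small_matrix, one_config, fast_cv):
        mask = M.ScaleMask(False, False, True, "short_only")
        cols = small_matrix.schema.names_by_scale(mask.scale_tags())
        n_short = sum(1 for f in small_matrix.schema.fields
                      if f.scale_tag == "short")
        n_cond = sum(1 for f in small_matrix.schema.fields
                     if f.scale_tag == "condition")
        assert len(cols) == n_short + n_cond

    def test_all_scales_off_rejected(self):
        with pytest.raises(ValueError, match="at least one scale"):
            M.ScaleMask(False, False, False)

    def test_mask_with_no_matching_columns_rejected(self, small_matrix,
                                                    one_config, fast_cv):
        long_cols = small_matrix.schema.names_by_scale(["long"])
        sub = small_matrix.subset_columns(long_cols)
        with pytest.raises(ValueError, match="removes all features"):
            M.ablate(sub, [M.ScaleMask(False, True, False, "medium_only")],
                     "gbt", one_config, fast_cv)


class TestConstructedSimulations:
    def test_short_range_signal_punishes_long_only_mask(self, one_config):
        # RP driven purely by a short-scale descriptor: removing the short
        # blocks must cost accuracy, confirmed by the Mann-Whitney comparison
        from fespred import synthetic as S
        from fespred.datasetio import FeaturizerConfig, build_design_matrix
        spec = S.SyntheticRPSpec(n_proteins=15, mutants_per_protein=1, sigma=10.0,
                                 support=("CofAtom.Fe.2.HydrophobicCount",),
                                 weights=(-80.0,), seed=2)
        ds = S.make_synthetic_dataset(spec)
        mx = build_design_matrix(ds.entries, FeaturizerConfig(r1=11, r2=4),
                                 structures=ds.structures)
        cv = M.CVConfig(outer_folds=5, inner_folds=3, repeats=3, base_seed=0)
        res = M.ablate(mx, [M.ScaleMask(name="full"),
                            M.ScaleMask(True, False, False, "long_only")],
                       "gbt", one_config, cv)
        assert res["long_only"].metrics_mean["mae"] > res["full"].metrics_mean["mae"]
        p = M.compare_models_mannwhitney(
            {k: r.fold_metrics["mae"].tolist() for k, r in res.items()})
        assert p.loc["full", "long_only"] < 0.05

    def test_radius_scan_recovers_generative_locality(self, one_config):
        # medium-range signal generated in a 10 A sphere: the scan's best
        # cell lands at (or adjacent to) r1 = 10
        from fespred import synthetic as S
        spec = S.SyntheticRPSpec(n_proteins=30, mutants_per_protein=1, sigma=10.0,
                                 support=("Bar.GlyProCount", "Global.pH"),
                                 weights=(-80.0, -40.0), ref_r1=10.0, ref_r2=3.0,
                                 seed=4)
        ds = S.make_synthetic_dataset(spec)
        _, _, best = M.scan_radii(ds.entries, structures=ds.structures,
                                  model_kind="gbt", grid=one_config,
                                  cv=M.CVConfig(5, 3, repeats=2, base_seed=0),
                                  r1_grid=(8, 10, 12, 16), r2_grid=(3,))
        assert best[0] in (8, 10, 12)


class TestHoldout:
    def test_leave_proteins_out_no_leakage_and_outputs(self, small_matrix,
                                                       one_config):
        held = ["P000", "P003"]
        per, overall, preds = M.leave_proteins_out(small_matrix, held,
                                                   grid=one_config,
                                                   inner_folds=3, seed=0)
        assert set(per) == set(held)
        held_entries = small_matrix.groups[small_matrix.groups.isin(held)].index
        assert set(preds.index) == set(held_entries)
        assert overall >= 0

    def test_noiseless_linear_holdout_near_zero(self):
        mx = _linear_matrix(n=60, sigma=0.0)
        per, overall, _ = M.leave_proteins_out(mx, ["g0"], model_kind="linear",
                                               inner_folds=3, seed=0)
        assert overall == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_holdouts(self, small_matrix, one_config):
        with pytest.raises(ValueError, match="empty"):
            M.leave_proteins_out(small_matrix, [], grid=one_config)
        all_groups = list(small_matrix.groups.unique())
        with pytest.raises(ValueError, match="every protein"):
            M.leave_proteins_out(small_matrix, all_groups, grid=one_config)

    def test_mutant_holdout_directions(self, small_matrix, one_config):
        mutants = [eid for eid in small_matrix.X.index
                   if small_matrix.meta.loc[eid, "mutation_label"] != "WT"][:3]
        frame, mae, agree = M.leave_mutants_out(small_matrix, mutants,
                                                grid=one_config, inner_folds=3,
                                                seed=0, dead_band=5.0)
        assert len(frame) == 3 and mae >= 0 and 0 <= agree <= 1
        assert set(frame["direction_exp"]) <= {"up", "down", "unchanged"}

    def test_mutant_identical_to_wt_predicts_zero_shift(self, small_matrix,
                                                        one_config):
        # clone a WT row as a pseudo-mutant: identical features => zero dRP
        import copy
        wt_id = small_matrix.X.index[0]
        X = pd.concat([small_matrix.X,
                       small_matrix.X.loc[[wt_id]].set_axis(["clone"])])
        y = pd.concat([small_matrix.y, pd.Series({"clone": small_matrix.y[wt_id]})])
        g = pd.concat([small_matrix.groups,
                       pd.Series({"clone": small_matrix.groups[wt_id]})])
        meta = pd.concat([small_matrix.meta,
                          small_matrix.meta.loc[[wt_id]].set_axis(["clone"])])
        meta.loc["clone", "mutation_label"] = "A1A"
        mx = DesignMatrix(X=X, y=y, groups=g, schema=small_matrix.schema, meta=meta)
        frame, _, _ = M.leave_mutants_out(mx, ["clone"], grid=one_config,
                                          inner_folds=3, seed=0)
        assert frame["delta_pred_mv"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert frame["direction_pred"].iloc[0] == "unchanged"

    def test_dead_band_classifies_small_shift_unchanged(self):
        # |dRP_exp| = 2 mV <= 5 mV dead-band -> "unchanged"
        mx = _linear_matrix(n=20, sigma=0.0)
        meta = mx.meta.copy()
        meta["mutation_label"] = ["WT"] * 19 + ["M1X"]
        g = mx.groups.copy()
        g.iloc[-1] = g.iloc[0]
        y = mx.y.copy()
        y.iloc[-1] = y.loc[g.iloc[0] == mx.groups].iloc[0] + 2.0
        mx2 = DesignMatrix(X=mx.X, y=y, groups=g, schema=mx.schema, meta=meta)
        frame, _, _ = M.leave_mutants_out(mx2, [mx.X.index[-1]], model_kind="linear",
                                          inner_folds=3, seed=0)
        assert frame["direction_exp"].iloc[0] == "unchanged"

    def test_missing_wt_raises(self, small_matrix, one_config):
        no_wt = small_matrix.meta.copy()
        no_wt["mutation_label"] = "X1Y"
        mx = DesignMatrix(X=small_matrix.X, y=small_matrix.y,
                          groups=small_matrix.groups, schema=small_matrix.schema,
                          meta=no_wt)
        with pytest.raises(ValueError, match="wild type"):
            M.leave_mutants_out(mx, [small_matrix.X.index[1]], grid=one_config)


class TestMannWhitney:
    def test_identical_samples_p_near_one(self):
        p = M.compare_models_mannwhitney({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert p.loc["a", "b"] >= 0.99

    def test_exact_p_for_separated_triplets(self):
        p = M.compare_models_mannwhitney({"a": [1, 2, 3], "b": [101, 102, 103]})
        assert p.loc["a", "b"] == pytest.approx(0.1, abs=1e-12)

    def test_exact_p_matches_enumeration_oracle(self):
        # brute-force: U distribution over all C(6,3)=20 rank assignments
        x, y = [1.0, 2, 3], [101.0, 102, 103]
        pooled = sorted(x + y)
        us = []
        for combo in itertools.combinations(range(6), 3):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(6) if i not in combo]
            u = sum(1 for a in xs for b in ys if a > b)
            us.append(u)
        u_obs = sum(1 for a in x for b in y if a > b)
        # two-sided: double the one-sided tail of the symmetric U distribution
        tail = sum(1 for u in us if u <= min(u_obs, 9 - u_obs)) / len(us)
        p_exact = min(1.0, 2 * tail)
        got = M.compare_models_mannwhitney({"a": x, "b": y}).loc["a", "b"]
        assert got == pytest.approx(p_exact, abs=1e-12)
        assert p_exact == pytest.approx(0.1)

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(1)
        res = {k: rng.normal(size=6).tolist() for k in "abc"}
        p = M.compare_models_mannwhitney(res)
        assert np.allclose(p.values, p.values.T)
        assert np.all(np.diag(p.values) == 1.0)

    def test_insufficient_samples(self):
        with pytest.raises(ValueError, match=">= 3"):
            M.compare_models_mannwhitney({"a": [1, 2], "b": [1, 2, 3]})


class TestErrorVsResolution:
    def test_monotone_pairs_perfect_correlation(self):
        err = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        res = pd.Series([1.1, 1.5, 2.0, 2.9], index=list("abcd"))
        out = M.error_vs_resolution(err, res)
        assert out["sc"] == pytest.approx(1.0)

    def test_constant_errors_flagged(self):
        err = pd.Series([2.0, 2, 2, 2], index=list("abcd"))
        res = pd.Series([1.1, 1.5, 2.0, 2.9], index=list("abcd"))
        assert not M.error_vs_resolution(err, res)["defined"]

    def test_independent_errors_small_correlation(self):
        rng = np.random.default_rng(4)
        err = pd.Series(np.abs(rng.normal(size=60)))
        res = pd.Series(rng.uniform(1, 3, size=60))
        out = M.error_vs_resolution(err, res)
        assert abs(out["sc"]) < 0.3

    def test_too_few_resolved(self):
        err = pd.Series([1.0, 2, 3], index=list("abc"))
        res = pd.Series([1.0, np.nan, np.nan], index=list("abc"))
        with pytest.raises(ValueError, match="< 3"):
            M.error_vs_resolution(err, res)
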