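import numpy as np
import pandas as pd
import pytest

from evorisk import selection_pipeline as sp


def survival_data(n, beta, seed=0, censor_rate=0.02, base_rate=0.02, p_extra=0):
    """X ~ N(0,1), proportional-hazards outcomes with the given coefficients."""
    rng = np.random.default_rng(seed)
    p = len(beta) + p_extra
    X = rng.normal(size=(n, p))
    eta = X[:, : len(beta)] @ np.asarray(beta)
    T = rng.exponential(1.0 / (base_rate * np.exp(eta)))
    C = rng.exponential(1.0 / censor_rate, size=n)
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
    return df, np.minimum(T, C), (T <= C).astype(int)


class TestSelectionConfig:
    def test_protocol_defaults(self):
        cfg = sp.SelectionConfig()
        assert cfg.n_boot == 1000
        assert cfg.boot_feature_frac == 0.8
        assert cfg.boot_sample_frac == 0.8
        assert cfg.corr_threshold == 0.8
        assert cfg.outer_folds == 3
        assert cfg.outer_repeats == 5
        assert cfg.inner_scheme in ("kfold3", "loocv")
        for lam in (0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0):
            assert lam in cfg.lambda_grid

    @pytest.mark.parametrize(
        "kwargs",
        [dict(boot_feature_frac=0.0), dict(outer_folds=1), dict(max_k=0), dict(inner_scheme="x")],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            sp.SelectionConfig(**kwargs)


class TestPruneCollinear:
    def test_duplicate_column_one_survives(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        reduced, log = sp.prune_collinear(df, 0.8, rng)
        assert len({"a", "b"} & set(reduced.columns)) == 1
        assert "c" in reduced.columns

    def test_moderate_correlation_retained(self, rng):
        x = rng.normal(size=2000)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=2000)  # r = 0.5
        df = pd.DataFrame({"a": x, "b": y})
        reduced, _ = sp.prune_collinear(df, 0.8, rng)
        assert list(reduced.columns) == ["a", "b"]

    def test_zero_variance_dropped_first(self, rng):
        df = pd.DataFrame({"flat": np.ones(50), "x": rng.normal(size=50)})
        reduced, log = sp.prune_collinear(df, 0.8, rng)
        assert list(reduced.columns) == ["x"]
        assert ("flat", None, None) in log

    def test_deterministic_under_seed(self, rng):
        x = np.random.default_rng(1).normal(size=200)
        df = pd.DataFrame({"a": x, "b": x + 1e-9, "c": -x})
        r1, _ = sp.prune_collinear(df, 0.8, np.random.default_rng(5))
        r2, _ = sp.prune_collinear(df, 0.8, np.random.default_rng(5))
        assert list(r1.columns) == list(r2.columns)


class TestStepwise:
    def test_perfect_predictor_selected_first(self):
        df, y, delta = survival_data(150, [2.0], seed=1, p_extra=1)
        selected, trace = sp.stepwise_l0(df, y, delta, rng=np.random.default_rng(0))
        assert selected[0] == "f0"

    def test_trace_nondecreasing(self):
        df, y, delta = survival_data(200, [1.0, 0.8, 0.6], seed=2, p_extra=5)
        _, trace = sp.stepwise_l0(df, y, delta, rng=np.random.default_rng(0))
        scores = [s for _, s in trace]
        assert scores == sorted(scores)

    def test_max_k_respected(self):
        df, y, delta = survival_data(200, [1.0, 0.8, 0.6, 0.5], seed=3, p_extra=4)
        selected, _ = sp.stepwise_l0(df, y, delta, max_k=2, rng=np.random.default_rng(0))
        assert len(selected) <= 2

    def test_simulation_oracle_recovers_true_features(self):
        # 3 strongly hazardous features among 30; selection should find >= 2
        # of them in >= 80% of seeded runs
        hits = 0
        n_runs = 30
        for seed in range(n_runs):
            df, y, delta = survival_data(150, [1.5, 1.5, 1.5], seed=seed, p_extra=27)
            selected, _ = sp.stepwise_l0(df, y, delta, max_k=5, rng=np.random.default_rng(seed))
            if len({"f0", "f1", "f2"} & set(selected)) >= 2:
                hits += 1
        assert hits / n_runs >= 0.8

    def test_loocv_scheme_runs(self):
        df, y, delta = survival_data(25, [2.0], seed=4, p_extra=1)
        selected, _ = sp.stepwise_l0(df, y, delta, inner_scheme="loocv", rng=np.random.default_rng(0))
        assert isinstance(selected, list)


class TestTwoLoopCV:
    def test_bookkeeping_each_sample_once_per_replicate(self):
        df, y, delta = survival_data(60, [1.0], seed=5, p_extra=3)
        cfg = sp.SelectionConfig(outer_repeats=2, max_k=2, seed=9)
        res = sp.two_loop_cv(df, y, delta, cfg)
        counts = res.predictions.groupby(["replicate", "sample"]).size()
        assert (counts == 1).all()
        assert res.predictions.groupby("sample").size().eq(2).all()

    def test_determinism(self):
        df, y, delta = survival_data(60, [1.0], seed=6, p_extra=3)
        cfg = sp.SelectionConfig(outer_repeats=2, max_k=2, seed=4)
        a = sp.two_loop_cv(df, y, delta, cfg)
        b = sp.two_loop_cv(df, y, delta, cfg)
        pd.testing.assert_frame_equal(a.predictions, b.predictions)
        assert a.selections == b.selections

    def test_lasso_mode_runs_and_reports_nonzero(self):
        df, y, delta = survival_data(120, [1.5, 1.0], seed=7, p_extra=4)
        cfg = sp.SelectionConfig(outer_repeats=1, seed=2)
        res = sp.two_loop_cv(df, y, delta, cfg, model="lasso")
        assert np.isfinite(res.mean_ci)

    def test_l0_beats_or_ties_lasso_on_benchmark(self):
        df, y, delta = survival_data(200, [1.5, 1.2, 1.0], seed=8, p_extra=17)
        cfg = sp.SelectionConfig(outer_repeats=2, max_k=5, seed=3)
        l0 = sp.two_loop_cv(df, y, delta, cfg)
        lasso = sp.two_loop_cv(df, y, delta, cfg, model="lasso")
        assert l0.mean_ci >= lasso.mean_ci - 1e-9

    def test_leakage_canary_not_selected(self):
        """A feature carrying outcome information only in each model's test
        fold must not change training-time selection."""
        df, y, delta = survival_data(90, [1.0], seed=10, p_extra=5)
        cfg = sp.SelectionConfig(outer_repeats=1, max_k=3, seed=11)
        base = sp.two_loop_cv(df, y, delta, cfg)
        # reconstruct replicate-0 fold ids from the same seeded stream
        fold_ids = sp.outer_fold_assignments(
            len(df), cfg.outer_folds, sp._rng(cfg.seed, sp._STREAM_FOLDS, 0), delta
        )
        # constant in fold 0's training rows (folds 1+2), event indicator in
        # its test rows: only a train/test leak could make it selectable
        canary = np.full(len(df), 0.5)
        canary[fold_ids == 0] = delta[fold_ids == 0]
        df2 = df.copy()
        df2["canary"] = canary
        leaked = sp.two_loop_cv(df2, y, delta, cfg)
        # fold 0's model trains on folds 1+2 where the canary is noise
        assert "canary" not in leaked.selections[(0, 0)]
        assert leaked.selections[(0, 0)] == base.selections[(0, 0)]


class TestPermutationControl:
    def test_identity_permutation_is_noop(self):
        df, y, delta = survival_data(60, [1.5], seed=12, p_extra=2)
        cfg = sp.SelectionConfig(outer_repeats=1, max_k=2, seed=13)
        direct = sp.two_loop_cv(df, y, delta, cfg)
        perm = sp.permutation_control(df, y, delta, cfg, permutation=np.arange(len(df)))
        pd.testing.assert_frame_equal(direct.predictions, perm.predictions)

    def test_breaks_association(self):
        df, y, delta = survival_data(150, [2.0, 1.5], seed=14, p_extra=4)
        cfg = sp.SelectionConfig(outer_repeats=2, max_k=3, seed=15)
        direct = sp.two_loop_cv(df, y, delta, cfg)
        perm = sp.permutation_control(df, y, delta, cfg)
        assert direct.mean_ci > 0.65
        assert abs(perm.mean_ci - 0.5) < 0.1


class TestBootstrapImportance:
    def test_zero_variance_feature_never_selected(self):
        df, y, delta = survival_data(80, [1.5], seed=16, p_extra=2)
        df["flat"] = 1.0
        cfg = sp.SelectionConfig(n_boot=20, max_k=2, seed=17)
        table = sp.bootstrap_importance(df, y, delta, cfg)
        assert table.frequency["flat"] == 0.0

    def test_frequencies_in_unit_interval(self):
        df, y, delta = survival_data(80, [1.5], seed=18, p_extra=3)
        cfg = sp.SelectionConfig(n_boot=15, max_k=2, seed=19)
        table = sp.bootstrap_importance(df, y, delta, cfg)
        assert all(0.0 <= f <= 1.0 for f in table.frequency.values())
        assert table.n_boot == 15

    def test_strong_feature_attains_max_frequency(self):
        df, y, delta = survival_data(200, [2.5], seed=20, p_extra=10)
        cfg = sp.SelectionConfig(n_boot=30, max_k=3, seed=21)
        table = sp.bootstrap_importance(df, y, delta, cfg)
        assert table.frequency["f0"] == max(table.frequency.values())


class TestCorrelationLandscape:
    def test_duplicate_and_negated(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": -x, "d": rng.normal(size=200)})
        corr, order, missing = sp.correlation_landscape(df)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert missing == []

    def test_zero_variance_reported_missing(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50), "flat": np.ones(50)})
        corr, order, missing = sp.correlation_landscape(df)
        assert missing == ["flat"]
        assert "flat" not in corr.columns

    def test_planted_blocks_contiguous(self, rng):
        n = 300
        u, v = rng.normal(size=n), rng.normal(size=n)
        cols = {}
        for i in range(4):
            cols[f"u{i}"] = u + 0.1 * rng.normal(size=n)
            cols[f"v{i}"] = v + 0.1 * rng.normal(size=n)
        _, order, _ = sp.correlation_landscape(pd.DataFrame(cols))
        pos_u = sorted(order.index(f"u{i}") for i in range(4))
        pos_v = sorted(order.index(f"v{i}") for i in range(4))
        assert pos_u[-1] - pos_u[0] == 3  # block members adjacent
        assert pos_v[-1] - pos_v[0] == 3
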