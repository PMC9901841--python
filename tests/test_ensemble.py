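"""Stacked ensemble, applicability domain, baselines and surrogate tree."""

import numpy as np
import pandas as pd
import pytest

from pampanet import ensemble, metrics
from pampanet.chemdata import DescriptorTable
from pampanet.rprop_mlp import RpropConfig
from pampanet.selection import CVPlan
from pampanet.synthetic import SyntheticSpec, generate_descriptor_dataset


class TestEnsembleSD:
    @pytest.mark.parametrize(
        "preds, expected",
        [
            ([-5.5, -5.5, -5.5], 0.0),
            ([-5.0, -6.0], np.sqrt(0.5)),
            ([0.0, 0.0, 3.0], np.sqrt(3.0)),
        ],
    )
    def test_hand_values(self, preds, expected):
        assert ensemble.ensemble_sd(preds) == pytest.approx(expected, abs=1e-12)

    def test_matches_two_pass_variance_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            preds = rng.normal(size=rng.integers(2, 9))
            mean = sum(preds) / len(preds)
            oracle = (sum((p - mean) ** 2 for p in preds) / (len(preds) - 1)) ** 0.5
            assert ensemble.ensemble_sd(preds) == pytest.approx(oracle, abs=1e-12)

    def test_single_prediction_rejected(self):
        with pytest.raises(ValueError):
            ensemble.ensemble_sd([1.0])


class TestADThreshold:
    def test_three_times_max(self):
        assert ensemble.compute_ad_threshold([0.1, 0.23, 0.05]) == pytest.approx(0.69)
        assert ensemble.compute_ad_threshold([0.1]) == pytest.approx(0.3)

    def test_degenerate_all_zero(self):
        assert ensemble.compute_ad_threshold([0.0, 0.0]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble.compute_ad_threshold([])


class TestBaseCorrelation:
    def test_identical_and_anticorrelated(self):
        a = np.array([0.1, 0.2, 0.3, 0.15, 0.25])
        assert ensemble.base_prediction_correlation(a, a) == pytest.approx(1.0)
        assert ensemble.base_prediction_correlation(a, -a) == pytest.approx(-1.0)

    def test_independent_fold_errors_weakly_correlated(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0.1, 0.3, 60), rng.uniform(0.1, 0.3, 60)
        assert abs(ensemble.base_prediction_correlation(a, b)) < 0.35

    def test_mismatched_plans_rejected(self):
        with pytest.raises(ValueError):
            ensemble.base_prediction_correlation(np.ones(5), np.ones(6))


@pytest.fixture(scope="module")
def fitted(small_synthetic_module, fast_specs_module):
    table, y = small_synthetic_module
    specs, meta = fast_specs_module
    est = ensemble.StackedEnsembleRegressor(
        base_specs=specs, meta_spec=meta, random_state=0
    )
    est.fit(table.data.iloc[:110], y[:110])
    return est, table, y


@pytest.fixture(scope="module")
def small_synthetic_module():
    spec = SyntheticSpec(
        n_molecules=150, n_descriptors=30, n_informative=5, n_constant=0,
        correlated_block_size=6, noise_sd=0.15, seed=11,
    )
    table, y, _ = generate_descriptor_dataset(spec)
    return table, y


@pytest.fixture(scope="module")
def fast_specs_module():
    cfg = RpropConfig(max_steps=1500)
    return (
        [ensemble.BaseLearnerSpec("A", (8, 4), cfg), ensemble.BaseLearnerSpec("B", (12, 6), cfg)],
        ensemble.BaseLearnerSpec("M", (2, 1), cfg),
    )


class TestStackedEnsemble:
    def test_training_set_sd_within_threshold_by_construction(self, fitted):
        est, _, _ = fitted
        assert (est.train_sds_ <= est.ad_threshold_ + 1e-12).all()
        assert est.ad_threshold_ == pytest.approx(3 * est.train_sds_.max())

    def test_train_fit_quality(self, fitted):
        est, table, y = fitted
        pred = est.predict(table.data.iloc[:110])
        assert metrics.r_squared(y[:110], pred) > 0.9

    def test_predict_deterministic_for_duplicates(self, fitted):
        est, table, _ = fitted
        row = table.data.iloc[[0, 0]]
        recs = est.predict_with_ad(row, ids=["a", "b"])
        assert recs[0].predicted_log_pe == recs[1].predicted_log_pe
        assert recs[0].sd == recs[1].sd

    def test_prediction_records_consistent(self, fitted):
        est, table, _ = fitted
        recs = est.predict_with_ad(table.data.iloc[110:])
        for r in recs:
            assert r.inside_domain == (r.sd <= est.ad_threshold_)
            assert r.permeability_class == ("higher" if r.predicted_log_pe >= -6.2 else "lower")

    def test_out_of_distribution_probes_flagged_more_often(self, fitted):
        est, table, y = fitted
        rng = np.random.default_rng(5)
        cols = table.data.columns
        in_dist = pd.DataFrame(
            table.data.iloc[:110].to_numpy() + 0.05 * rng.normal(size=(110, len(cols))),
            columns=cols,
        )
        # descriptors far outside the training range
        out_dist = pd.DataFrame(
            rng.normal(loc=8.0, scale=2.0, size=(100, len(cols))), columns=cols
        )
        frac_in = np.mean([not r.inside_domain for r in est.predict_with_ad(in_dist)])
        frac_out = np.mean([not r.inside_domain for r in est.predict_with_ad(out_dist)])
        assert frac_out > frac_in

    def test_manifest_mismatch_rejected(self, fitted):
        est, table, _ = fitted
        bad = table.data.rename(columns={table.data.columns[0]: "renamed"})
        with pytest.raises(ValueError, match="manifest"):
            est.predict(bad)

    def test_degenerate_stack_tracks_identical_bases(self, fast_specs_module):
        # two identical base specs -> identical meta inputs; the stack should
        # track either base closely on the training data
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, size=(80, 4))
        y = -6.2 + X @ [1.0, -0.5, 0.8, 0.0] + 0.05 * rng.normal(size=80)
        cfg = RpropConfig(max_steps=1500, seed=42)  # pinned init: truly identical bases
        spec = ensemble.BaseLearnerSpec("A", (6,), cfg)
        est = ensemble.StackedEnsembleRegressor(
            base_specs=[spec, spec],
            meta_spec=ensemble.BaseLearnerSpec("M", (2, 1), RpropConfig(max_steps=1500)),
            random_state=0,
        ).fit(X, y)
        base = est._base_predict_raw(est._Xs_train_)
        assert np.allclose(base[:, 0], base[:, 1])
        assert (est.train_sds_ == 0).all()
        assert metrics.rmse(y, est.predict(X)) <= metrics.rmse(y, base[:, 0]) + 0.05

    def test_stacking_dominance_over_seeds(self, small_synthetic_module, fast_specs_module):
        # median ensemble holdout RMSE should not exceed the worse base model's
        table, y = small_synthetic_module
        specs, meta = fast_specs_module
        Xtr, ytr = table.data.iloc[:110], y[:110]
        Xte, yte = table.data.iloc[110:], y[110:]
        ens_rmse, worse_rmse = [], []
        for seed in range(20):
            est = ensemble.StackedEnsembleRegressor(
                base_specs=specs, meta_spec=meta, random_state=seed
            ).fit(Xtr, ytr)
            ens_rmse.append(metrics.rmse(yte, est.predict(Xte)))
            base = est._base_predict_raw(est._prepare_new(Xte))
            worse_rmse.append(max(metrics.rmse(yte, base[:, k]) for k in range(2)))
        assert np.median(ens_rmse) <= np.median(worse_rmse)

    def test_out_of_fold_mode_fits_and_roundtrips(self, small_synthetic_module, fast_specs_module):
        table, y = small_synthetic_module
        specs, meta = fast_specs_module
        est = ensemble.StackedEnsembleRegressor(
            base_specs=specs, meta_spec=meta, meta_feature_mode="out_of_fold",
            cv=CVPlan(k=5, repeats=1, seed=0), random_state=0,
        ).fit(table.data.iloc[:100], y[:100])
        assert est.meta_feature_mode == "out_of_fold"
        d = est.to_dict()
        assert ensemble.StackedEnsembleRegressor.from_dict(d).meta_feature_mode == "out_of_fold"

    def test_save_load_bit_exact(self, fitted, tmp_path):
        est, table, _ = fitted
        path = tmp_path / "model.json"
        ensemble.save_model(est, path)
        restored = ensemble.load_model(path)
        X_new = table.data.iloc[110:]
        assert np.array_equal(est.predict(X_new), restored.predict(X_new))
        assert restored.ad_threshold_ == est.ad_threshold_

    def test_truncated_model_file_rejected(self, fitted, tmp_path):
        est, _, _ = fitted
        path = tmp_path / "model.json"
        ensemble.save_model(est, path)
        path.write_text(path.read_text()[: len(path.read_text()) // 2])
        with pytest.raises(ValueError, match="corrupt"):
            ensemble.load_model(path)


class TestCVEvaluateBase:
    def test_recovers_clean_linear_signal(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, size=(90, 3))
        y = X @ [0.6, -0.4, 0.3] + 0.2
        spec = ensemble.BaseLearnerSpec("A", (6,), RpropConfig(max_steps=1500))
        m, fold_rmse = ensemble.cv_evaluate_base(
            spec, X, y, CVPlan(k=5, repeats=1, seed=0), random_state=0
        )
        assert m.context == "cv"
        assert m.r2 >= 0.95
        assert len(fold_rmse) == 5

    def test_pure_noise_target_scores_near_zero(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1, size=(80, 5))
        y = rng.normal(size=80)
        spec = ensemble.BaseLearnerSpec("A", (4,), RpropConfig(max_steps=600))
        m, _ = ensemble.cv_evaluate_base(
            spec, X, y, CVPlan(k=4, repeats=1, seed=0), random_state=0
        )
        assert m.r2 <= 0.1


class TestLinearBaseline:
    def test_exact_linear_target_resubstitution_r2_one(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 3))
        y = X @ [2.0, -1.0, 0.5] + 3.0
        _, m = ensemble.fit_linear_baseline(X, y, CVPlan(k=4, repeats=1, seed=0))
        assert m["resubstitution"].r2 == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_design_coefficients_recovered(self):
        # +-1 orthogonal design: OLS equals the true coefficients exactly
        X = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]] * 3, dtype=float)
        y = X @ [1.7, -0.3] + 0.9
        model, _ = ensemble.fit_linear_baseline(X, y, CVPlan(k=3, repeats=1, seed=0))
        assert model.coef_ == pytest.approx([1.7, -0.3], abs=1e-10)
        assert model.intercept_ == pytest.approx(0.9, abs=1e-10)

    def test_pure_noise_cv_r2_near_zero(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(100, 6))
        y = rng.normal(size=100)
        _, m = ensemble.fit_linear_baseline(X, y, CVPlan(k=5, repeats=2, seed=0))
        assert m["cv"].r2 <= 0.1

    def test_holdout_context_present_when_supplied(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(50, 2))
        y = X @ [1.0, 1.0]
        _, m = ensemble.fit_linear_baseline(
            X[:40], y[:40], CVPlan(k=4, repeats=1, seed=0), X[40:], y[40:]
        )
        assert m["holdout"].context == "holdout"

    def test_rank_deficient_rejected(self):
        X = np.ones((20, 2))
        X[:, 1] = 2 * X[:, 0]
        with pytest.raises(ValueError):
            ensemble.fit_linear_baseline(X, np.arange(20.0), CVPlan(k=3, repeats=1, seed=0))


class TestSurrogateTree:
    def test_binary_descriptor_perfect_split(self):
        X = pd.DataFrame({"flag": [0.0] * 10 + [1.0] * 10, "junk": np.zeros(20)})
        y = np.array([-7.0] * 10 + [-5.0] * 10)
        tree, _, report = ensemble.surrogate_tree(X, y, min_samples_leaf=2)
        assert len(report) == 2
        assert report["n"].sum() == 20
        assert set(report["permeability_class"]) == {"higher", "lower"}

    def test_leaf_counts_partition_dataset(self, small_synthetic_module):
        table, y = small_synthetic_module
        _, _, report = ensemble.surrogate_tree(table, y)
        assert report["n"].sum() == len(y)
        assert report["pct"].sum() == pytest.approx(100.0)

    def test_root_split_is_planted_dominant_descriptor(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(200, 8)), columns=[f"d{i}" for i in range(8)])
        y = np.where(X["d3"] > 0, -5.0, -7.0) + 0.1 * rng.normal(size=200)
        _, _, report = ensemble.surrogate_tree(X, y)
        assert report.attrs["root_feature"] == "d3"

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError):
            ensemble.surrogate_tree(np.random.default_rng(0).normal(size=(10, 2)), np.ones(10))
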