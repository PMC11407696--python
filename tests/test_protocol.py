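"""Cross-validation protocol, hyperparameter search, importance, persistence."""

import numpy as np
import pytest

from memddg.curation import Mutation
from memddg.features import FeatureSetId, make_feature_spec
from memddg.protocol import (
    CVConfig,
    cross_validate,
    feature_importance,
    fit_final,
    hyperparameter_search,
    kfold_split,
    pearson_cc,
    predict_ddg,
    repeated_cv,
)
from memddg.synthetic import PlantedDatasetSpec, planted_dataset


def linear_problem(rng, n=200, p=10, noise=0.0):
    X = rng.normal(size=(n, p))
    y = 3.0 * X[:, 0] + noise * rng.normal(size=n)
    return X, y


class TestKFold:
    def test_equal_fold_sizes(self):
        folds = kfold_split(10, 5, seed=0)
        assert sorted(len(f) for f in folds) == [2, 2, 2, 2, 2]

    def test_partition_property(self):
        folds = kfold_split(23, 4, seed=1)
        joined = np.concatenate(folds)
        assert sorted(joined) == list(range(23))
        sizes = sorted(len(f) for f in folds)
        assert sizes[-1] - sizes[0] <= 1

    def test_same_seed_same_split(self):
        f1 = kfold_split(50, 5, seed=9)
        f2 = kfold_split(50, 5, seed=9)
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(3, 5, seed=0)


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=50)
        assert pearson_cc(x, x) == pytest.approx(1.0)
        assert pearson_cc(x, -x) == pytest.approx(-1.0)

    def test_affine_invariance(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        base = pearson_cc(x, y)
        assert pearson_cc(2.5 * x + 1.0, y) == pytest.approx(base, abs=1e-12)
        assert pearson_cc(x, 0.1 * y - 7.0) == pytest.approx(base, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            pearson_cc(np.ones(10), np.arange(10.0))


class TestCrossValidate:
    def test_learns_noiseless_linear_signal(self, rng, fast_hp):
        X, y = linear_problem(rng, n=200)
        result = cross_validate(X, y, fast_hp, CVConfig(k=5, seed=3))
        assert result.pcc >= 0.99

    def test_null_target_gives_no_correlation(self, rng, fast_hp):
        X, y = linear_problem(rng, n=500)
        y_null = rng.permutation(y)
        result = cross_validate(X, y_null, fast_hp, CVConfig(k=5, seed=4))
        assert abs(result.pcc) < 0.2

    def test_every_sample_predicted_once(self, rng, fast_hp):
        X, y = linear_problem(rng, n=60)
        result = cross_validate(X, y, fast_hp, CVConfig(k=5, seed=5))
        assert result.predictions.shape == (60,)
        assert not np.any(np.isnan(result.predictions))
        joined = np.concatenate(result.fold_indices)
        assert sorted(joined) == list(range(60))

    def test_rmse_matches_brute_force(self, rng, fast_hp):
        X, y = linear_problem(rng, n=80)
        result = cross_validate(X, y, fast_hp, CVConfig(k=4, seed=6))
        brute = np.sqrt(np.mean((result.y_true - result.predictions) ** 2))
        assert result.rmse == pytest.approx(brute, abs=1e-12)

    def test_constant_target_rejected(self, fast_hp):
        with pytest.raises(ValueError, match="constant"):
            cross_validate(np.random.default_rng(0).normal(size=(20, 3)),
                           np.ones(20), fast_hp, CVConfig(k=4, seed=0))


class TestSearch:
    def test_single_point_space_returned(self, rng, fast_hp):
        X, y = linear_problem(rng, n=60)
        space = {name: [value] for name, value in fast_hp.items()}
        hp, _ = hyperparameter_search(X, y, space, CVConfig(k=3, n_search_iters=3, seed=1))
        assert hp == fast_hp

    def test_same_seed_same_winner(self, rng, fast_hp):
        X, y = linear_problem(rng, n=60)
        space = dict(fast_hp, max_depth=[2, 3, 4], n_estimators=[30, 60])
        space = {k: v if isinstance(v, list) else [v] for k, v in space.items()}
        cfg = CVConfig(k=3, n_search_iters=4, seed=7)
        hp1, r1 = hyperparameter_search(X, y, space, cfg)
        hp2, r2 = hyperparameter_search(X, y, space, cfg)
        assert hp1 == hp2 and r1.pcc == r2.pcc

    def test_winner_is_argmax_over_space(self, rng, fast_hp):
        """With enough draws over a two-point grid the winner's PCC equals the
        exhaustive maximum under the same fold seed."""
        X, y = linear_problem(rng, n=60, noise=1.0)
        space = {k: v if isinstance(v, list) else [v]
                 for k, v in dict(fast_hp, max_depth=[1, 3]).items()}
        cfg = CVConfig(k=3, n_search_iters=10, seed=2)
        _, best = hyperparameter_search(X, y, space, cfg)
        exhaustive = max(
            cross_validate(X, y, dict(fast_hp, max_depth=d), cfg).pcc for d in (1, 3)
        )
        assert best.pcc == pytest.approx(exhaustive, abs=1e-12)


class TestRepeatedCV:
    def test_best_run_at_least_mean(self, rng, fast_hp):
        X, y = linear_problem(rng, n=80, noise=0.5)
        mean_pcc, sd_pcc, best = repeated_cv(X, y, fast_hp, CVConfig(k=4, n_eval_iters=3, seed=8))
        assert best.pcc >= mean_pcc - 1e-12
        assert sd_pcc >= 0.0

    def test_deterministic_under_seed(self, rng, fast_hp):
        X, y = linear_problem(rng, n=60, noise=0.5)
        cfg = CVConfig(k=3, n_eval_iters=2, seed=10)
        out1 = repeated_cv(X, y, fast_hp, cfg)
        out2 = repeated_cv(X, y, fast_hp, cfg)
        assert out1[0] == out2[0] and out1[1] == out2[1]


class TestImportance:
    def test_normalized_to_unit_sum_and_planted_recovery(self, rng, fast_hp):
        n, p = 150, 10
        X = rng.normal(size=(n, p))
        y = 2.0 * X[:, 1] + 1.5 * X[:, 4]
        names = [f"f{i}" for i in range(p)]
        ranked, rollup = feature_importance(
            X, y, fast_hp, n_repeats=2, k=3, seed=3, feature_names=names,
            groups={"f1": "signal", "f4": "signal"},
        )
        total = sum(imp for _, imp in ranked)
        assert total == pytest.approx(1.0, abs=1e-9)
        top2 = {name for name, _ in ranked[:2]}
        assert top2 == {"f1", "f4"}
        assert rollup["signal"] >= 0.8

    def test_constant_feature_gets_zero(self, rng, fast_hp):
        X = rng.normal(size=(100, 5))
        X[:, 3] = 1.0
        y = X[:, 0].copy()
        ranked, _ = feature_importance(X, y, fast_hp, n_repeats=1, k=3, seed=4)
        imp = dict(ranked)
        assert imp["f3"] == 0.0


class TestFinalModelAndPrediction:
    def test_save_load_round_trip(self, tmp_path, planted_small, fast_hp):
        ds = planted_small
        spec = make_feature_spec(FeatureSetId.ONLY_10_PLUS)
        model = fit_final(ds.X, ds.y, fast_hp, spec, seed=1)
        in_memory = model.predict_matrix(ds.X)
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = type(model).load(path)
        assert np.array_equal(loaded.predict_matrix(ds.X), in_memory)

    def test_refit_same_seed_identical(self, planted_small, fast_hp):
        ds = planted_small
        m1 = fit_final(ds.X, ds.y, fast_hp, seed=2)
        m2 = fit_final(ds.X, ds.y, fast_hp, seed=2)
        assert np.array_equal(m1.predict_matrix(ds.X), m2.predict_matrix(ds.X))

    def test_wrong_width_rejected(self, planted_small, fast_hp):
        ds = planted_small
        model = fit_final(ds.X, ds.y, fast_hp, seed=3)
        with pytest.raises(ValueError):
            model.predict_matrix(ds.X[:, :50])

    def test_spec_mismatch_rejected(self, planted_small, fast_hp):
        from memddg.features import FeatureSetSpec

        ds = planted_small
        model = fit_final(ds.X, ds.y, fast_hp, seed=3)
        base = make_feature_spec(FeatureSetId.ONLY_10_PLUS)
        other = FeatureSetSpec(set_id=base.set_id, names=tuple(reversed(base.names)))
        with pytest.raises(ValueError, match="mismatch"):
            model.predict_matrix(ds.X, spec=other)

    def test_predict_single_mutation_deterministic(self, planted_small, fast_hp):
        ds = planted_small
        model = fit_final(ds.X, ds.y, fast_hp, seed=4)
        rec = ds.records[0]
        mut_id, int_id = rec.partner_a_id, rec.partner_b_id
        args = (
            model,
            ds.sequences[int_id],
            ds.sequences[mut_id],
            rec.mutation,
            (ds.pssms[mut_id], ds.pssms[int_id]),
        )
        assert predict_ddg(*args) == predict_ddg(*args)

    def test_predict_rejects_wt_mismatch(self, planted_small, fast_hp):
        ds = planted_small
        model = fit_final(ds.X, ds.y, fast_hp, seed=4)
        rec = ds.records[0]
        mut_id, int_id = rec.partner_a_id, rec.partner_b_id
        seq = ds.sequences[mut_id]
        wrong = "C" if seq[rec.mutation.position - 1] != "C" else "D"
        bad = Mutation(wrong, rec.mutation.position, rec.mutation.mut_aa)
        with pytest.raises(ValueError, match="mismatch"):
            predict_ddg(model, ds.sequences[int_id], seq, bad,
                        (ds.pssms[mut_id], ds.pssms[int_id]))
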