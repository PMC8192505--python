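import numpy as np
import pytest

from agbt.downstream import (
    CONSENSUS_SEEDS,
    ConsensusEnsemble,
    ModelSpec,
    consensus_predict,
    evaluate,
    split_random,
    split_scaffold,
    train_consensus,
    train_model,
)

RING_SCAFFOLDS = ["c1ccccc1", "c1ccncc1", "C1CCCCC1", "C1CCCC1", "C1CCNCC1",
                  "c1ccsc1", "C1CCOC1", "c1ccoc1", "C1CCNC1", "c1cncnc1"]


class TestSplits:
    def test_random_811_sizes(self):
        plan = split_random([f"m{i}" for i in range(100)], seed=0)
        assert (len(plan.train), len(plan.validation), len(plan.test)) == (80, 10, 10)

    def test_random_deterministic(self):
        ids = [f"m{i}" for i in range(50)]
        assert split_random(ids, 3).test == split_random(ids, 3).test

    def test_ten_seeds_distinct_test_sets(self):
        ids = [f"m{i}" for i in range(100)]
        tests = [frozenset(split_random(ids, s).test) for s in range(10)]
        assert len(set(tests)) == 10

    def test_too_few_molecules(self):
        with pytest.raises(ValueError):
            split_random(["a", "b"], 0)

    def test_scaffold_groups_never_straddle(self):
        ids = [f"m{i}" for i in range(100)]
        smiles = [RING_SCAFFOLDS[i % 10] for i in range(100)]
        plan = split_scaffold(ids, smiles)
        by_scaffold = {}
        for mol_id, smi in zip(ids, smiles):
            by_scaffold.setdefault(smi, set()).add(mol_id)
        partitions = [set(plan.train), set(plan.validation), set(plan.test)]
        for members in by_scaffold.values():
            assert sum(bool(members & p) for p in partitions) == 1

    def test_scaffold_equal_groups_8_1_1(self):
        ids = [f"m{i}" for i in range(100)]
        smiles = [RING_SCAFFOLDS[i % 10] for i in range(100)]
        plan = split_scaffold(ids, smiles)
        assert (len(plan.train), len(plan.validation), len(plan.test)) == (80, 10, 10)

    def test_single_scaffold_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            split_scaffold(["a", "b", "c"], ["c1ccccc1"] * 3)

    def test_unparsable_smiles(self):
        with pytest.raises(ValueError, match="bad"):
            split_scaffold(["bad"], ["not_a_smiles"])


@pytest.fixture(scope="module")
def linear_data():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(500, 20))
    y = 3.0 * X[:, 0] + rng.normal(0, 0.01, 500)
    return X, y


FAST_NN = {"hidden": (128, 64), "epochs": 200, "dropout": 0.0, "lr": 3e-3, "patience": 30}


class TestModels:
    def test_stdnn_recovers_linear_signal(self, linear_data):
        X, y = linear_data
        spec = ModelSpec("stdnn", tasks=["y"], hyperparameters=FAST_NN)
        model = train_model(spec, X[:400], {"y": y[:400]})
        report = evaluate(model.predict(X[400:])["y"], y[400:], "regression")
        assert report.r_squared >= 0.95

    def test_mtdnn_matches_stdnn_on_duplicated_task(self, linear_data):
        X, y = linear_data
        st = ModelSpec("stdnn", tasks=["a"], hyperparameters=FAST_NN)
        mt = ModelSpec("mtdnn", tasks=["a", "b"], hyperparameters=FAST_NN)
        r_st = evaluate(train_model(st, X[:400], {"a": y[:400]}).predict(X[400:])["a"],
                        y[400:], "regression").r_squared
        r_mt = evaluate(train_model(mt, X[:400], {"a": y[:400], "b": y[:400]})
                        .predict(X[400:])["a"], y[400:], "regression").r_squared
        assert abs(r_st - r_mt) <= 0.05

    def test_mtdnn_requires_two_tasks(self):
        with pytest.raises(ValueError):
            ModelSpec("mtdnn", tasks=["only"])

    def test_gbdt_separable_classification(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-3, 0.3, size=(50, 4)), rng.normal(3, 0.3, size=(50, 4))])
        y = np.array([0.0] * 50 + [1.0] * 50)
        spec = ModelSpec("gbdt", tasks=["c"], task_types={"c": "classification"},
                         hyperparameters={"n_estimators": 50})
        model = train_model(spec, X, {"c": y})
        proba = model.predict(X)["c"]
        assert np.mean((proba >= 0.5) == y.astype(bool)) == 1.0

    def test_nan_features_rejected(self, linear_data):
        X, y = linear_data
        X = X.copy()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            train_model(ModelSpec("rf", tasks=["y"],
                                  hyperparameters={"n_estimators": 10}), X, {"y": y})

    def test_deterministic_given_seed(self, linear_data):
        X, y = linear_data
        spec = ModelSpec("gbdt", tasks=["y"], hyperparameters={"n_estimators": 20}, seed=5)
        p1 = train_model(spec, X[:100], {"y": y[:100]}).predict(X[100:120])["y"]
        p2 = train_model(spec, X[:100], {"y": y[:100]}).predict(X[100:120])["y"]
        np.testing.assert_array_equal(p1, p2)

    def test_mtdnn_missing_labels_masked(self, linear_data):
        X, y = linear_data
        mask_a = np.ones(400, dtype=bool)
        mask_b = np.zeros(400, dtype=bool)
        mask_b[:200] = True
        spec = ModelSpec("mtdnn", tasks=["a", "b"], hyperparameters=FAST_NN)
        model = train_model(spec, X[:400], {"a": y[:400], "b": y[:400]},
                            label_masks={"a": mask_a, "b": mask_b})
        report = evaluate(model.predict(X[400:])["a"], y[400:], "regression")
        assert report.r_squared >= 0.9


class TestConsensus:
    def test_mean_of_member_predictions(self, linear_data):
        X, y = linear_data

        class Stub:
            def __init__(self, value):
                self.value = value
                self.spec = ModelSpec("rf", tasks=["y"])

            def predict(self, X):
                return {"y": np.full(len(X), self.value)}

        ensemble = ConsensusEnsemble([Stub(1.0), Stub(2.0), Stub(3.0)])
        np.testing.assert_allclose(consensus_predict(ensemble, X[:4])["y"], 2.0)

    def test_identical_members_equal_single_member(self, linear_data):
        X, y = linear_data
        spec = ModelSpec("rf", tasks=["y"], hyperparameters={"n_estimators": 10})
        ensemble = train_consensus(spec, X[:100], {"y": y[:100]}, seeds=[3, 3, 3])
        single = ensemble.members[0].predict(X[100:120])["y"]
        np.testing.assert_allclose(consensus_predict(ensemble, X[100:120])["y"],
                                   single, rtol=1e-12)

    def test_default_protocol_is_20_seeds(self):
        assert CONSENSUS_SEEDS == tuple(range(20))

    def test_consensus_rmse_not_worse_than_worst_member(self, linear_data):
        X, y = linear_data
        spec = ModelSpec("gbdt", tasks=["y"], hyperparameters={"n_estimators": 20})
        ensemble = train_consensus(spec, X[:200], {"y": y[:200]}, seeds=range(5))
        member_rmse = [evaluate(m.predict(X[200:300])["y"], y[200:300],
                                "regression").rmse for m in ensemble.members]
        consensus_rmse = evaluate(consensus_predict(ensemble, X[200:300])["y"],
                                  y[200:300], "regression").rmse
        assert consensus_rmse <= max(member_rmse) + 1e-12


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        report = evaluate(y, y, "regression")
        assert report.r_squared == pytest.approx(1.0)
        assert report.rmse == 0.0 and report.mae == 0.0

    def test_constant_shift_preserves_squared_pearson(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        report = evaluate(y + 1.0, y, "regression")
        assert report.r_squared == pytest.approx(1.0)
        assert report.rmse == pytest.approx(1.0)
        assert report.mae == pytest.approx(1.0)
        assert report.extras["coefficient_of_determination"] < 1.0

    def test_positive_affine_invariance_of_r2_not_rmse(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        pred = y + rng.normal(0, 0.1, 50)
        base = evaluate(pred, y, "regression")
        scaled = evaluate(2.0 * pred + 5.0, y, "regression")
        assert scaled.r_squared == pytest.approx(base.r_squared)
        assert scaled.rmse > base.rmse

    def test_perfect_classifier(self):
        truth = np.array([0, 0, 1, 1], dtype=float)
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        report = evaluate(scores, truth, "classification")
        assert report.auc_roc == 1.0 and report.accuracy == 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.ones(5), np.arange(5, dtype=float), "regression")
        with pytest.raises(ValueError):
            evaluate(np.arange(5, dtype=float), np.ones(5), "regression")
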