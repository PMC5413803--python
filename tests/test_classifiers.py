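"""SVM / RBFN / RF contracts: scores, decisions, invariants, serialization."""

import numpy as np
import pytest

import pdtkit as pk
from pdtkit.classifiers import _LoadedRF, polynomial_kernel
from pdtkit.errors import ContractError, ParameterError, TrainingError
from tests.conftest import make_gaussian_dataset


def tiny_dataset(X, y, names=None):
    X = np.asarray(X, float).reshape(len(y), -1)
    return pk.LabeledDataset(
        X=X, y=np.asarray(y, int), feature_names=names or [f"f{j}" for j in range(X.shape[1])]
    )


class TestSVM:
    def test_polynomial_kernel_value(self):
        assert polynomial_kernel([1, 0], [1, 1], degree=2, coef0=1.0) == 4.0

    def test_two_point_separation_degree_one(self):
        data = tiny_dataset([[0.0], [1.0]], [-1, 1])
        model = pk.SVMClassifier(degree=1).fit(data)
        assert list(model.predict(data.X)) == [-1, 1]

    def test_xor_separable_with_degree_two(self):
        data = tiny_dataset([[0, 0], [1, 1], [0, 1], [1, 0]], [-1, -1, 1, 1])
        model = pk.SVMClassifier(degree=2, C=100.0).fit(data)
        assert np.array_equal(model.predict(data.X), data.y)

    def test_dual_constraints_hold(self, blobs):
        model = pk.SVMClassifier(degree=2, C=1.0).fit(blobs)
        assert abs(model.dual_coef_signed.sum()) < 1e-6
        assert np.all(model.alphas >= 0)
        assert np.all(model.alphas <= 1.0 + 1e-9)

    def test_support_vectors_at_margin_hard_fit(self, blobs):
        model = pk.SVMClassifier(degree=1, C=1e6).fit(blobs)
        sv_raw = model.scaler_.mean_ + model.svc_.support_vectors_ * model.scaler_.scale_
        # solver tolerance (libsvm tol=1e-3) leaves margins ~1e-5 off unity
        assert np.all(np.abs(model.decision_score(sv_raw)) >= 1 - 1e-4)

    def test_midpoint_of_symmetric_pair_scores_zero(self):
        data = tiny_dataset([[1.0, 2.0], [-1.0, -2.0]], [1, -1])
        model = pk.SVMClassifier(degree=1).fit(data)
        assert model.decision_score(np.array([[0.0, 0.0]]))[0] == pytest.approx(0.0, abs=1e-9)

    def test_score_continuity(self, blobs):
        model = pk.SVMClassifier().fit(blobs)
        x = blobs.X[:1]
        base = model.decision_score(x)[0]
        for eps in (1e-4, 1e-3):
            shifted = model.decision_score(x + eps)[0]
            assert abs(shifted - base) < 1.0 * eps * 100

    def test_single_class_rejected(self):
        data = tiny_dataset([[0.0], [1.0]], [1, 1])
        with pytest.raises(TrainingError):
            pk.SVMClassifier().fit(data)

    def test_dimension_mismatch(self, blobs):
        model = pk.SVMClassifier().fit(blobs)
        with pytest.raises(ContractError):
            model.decision_score(np.zeros((1, 5)))


def hand_built_rbfn(prototypes, betas, weights, m):
    return pk.RBFNClassifier.from_dict(
        {
            "n_clusters": len(prototypes),
            "seed": 0,
            "scaler": {"mean": [0.0] * m, "scale": [1.0] * m},
            "prototypes": prototypes,
            "betas": betas,
            "weights": weights,
        }
    )


class TestRBFN:
    def test_hand_computed_single_neuron(self):
        # one neuron at mu=0 with beta=1, output weight w=(1,0), no bias:
        # activation at x=1 is exp(-1)
        model = hand_built_rbfn([[0.0]], [1.0], [[1.0, 0.0], [0.0, 0.0]], m=1)
        scores = model.output_scores(np.array([[1.0]]))
        assert scores[0, 0] == pytest.approx(np.exp(-1), abs=1e-12)

    def test_activation_is_one_at_prototype(self):
        model = hand_built_rbfn([[2.0, -1.0]], [0.7], [[1.0, 0.0], [0.0, 0.0]], m=2)
        assert model.activations(np.array([[2.0, -1.0]]))[0, 0] == pytest.approx(1.0)

    def test_far_from_prototypes_scores_approach_bias(self):
        bias = [0.3, 0.6]
        model = hand_built_rbfn([[0.0]], [1.0], [[1.0, -1.0], bias], m=1)
        scores = model.output_scores(np.array([[50.0]]))
        assert np.allclose(scores[0], bias, atol=1e-12)

    def test_neuron_permutation_invariance(self):
        protos = [[0.0, 0.0], [1.0, 2.0], [-1.0, 0.5]]
        betas = [0.5, 1.0, 2.0]
        w = [[0.2, -0.1], [0.4, 0.3], [-0.6, 0.9], [0.1, 0.2]]  # 3 neurons + bias
        perm = [2, 0, 1]
        model_a = hand_built_rbfn(protos, betas, w, m=2)
        model_b = hand_built_rbfn(
            [protos[i] for i in perm], [betas[i] for i in perm], [w[i] for i in perm] + [w[3]], m=2
        )
        X = np.random.default_rng(0).normal(size=(10, 2))
        assert np.allclose(model_a.output_scores(X), model_b.output_scores(X))

    def test_single_class_k1_predicts_that_class_everywhere(self):
        data = tiny_dataset([[0.0], [1.0], [2.0]], [1, 1, 1])
        model = pk.RBFNClassifier(n_clusters=1, seed=0).fit(data)
        probe = np.linspace(-100, 100, 21).reshape(-1, 1)
        assert np.all(model.predict(probe) == 1)

    def test_separated_blobs_training_accuracy(self, blobs):
        model = pk.RBFNClassifier(n_clusters=2, seed=0).fit(blobs)
        assert np.array_equal(model.predict(blobs.X), blobs.y)

    def test_interpolation_with_k_equals_n(self):
        data = make_gaussian_dataset(4, 4, [2.0, 0.0], seed=5)
        model = pk.RBFNClassifier(n_clusters=data.n, seed=0).fit(data)
        assert np.array_equal(model.predict(data.X), data.y)

    def test_k_exceeding_n_rejected(self, blobs):
        with pytest.raises(ParameterError):
            pk.RBFNClassifier(n_clusters=blobs.n + 1).fit(blobs)

    def test_probability_surrogate_monotone_with_score(self, blobs):
        model = pk.RBFNClassifier(n_clusters=2, seed=0).fit(blobs)
        X = np.random.default_rng(1).normal(scale=5, size=(30, 2))
        score = model.decision_score(X)
        proba = model.predict_proba(X)
        order = np.argsort(score)
        assert np.all(np.diff(proba[order]) >= -1e-12)
        assert np.all((proba >= 0) & (proba <= 1))


def leaf_tree(cls_index):
    """A degenerate one-node tree voting for class column ``cls_index``."""
    value = [[1.0, 0.0]] if cls_index == 0 else [[0.0, 1.0]]
    return {
        "children_left": [-1],
        "children_right": [-1],
        "feature": [-2],
        "threshold": [-2.0],
        "value": value,
    }


class TestRF:
    def test_deterministic_given_seed(self, blobs):
        probe = np.random.default_rng(2).normal(size=(20, 2))
        a = pk.RFClassifier(n_trees=50, seed=9).fit(blobs).vote_fraction(probe)
        b = pk.RFClassifier(n_trees=50, seed=9).fit(blobs).vote_fraction(probe)
        assert np.array_equal(a, b)

    def test_unanimous_deep_inside_class(self, blobs):
        model = pk.RFClassifier(n_trees=50, seed=0).fit(blobs)
        deep = np.array([[10.0, 10.0]])
        assert model.vote_fraction(deep)[0] == 1.0

    def test_vote_fraction_equals_tree_votes(self, blobs):
        model = pk.RFClassifier(n_trees=25, seed=4).fit(blobs)
        probe = np.random.default_rng(3).normal(scale=6, size=(15, 2))
        votes = np.mean(
            [est.predict(probe) == 1 for est in model.forest_.estimators_], axis=0
        )
        assert np.allclose(model.vote_fraction(probe), votes)

    def test_three_trees_two_positive_votes(self):
        forest = _LoadedRF(
            {
                "n_features": 1,
                "classes": [-1, 1],
                "trees": [leaf_tree(1), leaf_tree(1), leaf_tree(0)],
            }
        )
        assert forest.vote_fraction(np.array([[0.0]]))[0] == pytest.approx(2 / 3)

    def test_zero_positive_votes(self):
        forest = _LoadedRF(
            {"n_features": 1, "classes": [-1, 1], "trees": [leaf_tree(0)] * 4}
        )
        assert forest.vote_fraction(np.array([[0.0]]))[0] == 0.0

    def test_exact_tie_goes_to_control(self):
        forest = _LoadedRF(
            {"n_features": 1, "classes": [-1, 1], "trees": [leaf_tree(0), leaf_tree(1)]}
        )
        assert forest.predict(np.array([[0.0]]))[0] == -1

    def test_probability_bounds(self, blobs):
        model = pk.RFClassifier(n_trees=30, seed=1).fit(blobs)
        X = np.random.default_rng(5).normal(scale=20, size=(50, 2))
        p = model.vote_fraction(X)
        assert np.all((p >= 0) & (p <= 1))

    def test_invalid_tree_count(self):
        with pytest.raises(ParameterError):
            pk.RFClassifier(n_trees=0)


class TestSerialization:
    @pytest.mark.parametrize("family", ["svm", "rbfn", "rf"])
    def test_save_load_round_trip(self, family, blobs, tmp_path):
        spec = pk.ClassifierSpec(family, n_trees=25, seed=2)
        model = spec.make()
        model.fit(blobs)
        path = tmp_path / f"{family}.json"
        pk.save_model(model, path)
        loaded = pk.load_model(path)
        probe = np.random.default_rng(8).normal(scale=6, size=(20, 2))
        assert np.array_equal(loaded.predict(probe), model.predict(probe))
        if family != "rf":
            assert np.allclose(loaded.decision_score(probe), model.decision_score(probe), atol=1e-8)
        else:
            assert np.allclose(loaded.vote_fraction(probe), model.vote_fraction(probe))


class TestSpecFactory:
    def test_unknown_family_rejected(self):
        with pytest.raises(ParameterError):
            pk.ClassifierSpec("mlp")

    @pytest.mark.parametrize(
        "family,cls",
        [("svm", pk.SVMClassifier), ("rbfn", pk.RBFNClassifier), ("rf", pk.RFClassifier)],
    )
    def test_factory_types(self, family, cls):
        assert isinstance(pk.ClassifierSpec(family).make(), cls)
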