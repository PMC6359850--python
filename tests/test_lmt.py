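import numpy as np
import pytest

import gaitphase as gp
from gaitphase.lmt import LMTModel, LMTNode, predict_batch
from gaitphase.preprocess import InputError

from oracles import best_split_loop


def _leaf_model(gamma, class_order=gp.PHASE_ORDER):
    leaf = LMTNode()
    leaf.gamma = np.asarray(gamma, dtype=float)
    return LMTModel(root=leaf, class_order=class_order)


class TestDegenerateInduction:
    def test_single_class_gives_single_leaf_predicting_it(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        y = np.array(["Swing"] * 30, dtype=object)
        model = gp.train_lmt(X, y)
        assert model.tree_size == 1 and model.n_leaves == 1
        p = gp.leaf_probabilities(model, X[0])
        assert gp.predict_phase(model, X[0]) == "Swing"
        assert p[gp.PHASE_ORDER.index("Swing")] == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            gp.train_lmt(np.zeros((0, 4)), np.array([], dtype=object))

    def test_forced_single_leaf_equals_standalone_logitboost(self, separable_toy):
        X, y = separable_toy
        cfg = gp.LMTTrainConfig(
            min_instances=10 * len(y), num_boosting_iterations=25, prune=False
        )
        model = gp.train_lmt(X, y, config=cfg)
        assert model.tree_size == 1
        codes = np.array([gp.PHASE_ORDER.index(lab) for lab in y])
        gamma, _ = gp.fit_logitboost(X, codes, len(gp.PHASE_ORDER), 25)
        np.testing.assert_allclose(model.root.gamma, gamma, rtol=1e-10)


class TestSeparableToy:
    def test_root_split_matches_exhaustive_oracle(self, separable_toy):
        X, y = separable_toy
        cfg = gp.LMTTrainConfig(num_boosting_iterations=10, prune=False, seed=0)
        model = gp.train_lmt(X, y, config=cfg)
        oracle_f, oracle_thr, _ = best_split_loop(X.tolist(), list(y))
        assert oracle_f == 0  # the separating axis
        assert model.root.feature == oracle_f
        assert 1.0 < model.root.threshold < 2.0
        assert model.root.threshold == pytest.approx(oracle_thr)

    def test_training_accuracy_is_perfect(self, separable_toy):
        X, y = separable_toy
        model = gp.train_lmt(X, y, config=gp.LMTTrainConfig(num_boosting_iterations=10))
        assert (predict_batch(model, X) == y).mean() == 1.0

    def test_predictions_match_threshold_rule(self, separable_toy):
        X, y = separable_toy
        model = gp.train_lmt(X, y, config=gp.LMTTrainConfig(num_boosting_iterations=10))
        rule = np.where(X[:, 0] <= 1.5, "LR", "PO")
        assert (predict_batch(model, X) == rule).all()


class TestLogitBoost:
    def test_objective_non_increasing(self, separable_toy):
        X, y = separable_toy
        codes = np.array([gp.PHASE_ORDER.index(lab) for lab in y])
        _, nll_path = gp.fit_logitboost(X, codes, 4, 40)
        assert len(nll_path) >= 5
        assert all(b <= a + 1e-8 for a, b in zip(nll_path, nll_path[1:]))

    def test_objective_non_increasing_on_cohort(self, small_cohort_df):
        X = small_cohort_df[list(gp.FEATURE_NAMES)].to_numpy()[:500]
        y = small_cohort_df["label"].to_numpy()[:500]
        codes = np.array([gp.PHASE_ORDER.index(lab) for lab in y])
        _, nll_path = gp.fit_logitboost(X, codes, 4, 30)
        assert all(b <= a + 1e-8 for a, b in zip(nll_path, nll_path[1:]))


class TestProbabilities:
    def test_zero_gamma_leaf_uniform(self):
        model = _leaf_model(np.zeros((4, 21)))
        p = gp.leaf_probabilities(model, np.zeros(20))
        np.testing.assert_allclose(p, 0.25)
        # tie resolves to the first class in class_order
        assert gp.predict_phase(model, np.zeros(20)) == gp.PHASE_ORDER[0]

    def test_binary_form_reduces_to_sigmoid(self):
        # two classes, score gamma for class 0, zero for class 1
        for g in (-2.0, 0.0, 1.5):
            gamma = np.zeros((2, 3))
            gamma[0, 0] = g
            model = _leaf_model(gamma, class_order=("LR", "PO"))
            p = gp.leaf_probabilities(model, np.zeros(2))
            assert p[0] == pytest.approx(np.exp(g) / (1 + np.exp(g)))

    def test_random_gamma_matches_scalar_softmax(self):
        rng = np.random.default_rng(1)
        gamma = rng.normal(size=(4, 21))
        x = rng.normal(size=20)
        model = _leaf_model(gamma)
        p = gp.leaf_probabilities(model, x)
        scores = [g[0] + sum(gi * xi for gi, xi in zip(g[1:], x)) for g in gamma]
        exps = [np.exp(s - max(scores)) for s in scores]
        np.testing.assert_allclose(p, np.array(exps) / sum(exps), rtol=1e-10)

    def test_probabilities_sum_to_one_and_positive(self, tiny_trained_model):
        rng = np.random.default_rng(2)
        for _ in range(200):
            x = rng.normal(0, 30, size=20)
            p = gp.leaf_probabilities(tiny_trained_model, x)
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            assert (p > 0).all()

    def test_argmax_example(self):
        gamma = np.zeros((4, 21))
        gamma[1, 0] = 2.0  # class 2 dominates
        model = _leaf_model(gamma)
        assert gp.predict_phase(model, np.zeros(20)) == gp.PHASE_ORDER[1]

    def test_non_finite_input_rejected(self, tiny_trained_model):
        with pytest.raises(InputError):
            gp.leaf_probabilities(tiny_trained_model, np.r_[np.nan, np.zeros(19)])


class TestTreeStructure:
    def test_child_counts_sum_to_parent(self, tiny_trained_model):
        def walk(node):
            if node.is_leaf:
                return
            assert node.left.n_train + node.right.n_train == node.n_train
            walk(node.left)
            walk(node.right)

        walk(tiny_trained_model.root)
        assert tiny_trained_model.n_leaves <= tiny_trained_model.tree_size

    def test_accepted_splits_have_positive_gain(self, small_cohort_df):
        """Re-run the exhaustive gain oracle at the root split."""
        X = small_cohort_df[list(gp.FEATURE_NAMES)].to_numpy()[:300]
        y = list(small_cohort_df["label"].to_numpy()[:300])
        from gaitphase.lmt import _best_split

        got = _best_split(X, np.array([gp.PHASE_ORDER.index(l) for l in y]), 4)
        want = best_split_loop(X.tolist(), y)
        assert got is not None and want is not None
        f, thr, gain = got
        assert gain > 0
        assert (f, thr) == (want[0], pytest.approx(want[1]))
        assert gain == pytest.approx(want[2])


class TestPruning:
    def test_pruned_cv_error_within_one_se_of_unpruned(self, small_cohort_df):
        cfg = gp.LMTTrainConfig(num_boosting_iterations=10, prune=True, seed=1)
        model = gp.train_lmt(small_cohort_df.iloc[:1200], config=cfg)
        info = model.pruning_info
        if info is None or info.get("cv_error_rates") is None:
            pytest.skip("tree collapsed before pruning was needed")
        rates = info["cv_error_rates"]
        chosen_idx = info["alphas"].index(info["chosen_alpha"])
        assert rates[chosen_idx] <= rates[0] + info["one_se"] + 1e-12


class TestSerialization:
    def test_round_trip_identical_predictions(self, tiny_trained_model):
        doc = gp.serialize_model(tiny_trained_model)
        back = gp.deserialize_model(doc)
        assert back.tree_size == tiny_trained_model.tree_size
        assert back.n_leaves == tiny_trained_model.n_leaves
        rng = np.random.default_rng(3)
        X = rng.normal(0, 30, size=(1000, 20))
        assert (predict_batch(back, X) == predict_batch(tiny_trained_model, X)).all()

    def test_empty_document_rejected(self):
        with pytest.raises(InputError):
            gp.deserialize_model("")

    def test_malformed_document_reports_location(self):
        with pytest.raises(InputError, match="line"):
            gp.deserialize_model("{not json")

    def test_single_leaf_round_trip(self):
        X = np.zeros((20, 4))
        y = np.array(["PO"] * 20, dtype=object)
        model = gp.train_lmt(X, y)
        back = gp.deserialize_model(gp.serialize_model(model))
        assert gp.predict_phase(back, np.ones(4)) == "PO"
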