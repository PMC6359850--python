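import numpy as np
import pytest

import gaitphase as gp
from gaitphase.evaluate import (
    ConfusionMatrix,
    _apply_tsvc_per_recording,
    inject_isolated_outliers,
)
from gaitphase.preprocess import ConfigurationError, InputError

from conftest import make_clean_stream
from oracles import binary_metrics_loop, confusion_loop


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        labels = ["LR", "PO", "Swing", "TSw"] * 5
        cm = gp.confusion(labels, labels)
        assert np.array_equal(cm.counts, np.diag([5, 5, 5, 5]))

    def test_single_instance_off_diagonal(self):
        cm = gp.confusion(["LR"], ["PO"])
        assert cm.counts[0, 1] == 1 and cm.total == 1

    def test_random_pair_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        true = rng.choice(gp.PHASE_ORDER, 100)
        pred = rng.choice(gp.PHASE_ORDER, 100)
        cm = gp.confusion(true, pred)
        assert cm.counts.tolist() == confusion_loop(true, pred, gp.PHASE_ORDER)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            gp.confusion(["LR"], ["LR", "PO"])


class TestPerClassMetrics:
    def test_perfect_matrix_all_ones(self):
        cm = ConfusionMatrix(np.diag([10, 20, 30, 40]))
        rep = gp.per_class_metrics(cm)
        assert rep.accuracy == 1.0
        assert np.allclose(rep.per_class.to_numpy(), 1.0)
        assert all(v == 1.0 for v in rep.weighted.values())

    def test_binary_matrix_matches_scalar_arithmetic(self):
        cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]), class_order=("A", "B"))
        rep = gp.per_class_metrics(cm)
        want = binary_metrics_loop(tp=8, fn=2, fp=1, tn=9)
        for m, v in want.items():
            assert rep.per_class.loc["A", m] == pytest.approx(v)
        assert rep.per_class.loc["A", "mcc"] == pytest.approx(70 / np.sqrt(9900))

    def test_random_matrices_match_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            counts = rng.integers(0, 50, size=(4, 4))
            if counts.sum() == 0:
                continue
            rep = gp.per_class_metrics(ConfusionMatrix(counts))
            for i, cls in enumerate(gp.PHASE_ORDER):
                tp = counts[i, i]
                fn = counts[i].sum() - tp
                fp = counts[:, i].sum() - tp
                tn = counts.sum() - tp - fn - fp
                want = binary_metrics_loop(tp, fn, fp, tn)
                for m, v in want.items():
                    assert rep.per_class.loc[cls, m] == pytest.approx(v), (cls, m)

    def test_zero_predicted_class_flagged_zero_precision(self):
        counts = np.array([[0, 5, 0, 0], [0, 5, 0, 0], [0, 0, 5, 0], [0, 0, 0, 5]])
        rep = gp.per_class_metrics(ConfusionMatrix(counts))
        assert rep.per_class.loc["LR", "precision"] == 0.0
        assert rep.undefined_flags.loc["LR", "precision"]

    def test_tp_tn_fp_fn_partition_total(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 30, size=(4, 4))
        total = counts.sum()
        for i in range(4):
            tp = counts[i, i]
            fn = counts[i].sum() - tp
            fp = counts[:, i].sum() - tp
            tn = total - tp - fn - fp
            assert tp + fn + fp + tn == total

    def test_mcc_near_zero_for_random_predictions(self):
        rng = np.random.default_rng(3)
        true = rng.choice(gp.PHASE_ORDER, 10000)
        pred = rng.choice(gp.PHASE_ORDER, 10000)
        rep = gp.per_class_metrics(gp.confusion(true, pred))
        assert abs(rep.weighted["mcc"]) < 0.05

    def test_weighted_within_per_class_extremes(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 40, size=(4, 4))
        rep = gp.per_class_metrics(ConfusionMatrix(counts))
        for m in rep.weighted:
            col = rep.per_class[m]
            assert col.min() - 1e-12 <= rep.weighted[m] <= col.max() + 1e-12

    def test_empty_matrix_rejected(self):
        with pytest.raises(InputError):
            gp.per_class_metrics(ConfusionMatrix(np.zeros((4, 4), dtype=int)))


class TestWeightedAverage:
    def test_equal_counts_is_mean(self):
        assert gp.weighted_average([0.2, 0.4, 0.6], [7, 7, 7]) == pytest.approx(0.4)

    def test_constant_values_unchanged(self):
        assert gp.weighted_average([0.9] * 4, [1, 10, 100, 3]) == pytest.approx(0.9)

    def test_two_class_example(self):
        assert gp.weighted_average([0.9, 0.5], [90, 10]) == pytest.approx(0.86)

    def test_invariant_to_class_ordering(self):
        vals, cnts = [0.1, 0.5, 0.9], [5, 10, 2]
        perm = [2, 0, 1]
        assert gp.weighted_average(vals, cnts) == pytest.approx(
            gp.weighted_average([vals[i] for i in perm], [cnts[i] for i in perm])
        )

    def test_zero_total_rejected(self):
        with pytest.raises(InputError):
            gp.weighted_average([0.5], [0])


class TestStratifiedKFold:
    def test_balanced_divisible_case(self):
        labels = np.repeat(gp.PHASE_ORDER, 25)
        folds = gp.stratified_kfold(labels, k=5, seed=0)
        for fold in folds:
            vals, counts = np.unique(labels[fold], return_counts=True)
            assert sorted(vals) == sorted(gp.PHASE_ORDER)
            assert (counts == 5).all()

    def test_folds_partition_index_set(self):
        rng = np.random.default_rng(5)
        labels = rng.choice(gp.PHASE_ORDER, 101)
        folds = gp.stratified_kfold(labels, k=5, seed=3)
        pooled = np.concatenate(folds)
        assert sorted(pooled) == list(range(101))

    def test_fixed_seed_reproducible(self):
        labels = np.repeat(gp.PHASE_ORDER, 10)
        a = gp.stratified_kfold(labels, k=5, seed=9)
        b = gp.stratified_kfold(labels, k=5, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_scarce_class_rejected(self):
        labels = ["LR"] * 50 + ["PO"] * 3
        with pytest.raises(ConfigurationError):
            gp.stratified_kfold(labels, k=5)


class TestTsvcInEvaluation:
    def test_tsvc_noop_on_clean_cyclic_stream(self):
        import pandas as pd

        clean = make_clean_stream(4)
        df = pd.DataFrame(
            {"label": clean, "end_index": range(len(clean)), "recording_id": "r"}
        )
        pred = np.asarray(clean, dtype=object)
        corrected = _apply_tsvc_per_recording(df, pred)
        assert list(corrected) == clean

    def test_outlier_injection_improves_with_tsvc(self):
        import pandas as pd

        clean = make_clean_stream(10)
        corrupted = np.asarray(
            inject_isolated_outliers(clean, rate=0.1, seed=1), dtype=object
        )
        df = pd.DataFrame(
            {"label": clean, "end_index": range(len(clean)), "recording_id": "r"}
        )
        raw_acc = (corrupted == np.asarray(clean, dtype=object)).mean()
        corrected = _apply_tsvc_per_recording(df, corrupted)
        cor_acc = (corrected == np.asarray(clean, dtype=object)).mean()
        assert raw_acc < 1.0 and cor_acc == 1.0

    def test_tsvc_never_crosses_recording_boundaries(self):
        import pandas as pd

        # recording b starts mid-cycle; a boundary-blind TSVC would relabel it
        a = ["LR"] * 6
        b = ["Swing"] * 6
        df = pd.DataFrame(
            {
                "label": a + b,
                "end_index": list(range(6)) + list(range(6)),
                "recording_id": ["a"] * 6 + ["b"] * 6,
            }
        )
        pred = np.asarray(a + b, dtype=object)
        corrected = _apply_tsvc_per_recording(df, pred)
        assert list(corrected) == a + b


class TestCrossval:
    def test_pooled_confusion_total_equals_window_count(self, small_cohort_df):
        df = small_cohort_df
        cfg = gp.LMTTrainConfig(num_boosting_iterations=8, prune=False, seed=0)
        reports = gp.crossval_report(df, k=3, config=cfg, seed=0)
        assert reports["lmt"].cm.total == len(df)
        assert reports["lmt_tsvc"].cm.total == len(df)

    def test_resubstitution_report_runs(self, small_cohort_df, tiny_trained_model):
        reports = gp.resubstitution_report(small_cohort_df, tiny_trained_model)
        assert 0.5 < reports["lmt"].accuracy <= 1.0
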