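"""Cross-validation protocol and metric formulas."""

import numpy as np
import pytest
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score, roc_auc_score)

from kbfmgmt.model import ClassifierSpec
from kbfmgmt.train_eval import (ArrayDataset, TrainConfig, evaluate,
                                make_folds, predict_patient, run_cv,
                                train_fold)

TINY_SPEC = ClassifierSpec(dims=3, input_side=8, seed=0)


def _tiny_samples(n, rng, signal=1.0, prefix="P"):
    """Patients whose mean intensity encodes the label (separable)."""
    samples = []
    for i in range(n):
        label = i % 2
        x = rng.normal(signal * label, 0.1,
                       size=(8, 8, 8)).astype(np.float32)
        samples.append((f"{prefix}{i:03d}", x, label))
    return samples


class TestMakeFolds:
    def test_stratified_partition(self):
        patients = [(f"p{i}", 1 if i < 6 else 0) for i in range(10)]
        split = make_folds(patients, 5, seed=0)
        sizes = [len(split.fold_patients(i)) for i in range(5)]
        assert sizes == [2] * 5
        for i in range(5):
            pos = sum(1 for p in split.fold_patients(i)
                      if dict(patients)[p] == 1)
            assert pos in (1, 2)

    def test_union_is_everyone_and_disjoint(self):
        patients = [(f"p{i}", i % 2) for i in range(13)]
        split = make_folds(patients, 5, seed=3)
        seen = [p for i in range(5) for p in split.fold_patients(i)]
        assert sorted(seen) == sorted(p for p, _ in patients)

    def test_leave_one_out(self):
        patients = [(f"p{i}", i % 2) for i in range(6)]
        split = make_folds(patients, 6, seed=0)
        assert all(len(split.fold_patients(i)) == 1 for i in range(6))

    def test_deterministic_per_seed(self):
        patients = [(f"p{i}", i % 2) for i in range(12)]
        a = make_folds(patients, 4, seed=9)
        b = make_folds(patients, 4, seed=9)
        assert a.assignment == b.assignment

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            make_folds([("a", 0), ("b", 1)], 3, seed=0)


class TestEvaluate:
    def test_perfect_scores(self):
        r = evaluate([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert (r.ACC, r.SPE, r.SEN, r.PRE, r.F1, r.AUC) == (1.0,) * 6

    def test_hand_computed_confusion(self):
        # TP=3 FN=1 TN=2 FP=2
        scores = [0.9, 0.8, 0.7, 0.2, 0.6, 0.9, 0.1, 0.3]
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        r = evaluate(scores, labels)
        assert (r.TP, r.FN, r.TN, r.FP) == (3, 1, 2, 2)
        assert r.ACC == pytest.approx(0.625)
        assert r.SEN == pytest.approx(0.75)
        assert r.SPE == pytest.approx(0.5)
        assert r.PRE == pytest.approx(0.6)
        assert r.F1 == pytest.approx(2 / 3)

    def test_constant_scores_auc_half(self):
        r = evaluate([0.4] * 6, [1, 0, 1, 0, 1, 0])
        assert r.AUC == pytest.approx(0.5)

    def test_single_class_leaves_metrics_absent(self):
        r = evaluate([0.9, 0.2], [1, 1])
        assert r.SPE is None and r.AUC is None
        assert r.SEN == pytest.approx(0.5)

    def test_matches_sklearn_on_random_vectors(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 3)
            r = evaluate(s, y)
            pred = (s >= 0.5).astype(int)
            assert r.ACC == pytest.approx(accuracy_score(y, pred))
            assert r.AUC == pytest.approx(roc_auc_score(y, s))
            if r.SEN is not None:
                assert r.SEN == pytest.approx(
                    recall_score(y, pred, zero_division=np.nan), nan_ok=True)
            if r.PRE is not None:
                assert r.PRE == pytest.approx(
                    precision_score(y, pred, zero_division=np.nan),
                    nan_ok=True)
            if r.F1 is not None:
                assert r.F1 == pytest.approx(f1_score(y, pred))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])


class TestTrainFold:
    def test_zero_learning_rate_freezes_weights(self, rng):
        samples = _tiny_samples(6, rng)
        cfg = TrainConfig(max_epochs=2, learning_rate=0.0, seed=0)
        model, history = train_fold(samples, cfg, TINY_SPEC)
        assert len(history) == 2
        assert history[0] == pytest.approx(history[1], rel=1e-6)
        model2, _ = train_fold(samples, cfg, TINY_SPEC)
        for p, q in zip(model.parameters(), model2.parameters()):
            assert np.array_equal(p.value, q.value)

    def test_single_class_rejected(self, rng):
        samples = [(f"p{i}", rng.normal(size=(8, 8, 8)).astype(np.float32), 1)
                   for i in range(4)]
        with pytest.raises(ValueError, match="single class"):
            train_fold(samples, TrainConfig(max_epochs=1), TINY_SPEC)

    def test_loss_decreases_on_separable_data(self, rng):
        samples = _tiny_samples(12, rng)
        cfg = TrainConfig(max_epochs=15, seed=0, learning_rate=1e-3)
        _model, history = train_fold(samples, cfg, TINY_SPEC)
        assert history[-1] < history[0]


class TestRunCV:
    def test_single_mode_no_leakage_and_mean(self, rng):
        ds = ArrayDataset("a", _tiny_samples(10, rng))
        cfg = TrainConfig(max_epochs=2, seed=0)
        res = run_cv(ds, "single", cfg, TINY_SPEC, k=5)
        assert len(res.fold_reports) == 5
        assert len(res.oof_scores) == 10
        for m, v in res.mean_report.items():
            vals = [getattr(r, m) for r in res.fold_reports
                    if getattr(r, m) is not None]
            if vals:
                assert v == pytest.approx(np.mean(vals), abs=1e-12)

    def test_merged_folds_mix_both_cohorts(self, rng):
        a = ArrayDataset("a", _tiny_samples(10, rng, prefix="A"))
        b = ArrayDataset("b", _tiny_samples(10, rng, prefix="B"))
        cfg = TrainConfig(max_epochs=1, seed=0)
        res = run_cv((a, b), "merged", cfg, TINY_SPEC, k=5)
        # out-of-fold predictions cover every patient of both cohorts
        assert {p[0] for p in res.oof_scores} == {"A", "B"}
        assert len(res.oof_scores) == 20

    def test_cross_mode_tests_only_other_cohort(self, rng):
        a = ArrayDataset("a", _tiny_samples(10, rng, prefix="A"))
        b = ArrayDataset("b", _tiny_samples(10, rng, prefix="B"))
        cfg = TrainConfig(max_epochs=1, seed=0)
        res = run_cv((a, b), "cross", cfg, TINY_SPEC, k=5)
        assert all(p.startswith("B") for p in res.oof_scores)

    def test_domain_shift_degrades_cross_auc(self, rng):
        # cohorts with opposite signal direction
        a = ArrayDataset("a", _tiny_samples(10, rng, signal=+2.0, prefix="A"))
        b = ArrayDataset("b", _tiny_samples(10, rng, signal=-2.0, prefix="B"))
        cfg = TrainConfig(max_epochs=25, seed=0, learning_rate=1e-3)
        single = run_cv(ArrayDataset("a2", a.samples), "single", cfg,
                        TINY_SPEC, k=5)
        a.folds = None
        cross = run_cv((a, b), "cross", cfg, TINY_SPEC, k=5)
        assert cross.mean_report["AUC"] < single.mean_report["AUC"]

    def test_csv_export(self, rng, tmp_path):
        import pandas as pd
        ds = ArrayDataset("a", _tiny_samples(8, rng))
        res = run_cv(ds, "single", TrainConfig(max_epochs=1, seed=0),
                     TINY_SPEC, k=4)
        out = tmp_path / "metrics.csv"
        res.to_csv(out)
        df = pd.read_csv(out)
        assert len(df) == 5  # four folds + mean row
        assert "AUC" in df.columns


class TestPredictPatient:
    def test_2d_score_is_mean_over_slices(self, rng):
        from kbfmgmt.model import build_classifier
        from kbfmgmt.nn import sigmoid
        spec = ClassifierSpec(dims=2, input_side=8, seed=0)
        model = build_classifier(spec)
        x = rng.normal(size=(5, 8, 8)).astype(np.float32)
        expected = float(np.mean(sigmoid(model.forward(x[:, None]))))
        assert predict_patient(model, x, 2) == pytest.approx(expected)
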