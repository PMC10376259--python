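import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facescreen.evaluate import (
    ClipPredictionSet,
    SVMConfig,
    compute_metrics,
    loso_clip_predictions,
    loso_evaluate,
    threshold_sweep,
    vote,
)


def _feature_table(rng, n_subjects=6, clips_per_subject=4, separation=0.0):
    """Synthetic clip-feature table; `separation` shifts dementia features."""
    rows = []
    for i in range(n_subjects):
        label = "dementia" if i % 2 else "healthy"
        subject = f"S{i:02d}"
        for c in range(clips_per_subject):
            feats = rng.normal(size=4) + (separation if label == "dementia" else 0.0)
            rows.append(
                {
                    "subject_id": subject,
                    "session_id": f"{subject}_s0",
                    "clip_index": c,
                    "label": label,
                    **{f"m_AU{j:02d}": feats[j] for j in range(4)},
                }
            )
    return pd.DataFrame(rows)


class TestLOSO:
    def test_separable_features_predicted_perfectly(self, rng):
        table = _feature_table(rng, n_subjects=8, separation=8.0)
        preds = loso_clip_predictions(table)
        for subject in preds.subjects:
            expected = 1.0 if preds.labels[subject] == "dementia" else 0.0
            assert preds.fractions[subject] == expected

    def test_fold_order_is_irrelevant(self, rng):
        table = _feature_table(rng, n_subjects=6, separation=1.0)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = loso_clip_predictions(table)
        b = loso_clip_predictions(shuffled)
        assert a.fractions == b.fractions

    def test_fold_without_both_classes_rejected(self, rng):
        table = _feature_table(rng, n_subjects=2)  # one subject per class
        with pytest.raises(ValueError, match="fold"):
            loso_clip_predictions(table)

    def test_held_out_subject_never_in_training(self, rng, monkeypatch):
        # structural hygiene: record every fold's training subjects
        from sklearn.svm import SVC

        table = _feature_table(rng, n_subjects=6)
        seen = []
        original = SVC.fit

        def spying_fit(self, X, y, **kw):
            seen.append(len(X))
            return original(self, X, y, **kw)

        monkeypatch.setattr(SVC, "fit", spying_fit)
        loso_clip_predictions(table)
        # each fold trains on all clips minus the held-out subject's 4
        assert seen == [len(table) - 4] * 6


class TestVote:
    def test_worked_example_25_percent(self):
        assert vote(0.3, 0.25) == "dementia"

    def test_majority_tie_breaks_healthy(self):
        # strict inequality: exactly half the clips is not enough
        assert vote(0.5, 0.5) == "healthy"

    def test_threshold_one_is_never_exceeded(self):
        assert vote(1.0, 1.0) == "healthy"

    def test_healthy_polarity(self):
        assert vote(0.3, 0.5, polarity="healthy") == "healthy"
        assert vote(0.8, 0.5, polarity="healthy") == "dementia"

    def test_threshold_range_checked(self):
        with pytest.raises(ValueError):
            vote(0.5, 1.5)


def _prediction_set(fractions_by_label):
    fractions, labels = {}, {}
    i = 0
    for label, values in fractions_by_label.items():
        for p in values:
            subject = f"{label[0].upper()}{i:02d}"
            fractions[subject] = p
            labels[subject] = label
            i += 1
    clip_preds = {s: () for s in fractions}
    return ClipPredictionSet(fractions, labels, clip_preds)


def _grid_oracle(preds, grid_step=0.01):
    """Brute-force sweep over a fixed threshold grid."""
    subjects = preds.subjects
    truth = np.array([preds.labels[s] == "dementia" for s in subjects])
    p = np.array([preds.fractions[s] for s in subjects])
    best_acc, best_gap = 0.0, np.inf
    best_eer_bal = None
    for t in np.arange(0.0, 1.0 + grid_step / 2, grid_step):
        decided = p > t
        acc = float((decided == truth).mean())
        tpr = (decided & truth).sum() / truth.sum()
        tnr = (~decided & ~truth).sum() / (~truth).sum()
        gap = abs((1 - tnr) - (1 - tpr))
        best_acc = max(best_acc, acc)
        if gap < best_gap:
            best_gap, best_eer_bal = gap, (tpr + tnr) / 2
    return best_acc, best_gap, best_eer_bal


class TestThresholdSweep:
    def test_separated_fractions_give_perfect_accuracy(self):
        preds = _prediction_set({"healthy": [0.0, 0.1], "dementia": [0.8, 0.9]})
        sweep = threshold_sweep(preds)
        assert sweep.best_accuracy == 1.0
        assert sweep.eer_accuracy == 1.0

    def test_uninformative_fractions_hit_prevalence(self):
        preds = _prediction_set({"healthy": [0.5] * 6, "dementia": [0.5] * 4})
        sweep = threshold_sweep(preds)
        assert sweep.best_accuracy == pytest.approx(0.6)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_dense_grid_oracle(self, seed):
        # 10 clips per subject -> fractions on a 0.1 grid, so the 0.01-step
        # brute force reaches every achievable decision vector
        r = np.random.default_rng(seed)
        preds = _prediction_set(
            {
                "healthy": (r.integers(0, 11, size=5) / 10).tolist(),
                "dementia": (r.integers(0, 11, size=5) / 10).tolist(),
            }
        )
        sweep = threshold_sweep(preds)
        best_acc, best_gap, eer_bal = _grid_oracle(preds)
        assert sweep.best_accuracy == pytest.approx(best_acc)
        row = sweep.table[sweep.table["threshold"] == sweep.eer_threshold].iloc[0]
        assert abs(row["fpr"] - row["fnr"]) == pytest.approx(best_gap)
        assert sweep.eer_accuracy == pytest.approx(eer_bal)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_recall_nonincreasing_specificity_nondecreasing(self, seed):
        r = np.random.default_rng(seed)
        preds = _prediction_set(
            {"healthy": r.uniform(0, 1, 4).tolist(), "dementia": r.uniform(0, 1, 4).tolist()}
        )
        table = threshold_sweep(preds).table
        assert np.all(np.diff(table["recall"]) <= 1e-12)
        assert np.all(np.diff(1 - table["fpr"]) >= -1e-12)

    def test_tie_breaks_choose_smallest_threshold(self):
        preds = _prediction_set({"healthy": [0.0, 0.2], "dementia": [0.6, 1.0]})
        sweep = threshold_sweep(preds)
        candidates = sweep.table[sweep.table["accuracy"] == sweep.best_accuracy]
        assert sweep.best_threshold == candidates["threshold"].min()

    def test_single_class_rejected(self):
        preds = _prediction_set({"healthy": [0.2, 0.4]})
        with pytest.raises(ValueError):
            threshold_sweep(preds)


class TestComputeMetrics:
    def test_perfect_prediction(self):
        labels = {"A": "dementia", "B": "healthy"}
        report = compute_metrics(labels, labels, eer_accuracy=1.0)
        assert (report.accuracy, report.recall, report.precision, report.f1) == (1, 1, 1, 1)

    def test_confusion_matrix_arithmetic(self):
        # TP=5 FN=5 TN=9 FP=1 over 20 subjects
        labels, decisions = {}, {}
        for i in range(10):
            labels[f"D{i}"] = "dementia"
            decisions[f"D{i}"] = "dementia" if i < 5 else "healthy"
        for i in range(10):
            labels[f"H{i}"] = "healthy"
            decisions[f"H{i}"] = "dementia" if i == 0 else "healthy"
        report = compute_metrics(decisions, labels)
        assert report.accuracy == pytest.approx(0.7)
        assert report.recall == pytest.approx(0.5)
        assert report.precision == pytest.approx(5 / 6)
        expected_f1 = 2 * 0.5 * (5 / 6) / (0.5 + 5 / 6)
        assert report.f1 == pytest.approx(expected_f1)

    def test_degenerate_predictor_warns(self):
        labels = {"A": "dementia", "B": "healthy"}
        decisions = {"A": "healthy", "B": "healthy"}
        with pytest.warns(UserWarning, match="precision"):
            report = compute_metrics(decisions, labels)
        assert report.recall == 0.0 and report.precision == 0.0 and report.f1 == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics({}, {})


def test_loso_evaluate_end_to_end(rng):
    table = _feature_table(rng, n_subjects=8, separation=6.0)
    result = loso_evaluate(table, SVMConfig(C=1.0))
    assert result["metrics"].accuracy == 1.0
    assert result["metrics"].eer_accuracy == 1.0
    assert set(result["decisions"]) == set(result["predictions"].subjects)
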