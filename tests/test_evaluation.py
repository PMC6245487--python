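import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trisomap.evaluation import (
    MetricsReport,
    compute_metrics,
    confusion,
    run_protocol,
    split_indices,
)
from trisomap.io_formats import CONTROL_LABEL, DS_LABEL


class TestSplitIndices:
    def test_study_cohort_sizes(self):
        train, test = split_indices(378, 0.75, seed=0)
        assert len(train) == 283 and len(test) == 95  # floor(283.5) = 283

    def test_tiny_split(self):
        train, test = split_indices(4, 0.75, seed=1)
        assert len(train) == 3 and len(test) == 1

    def test_deterministic_disjoint_exhaustive(self):
        a = split_indices(50, 0.6, seed=9)
        b = split_indices(50, 0.6, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        assert not set(a[0]) & set(a[1])
        assert sorted([*a[0], *a[1]]) == list(range(50))
        c = split_indices(50, 0.6, seed=10)
        assert not np.array_equal(a[0], c[0])

    def test_stratified_preserves_class_fractions(self):
        labels = np.array([DS_LABEL] * 20 + [CONTROL_LABEL] * 80)
        train, _ = split_indices(100, 0.75, seed=3, stratify_labels=labels)
        assert (labels[train] == DS_LABEL).sum() == 15

    def test_degenerate_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_indices(10, 0.0)
        with pytest.raises(ValueError):
            split_indices(3, 0.2)  # empty train side


class TestConfusion:
    def test_perfect_and_all_control(self):
        truth = np.array([DS_LABEL] * 2 + [CONTROL_LABEL] * 8)
        assert confusion(truth, truth) == (2, 0, 0, 8)
        allc = np.array([CONTROL_LABEL] * 10)
        assert confusion(truth, allc) == (0, 0, 2, 8)

    def test_swapped_positive_class(self):
        truth = np.array([DS_LABEL, DS_LABEL, CONTROL_LABEL, CONTROL_LABEL])
        pred = np.array([DS_LABEL, CONTROL_LABEL, DS_LABEL, CONTROL_LABEL])
        tp, fp, fn, tn = confusion(truth, pred, positive=DS_LABEL)
        assert confusion(truth, pred, positive=CONTROL_LABEL) == (tn, fn, fp, tp)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            confusion([DS_LABEL], ["trisomy"])


class TestComputeMetrics:
    def test_hand_worked_confusion_table(self):
        m = compute_metrics(38, 1, 2, 54)
        assert m.accuracy == pytest.approx(92 / 95)
        assert m.precision == pytest.approx(38 / 39)
        assert m.recall == pytest.approx(0.95)
        assert m.f_score == pytest.approx(2 * (38 / 39) * 0.95 / ((38 / 39) + 0.95))
        assert m.fp_rate == pytest.approx(1 / 55)
        assert m.fn_rate == pytest.approx(0.05)
        assert not m.undefined

    def test_perfect_case(self):
        m = compute_metrics(2, 0, 0, 8)
        assert (m.accuracy, m.precision, m.recall, m.f_score) == (1, 1, 1, 1)
        assert (m.fp_rate, m.fn_rate) == (0, 0)

    def test_degenerate_no_positive_predictions(self):
        m = compute_metrics(0, 0, 5, 5)
        assert m.precision == 0 and "precision" in m.undefined
        assert m.recall == 0 and m.fn_rate == 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(-1, 0, 0, 1)

    @given(
        st.tuples(
            st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(1, 50)
        )
    )
    @settings(deadline=None, max_examples=200)
    def test_metric_identities(self, counts):
        tp, fp, fn, tn = counts
        m = compute_metrics(tp, fp, fn, tn)
        if tp + fn > 0:
            assert m.recall == pytest.approx(1.0 - m.fn_rate)
        if fp + tn > 0:
            specificity = tn / (tn + fp)
            assert m.fp_rate == pytest.approx(1.0 - specificity)
        assert 0 <= m.accuracy <= 1

    def test_agrees_with_sklearn_oracle(self):
        """Independent cross-check of the metric formulas on random label vectors."""
        from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score

        rng = np.random.default_rng(0)
        classes = np.array([CONTROL_LABEL, DS_LABEL], dtype=object)
        for _ in range(50):
            yt = classes[rng.integers(0, 2, 30)]
            yp = classes[rng.integers(0, 2, 30)]
            m = compute_metrics(*confusion(yt, yp))
            assert m.accuracy == pytest.approx(accuracy_score(yt, yp))
            assert m.precision == pytest.approx(
                precision_score(yt, yp, pos_label=DS_LABEL, zero_division=0)
            )
            assert m.recall == pytest.approx(
                recall_score(yt, yp, pos_label=DS_LABEL, zero_division=0)
            )
            if not m.undefined:
                assert m.f_score == pytest.approx(f1_score(yt, yp, pos_label=DS_LABEL))
                assert m.f_score_weighted == pytest.approx(
                    f1_score(yt, yp, average="weighted")
                )


class TestRunProtocol:
    @staticmethod
    def _labels(n_ds=10, n_control=30, seed=0):
        labels = np.array([DS_LABEL] * n_ds + [CONTROL_LABEL] * n_control, dtype=object)
        np.random.default_rng(seed).shuffle(labels)
        return labels

    def test_deterministic_runs_have_zero_std(self):
        labels = self._labels()

        def perfect(train_idx, test_idx, run_seed):
            return labels[test_idx]

        report = run_protocol(perfect, labels, n_repeats=10, seed=4)
        assert all(v == 0.0 for v in report.std.values())
        assert report.mean["accuracy"] == 1.0

    def test_pooled_counts_are_sums_and_mean_bounded(self):
        labels = self._labels()
        rng = np.random.default_rng(5)

        def noisy(train_idx, test_idx, run_seed):
            out = labels[test_idx].copy()
            flip = rng.random(len(out)) < 0.3
            swapped = np.where(out == DS_LABEL, CONTROL_LABEL, DS_LABEL)
            return np.where(flip, swapped, out)

        report = run_protocol(noisy, labels, n_repeats=10, seed=4)
        assert report.pooled.tp == sum(r.tp for r in report.runs)
        accs = [r.accuracy for r in report.runs]
        assert min(accs) <= report.mean["accuracy"] <= max(accs)

    def test_single_class_dataset_rejected(self):
        labels = np.array([CONTROL_LABEL] * 20, dtype=object)
        with pytest.raises(ValueError, match="both classes"):
            run_protocol(lambda a, b, s: labels[b], labels)

    def test_splits_differ_across_repeats(self):
        labels = self._labels()
        seen = []

        def record(train_idx, test_idx, run_seed):
            seen.append(tuple(test_idx))
            return labels[test_idx]

        run_protocol(record, labels, n_repeats=5, seed=0)
        assert len(set(seen)) == 5
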