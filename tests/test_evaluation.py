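"""Confusion-matrix battery: orientation, pooled OVR identities, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ganoderma_ftir.evaluation import (
    RunMetrics,
    confusion_matrix,
    core_metrics,
    macro_prf,
    ovr_counts,
    run_metrics,
    summarize_runs,
)


class TestConfusionMatrix:
    def test_all_correct_is_diagonal(self):
        true = ["GL", "GL", "GS", "GS", "GT", "GT"]
        cm = confusion_matrix(true, true, ("GL", "GS", "GT"))
        np.testing.assert_array_equal(cm.counts, np.diag([2, 2, 2]))

    def test_orientation_rows_are_predicted(self):
        true = ["GL"] * 5
        pred = ["GT"] * 5
        cm = confusion_matrix(true, pred, ("GL", "GS", "GT"))
        assert cm.counts[2, 0] == 5  # GT row, GL column
        assert cm.counts.sum() == 5
        assert cm.transposed().counts[0, 2] == 5

    def test_sample_order_irrelevant(self):
        rng = np.random.default_rng(0)
        true = rng.choice(["a", "b"], size=50).tolist()
        pred = rng.choice(["a", "b"], size=50).tolist()
        cm1 = confusion_matrix(true, pred, ("a", "b"))
        perm = rng.permutation(50)
        cm2 = confusion_matrix([true[i] for i in perm], [pred[i] for i in perm], ("a", "b"))
        np.testing.assert_array_equal(cm1.counts, cm2.counts)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["a"], ["z"], ("a", "b"))


class TestOvrCounts:
    def test_diagonal_has_no_errors(self):
        cm = confusion_matrix(["a", "b"], ["a", "b"], ("a", "b"))
        _, pooled = ovr_counts(cm)
        assert pooled.fp == pooled.fn == 0

    def test_three_class_250_of_300_correct(self):
        # brute-force-derived pooled OVR table for 250/300 correct
        counts = np.diag([100, 80, 70])
        counts[0, 1] = 10
        counts[1, 2] = 20
        counts[2, 0] = 20
        from ganoderma_ftir.evaluation import ConfusionMatrix

        cm = ConfusionMatrix(counts, ("a", "b", "c"))
        _, pooled = ovr_counts(cm)
        assert (pooled.tp, pooled.fn, pooled.fp, pooled.tn) == (250, 50, 50, 550)

    def test_per_class_matches_label_pair_recount(self):
        rng = np.random.default_rng(3)
        classes = ("x", "y", "z")
        true = rng.choice(classes, size=60)
        pred = rng.choice(classes, size=60)
        per_class, _ = ovr_counts(confusion_matrix(true, pred, classes))
        for cls in classes:
            tp = int(np.sum((true == cls) & (pred == cls)))
            fn = int(np.sum((true == cls) & (pred != cls)))
            fp = int(np.sum((true != cls) & (pred == cls)))
            tn = 60 - tp - fn - fp
            c = per_class[cls]
            assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)


class TestCoreMetrics:
    def test_perfect_matrix(self):
        cm = confusion_matrix(["a", "b"], ["a", "b"], ("a", "b"))
        _, pooled = ovr_counts(cm)
        assert core_metrics(pooled) == (100.0, 100.0, 100.0)

    def test_sensitivity_from_counts(self):
        from ganoderma_ftir.evaluation import OvrCounts

        _, sens, _ = core_metrics(OvrCounts(tp=8, tn=10, fp=2, fn=2))
        assert sens == pytest.approx(80.0)

    def test_reported_run1_triple_follows_identities(self):
        # a 3-class pooled table with sensitivity 83.47% must give
        # accuracy 88.98% and specificity 91.73% by the exact identities
        sens = 83.47
        e = 1 - sens / 100
        assert 100 * (1 - 2 * e / 3) == pytest.approx(88.98, abs=0.01)
        assert 100 * (1 - e / 2) == pytest.approx(91.73, abs=0.01)


@st.composite
def confusion_matrices(draw):
    k = draw(st.integers(min_value=2, max_value=4))
    counts = draw(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=30), min_size=k, max_size=k),
            min_size=k,
            max_size=k,
        )
    )
    counts = np.asarray(counts)
    # ensure every class appears in truth and something is predicted
    counts += np.eye(k, dtype=int)
    from ganoderma_ftir.evaluation import ConfusionMatrix

    return ConfusionMatrix(counts, tuple(f"c{i}" for i in range(k)))


class TestPooledIdentities:
    @settings(max_examples=200, derandomize=True)
    @given(confusion_matrices())
    def test_micro_identities_hold_exactly(self, cm):
        """acc = 1 - 2e/K and spec = 1 - e/(K-1) with e = 1 - sens, any K x K."""
        k = len(cm.class_order)
        _, pooled = ovr_counts(cm)
        assert pooled.fp == pooled.fn
        acc, sens, spec = core_metrics(pooled)
        e = 1 - sens / 100
        assert acc / 100 == pytest.approx(1 - 2 * e / k, abs=1e-12)
        assert spec / 100 == pytest.approx(1 - e / (k - 1), abs=1e-12)


class TestMacroPrf:
    def test_harmonic_mean_identity(self):
        cm = confusion_matrix(
            ["a"] * 9 + ["b"] * 9, ["a"] * 8 + ["b"] + ["b"] * 7 + ["a"] * 2, ("a", "b")
        )
        p, r, f = macro_prf(cm)
        per_class, _ = ovr_counts(cm)
        for cls in ("a", "b"):
            c = per_class[cls]
            pc, rc = c.tp / (c.tp + c.fp), c.tp / (c.tp + c.fn)
            assert 2 * pc * rc / (pc + rc) > 0
        # p == r implies f == p
        if p == pytest.approx(r):
            assert f == pytest.approx(p)

    def test_never_predicted_class_warns_and_contributes_zero(self):
        cm = confusion_matrix(["a", "b", "b"], ["b", "b", "b"], ("a", "b"))
        with pytest.warns(UserWarning, match="never predicted"):
            p, r, f = macro_prf(cm)
        assert p == pytest.approx((0.0 + 2 / 3) / 2)


class TestSummarizeRuns:
    @staticmethod
    def _metrics(values):
        return [
            RunMetrics(accuracy=v, sensitivity=v, specificity=v, precision=v / 100,
                       recall=v / 100, f1=v / 100)
            for v in values
        ]

    def test_population_sd_closed_form_two_values(self):
        summary = summarize_runs(self._metrics([80.0, 90.0]))
        assert summary.mean["accuracy"] == pytest.approx(85.0)
        assert summary.sd["accuracy"] == pytest.approx(5.0)  # |a-b|/2, divisor n
        assert summary.cv["accuracy"] == pytest.approx(100 * 5 / 85)

    def test_constant_series_zero_sd(self):
        summary = summarize_runs(self._metrics([90.0, 90.0, 90.0]))
        assert summary.sd["accuracy"] == 0.0
        assert summary.cv["accuracy"] == 0.0

    def test_run_order_invariant(self):
        values = [88.0, 91.0, 85.0, 90.0]
        a = summarize_runs(self._metrics(values))
        b = summarize_runs(self._metrics(values[::-1]))
        for key in a.mean:
            assert a.mean[key] == pytest.approx(b.mean[key], abs=1e-12)
            assert a.sd[key] == pytest.approx(b.sd[key], abs=1e-12)


class TestRunMetricsBattery:
    def test_full_battery_consistency(self):
        rng = np.random.default_rng(9)
        classes = ("GL", "GS", "GT")
        true = rng.choice(classes, size=90)
        pred = np.where(rng.uniform(size=90) < 0.8, true, rng.choice(classes, size=90))
        cm = confusion_matrix(true, pred, classes)
        m = run_metrics(cm)
        _, pooled = ovr_counts(cm)
        acc, sens, spec = core_metrics(pooled)
        assert (m.accuracy, m.sensitivity, m.specificity) == (acc, sens, spec)
        assert 0 <= m.f1 <= 1
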