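"""Nucleotide-level confusion counts and CC / F1 metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from crmseg.evaluate import (
    ConfusionCounts,
    cc_score,
    confusion_counts,
    f1_score,
    pooled_metrics,
)


class TestConfusionCounts:
    def test_identical(self):
        c = confusion_counts([(10, 20)], [(10, 20)], 100)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 90, 0, 0)

    def test_partial_overlap(self):
        c = confusion_counts([(0, 10)], [(5, 15)], 20)
        assert (c.tp, c.fp, c.fn, c.tn) == (5, 5, 5, 5)

    def test_empty_prediction(self):
        c = confusion_counts([], [(0, 10)], 50)
        assert (c.tp, c.fn, c.tn, c.fp) == (0, 10, 40, 0)

    def test_overlaps_unioned(self):
        c = confusion_counts([(0, 10), (5, 15)], [(0, 15)], 20)
        assert (c.tp, c.fp, c.fn, c.tn) == (15, 0, 0, 5)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            confusion_counts([(0, 30)], [], 20)

    def test_total_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            L = int(rng.integers(10, 100))
            def ivs():
                n = rng.integers(0, 4)
                out = []
                for _ in range(n):
                    a = int(rng.integers(0, L))
                    b = int(rng.integers(a, L + 1))
                    out.append((a, b))
                return out
            c = confusion_counts(ivs(), ivs(), L)
            assert c.total == L


class TestCc:
    def test_perfect_is_one(self):
        assert cc_score(ConfusionCounts(10, 90, 0, 0)) == pytest.approx(1.0, abs=1e-12)

    def test_hand_value(self):
        assert cc_score(ConfusionCounts(3, 4, 1, 2)) == pytest.approx(
            10 / math.sqrt(600), abs=1e-12
        )

    def test_zero_numerator(self):
        assert cc_score(ConfusionCounts(2, 2, 2, 2)) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_is_nan(self):
        assert math.isnan(cc_score(ConfusionCounts(0, 50, 0, 0)))

    @given(
        tp=st.integers(0, 50), tn=st.integers(0, 50),
        fp=st.integers(0, 50), fn=st.integers(0, 50),
    )
    def test_bounded_and_label_swap(self, tp, tn, fp, fn):
        c = ConfusionCounts(tp, tn, fp, fn)
        cc = cc_score(c)
        if not math.isnan(cc):
            assert -1.0 - 1e-12 <= cc <= 1.0 + 1e-12
        # swapping prediction and truth swaps FP and FN, keeps CC
        swapped = ConfusionCounts(tp, tn, fn, fp)
        cc2 = cc_score(swapped)
        if not (math.isnan(cc) or math.isnan(cc2)):
            assert cc == pytest.approx(cc2, abs=1e-12)
        pr, re, _ = f1_score(c)
        pr2, re2, _ = f1_score(swapped)
        if not (math.isnan(pr) or math.isnan(re2)):
            assert pr == pytest.approx(re2, abs=1e-12)

    def test_complement_negates_on_balanced_case(self):
        c = ConfusionCounts(3, 3, 2, 2)
        comp = ConfusionCounts(2, 2, 3, 3)  # complement prediction
        assert cc_score(comp) == pytest.approx(-cc_score(c), abs=1e-12)


class TestF1:
    def test_perfect(self):
        assert f1_score(ConfusionCounts(10, 90, 0, 0)) == (1.0, 1.0, 1.0)

    def test_hand_value(self):
        pr, re, f1 = f1_score(ConfusionCounts(3, 0, 1, 2))
        assert pr == pytest.approx(0.75)
        assert re == pytest.approx(0.6)
        assert f1 == pytest.approx(2 / 3, abs=1e-12)

    def test_zero_convention(self):
        assert f1_score(ConfusionCounts(0, 10, 3, 4)) == (0.0, 0.0, 0.0)

    def test_undefined_precision_is_nan(self):
        pr, re, f1 = f1_score(ConfusionCounts(0, 10, 0, 4))
        assert math.isnan(pr) and re == 0.0 and math.isnan(f1)


class TestPooled:
    def test_single_sequence_identity(self):
        c = ConfusionCounts(3, 4, 1, 2)
        df = pooled_metrics([c])
        assert df.loc["pooled", "cc"] == pytest.approx(cc_score(c), abs=1e-12)
        assert df.loc["seq0", "f1"] == df.loc["pooled", "f1"]

    def test_micro_pooling_sums_counts(self):
        df = pooled_metrics(
            [ConfusionCounts(1, 1, 1, 1), ConfusionCounts(2, 2, 2, 2)]
        )
        assert df.loc["pooled", ["tp", "tn", "fp", "fn"]].tolist() == [3, 3, 3, 3]
        assert df.loc["pooled", "cc"] == pytest.approx(0.0, abs=1e-12)

    def test_permutation_invariant(self):
        counts = [ConfusionCounts(3, 4, 1, 2), ConfusionCounts(5, 1, 0, 4),
                  ConfusionCounts(0, 9, 1, 0)]
        a = pooled_metrics(counts).loc["pooled"]
        b = pooled_metrics(counts[::-1]).loc["pooled"]
        assert a["cc"] == pytest.approx(b["cc"], abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pooled_metrics([])
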