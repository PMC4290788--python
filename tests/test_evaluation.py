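"""Confusion counting, P/R/F1 and micro-averaging.

The frozen expected metric values are recomputed independently from the
published per-subtype confusion counts (e.g. 641/(641+14) = 0.979).
"""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from thyroscore import (ValidationError, confusion_counts, evaluate,
                        micro_average, prf)


def _labels(**kw):
    return {pmid: frozenset(v) for pmid, v in kw.items()}


class TestConfusionCounts:
    def test_exact_match_counts(self):
        gold = _labels(p1={"PTC"})
        pred = _labels(p1={"PTC"})
        assert confusion_counts(pred, gold, "PTC") == (1, 0, 0, 0)
        assert confusion_counts(pred, gold, "ATC") == (0, 0, 0, 1)

    def test_multilabel_evaluated_per_subtype(self):
        gold = _labels(p1={"PTC", "FTC"})
        pred = _labels(p1={"PTC"})
        assert confusion_counts(pred, gold, "PTC") == (1, 0, 0, 0)
        assert confusion_counts(pred, gold, "FTC") == (0, 0, 1, 0)

    def test_tc_and_non_count_as_negative(self):
        gold = _labels(p1={"PTC"}, p2={"MTC"})
        pred = _labels(p1={"TC"}, p2={"NON"})
        assert confusion_counts(pred, gold, "PTC") == (0, 0, 1, 1)
        assert confusion_counts(pred, gold, "MTC") == (0, 0, 1, 1)

    def test_gold_defines_the_universe(self):
        gold = _labels(p1={"PTC"})
        pred = _labels(p1={"PTC"}, p9={"PTC"})  # p9 outside gold: ignored
        assert confusion_counts(pred, gold, "PTC") == (1, 0, 0, 0)

    def test_missing_prediction_counts_negative(self):
        gold = _labels(p1={"PTC"})
        assert confusion_counts({}, gold, "PTC") == (0, 0, 1, 0)

    def test_empty_gold(self):
        assert confusion_counts(_labels(p1={"PTC"}), {}, "PTC") == (0, 0, 0, 0)

    def test_unknown_subtype_rejected(self):
        with pytest.raises(ValidationError):
            confusion_counts({}, {}, "XTC")


class TestPRF:
    # Expected values recomputed by hand from the confusion counts.
    @pytest.mark.parametrize("tp, fp, fn, p, r, f1", [
        (641, 14, 186, 0.979, 0.775, 0.865),
        (75, 45, 12, 0.625, 0.862, 0.725),
        (189, 4, 41, 0.979, 0.822, 0.894),
        (114, 6, 27, 0.950, 0.809, 0.874),
    ])
    def test_published_style_counts(self, tp, fp, fn, p, r, f1):
        got = prf(tp, fp, fn)
        assert got == pytest.approx((p, r, f1), abs=5e-4)

    def test_degenerate_zero_convention(self):
        assert prf(0, 0, 0) == (0.0, 0.0, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            prf(-1, 0, 0)

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    def test_f1_between_p_and_r(self, tp, fp, fn):
        p, r, f1 = prf(tp, fp, fn)
        if p + r > 0:
            assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12
        assert 0 <= p <= 1 and 0 <= r <= 1 and 0 <= f1 <= 1


class TestMicroAverage:
    def test_pooled_counts(self):
        counts = {
            "PTC": (641, 14, 186, 372),
            "ATC": (114, 6, 27, 1066),
            "FTC": (75, 45, 12, 1081),
            "MTC": (189, 4, 41, 979),
        }
        # pooled: TP=1019, FP=69, FN=266
        p, r, f1 = micro_average(counts)
        assert (p, r, f1) == pytest.approx((0.937, 0.793, 0.859), abs=5e-4)

    def test_single_subtype_identity(self):
        counts = {"PTC": (10, 2, 3, 5)}
        assert micro_average(counts) == prf(10, 2, 3)

    def test_duplicated_counts_leave_ratios_unchanged(self):
        one = {"PTC": (10, 2, 3, 5)}
        two = {"PTC": (10, 2, 3, 5), "FTC": (10, 2, 3, 5)}
        assert micro_average(one) == pytest.approx(micro_average(two))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            micro_average({})


class TestEvaluate:
    def test_perfect_predictions(self):
        gold = {str(i): frozenset({"PTC" if i % 2 else "MTC"}) for i in range(10)}
        report = evaluate(gold, gold)
        for j in ("PTC", "MTC"):
            assert report.per_subtype[j].f1 == 1.0
        assert report.micro.f1 == 1.0

    def test_all_non_predictions_give_zero_recall(self):
        gold = {str(i): frozenset({"PTC"}) for i in range(5)}
        pred = {str(i): frozenset({"NON"}) for i in range(5)}
        report = evaluate(pred, gold)
        assert report.per_subtype["PTC"].recall == 0.0

    def test_micro_counts_conserved(self):
        gold = {str(i): frozenset({"PTC"}) for i in range(7)}
        pred = {str(i): frozenset({"FTC"}) for i in range(7)}
        report = evaluate(pred, gold)
        m = report.micro
        assert m.tp + m.fp + m.fn + m.tn == 4 * len(gold)

    def test_engineered_published_ptc_row(self):
        """1213 synthetic docs realizing counts (641, 14, 186, 372) give the
        published-style PTC metrics to 3 d.p."""
        gold, pred = {}, {}
        i = 0
        for _ in range(641):  # gold PTC, predicted PTC
            gold[str(i)] = frozenset({"PTC"})
            pred[str(i)] = frozenset({"PTC"})
            i += 1
        for _ in range(186):  # gold PTC, missed
            gold[str(i)] = frozenset({"PTC"})
            pred[str(i)] = frozenset({"NON"})
            i += 1
        for _ in range(14):   # spurious PTC prediction
            gold[str(i)] = frozenset({"MTC"})
            pred[str(i)] = frozenset({"PTC"})
            i += 1
        for _ in range(372):  # true negatives for PTC
            gold[str(i)] = frozenset({"MTC"})
            pred[str(i)] = frozenset({"MTC"})
            i += 1
        report = evaluate(pred, gold)
        row = report.per_subtype["PTC"]
        assert (row.tp, row.fp, row.fn, row.tn) == (641, 14, 186, 372)
        assert (row.precision, row.recall, row.f1) == \
               pytest.approx((0.979, 0.775, 0.865), abs=5e-4)

    def test_ftc_reassignment_turns_fp_into_tp(self):
        gold = _labels(p1={"PTC"}, p2={"PTC"})
        pred = _labels(p1={"PTC", "FTC"}, p2={"PTC"})
        plain = evaluate(pred, gold)
        adjusted = evaluate(pred, gold, ftc_reassign=["p1"])
        assert plain.per_subtype["FTC"].fp == 1
        assert adjusted.per_subtype["FTC"].fp == 0
        assert adjusted.per_subtype["FTC"].tp == 1

    def test_report_frame_recomputes_from_counts(self):
        gold = {str(i): frozenset({"PTC"}) for i in range(8)}
        pred = {str(i): frozenset({"PTC" if i < 6 else "NON"}) for i in range(8)}
        frame = evaluate(pred, gold).to_frame()
        for _, row in frame.iterrows():
            p, r, f1 = prf(row.TP, row.FP, row.FN)
            assert row.Precision == pytest.approx(p, abs=5e-4)
            assert row.Recall == pytest.approx(r, abs=5e-4)
            assert row.F1 == pytest.approx(f1, abs=5e-4)
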