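import math

import numpy as np
import pandas as pd
import pytest

import codonscan as cs
from codonscan.errors import MalformedIntervalError, ParameterError, UnmappableExonError
from codonscan.pipeline import EvaluationTable, bin_ppv_by_exon_length, roc_points


def _ann(rows):
    return pd.DataFrame(rows, columns=["seq_id", "start", "end", "strand", "name", "source"])


ANNOTATIONS = _ann([("chr1", 100, 200, "+", "exA", "truth"), ("chr1", 500, 560, "-", "exB", "truth")])


def _call(start, end, strand="+", seq_id="chr1", **kw):
    return cs.ExonCall(seq_id=seq_id, start=start, end=end, strand=strand, **kw)


class TestLabeling:
    def test_overlap_single_bp_is_true_positive(self):
        calls = cs.label_predictions([_call(199, 260)], ANNOTATIONS)
        assert calls[0].truth == "true_positive"

    def test_adjacent_interval_is_false_positive(self):
        calls = cs.label_predictions([_call(200, 260)], ANNOTATIONS)
        assert calls[0].truth == "false_positive"

    def test_strand_must_match(self):
        calls = cs.label_predictions([_call(510, 550, strand="+")], ANNOTATIONS)
        assert calls[0].truth == "false_positive"
        calls = cs.label_predictions([_call(510, 550, strand="-")], ANNOTATIONS)
        assert calls[0].truth == "true_positive"

    def test_min_overlap_threshold(self):
        calls = cs.label_predictions([_call(190, 260)], ANNOTATIONS, min_overlap=10)
        assert calls[0].truth == "true_positive"
        calls = cs.label_predictions([_call(191, 260)], ANNOTATIONS, min_overlap=10)
        assert calls[0].truth == "false_positive"

    def test_accepts_dataframe_input(self):
        df = _ann([("chr1", 120, 180, "+", "p0", "finder")])
        calls = cs.label_predictions(df, ANNOTATIONS)
        assert calls[0].truth == "true_positive" and calls[0].name == "p0"

    def test_bad_interval_rejected(self):
        with pytest.raises(MalformedIntervalError):
            _call(50, 50)
        with pytest.raises(MalformedIntervalError):
            _call(-1, 10)


class TestEvaluationTable:
    def test_published_scale_counts(self):
        """Counts of the scale reported for a GENSCAN-style evaluation:
        1818 TP + 1243 FP before filtering, 1345 TP + 262 FP after."""
        before = EvaluationTable(tp=1818, fp=1243, fn=0)
        after = EvaluationTable(tp=1345, fp=262, fn=0)
        assert before.ppv == pytest.approx(1818 / 3061)
        assert after.ppv == pytest.approx(1345 / 1607)
        assert after.ppv > before.ppv

    def test_fpr_uses_tp_plus_fn_denominator(self):
        t = EvaluationTable(tp=30, fp=12, fn=10)
        assert t.fpr == pytest.approx(12 / 40)
        assert t.sensitivity == pytest.approx(30 / 40)
        assert t.fpr_conventional is None
        t2 = EvaluationTable(tp=30, fp=12, fn=10, tn=88)
        assert t2.fpr_conventional == pytest.approx(12 / 100)

    def test_empty_counts_give_nan(self):
        t = EvaluationTable(tp=0, fp=0, fn=0)
        assert math.isnan(t.ppv) and math.isnan(t.sensitivity)


class TestChiSquare:
    def test_matches_hand_computed_pearson_statistic(self):
        # independent hand computation of the Pearson statistic on the same
        # 2x2 table (no continuity correction)
        before, after = (1818, 1243), (1345, 262)
        table = np.array([before, after], dtype=float)
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        by_hand = ((table - exp) ** 2 / exp).sum()
        stat, p = cs.chi_square_filter_effect(before, after)
        assert stat == pytest.approx(by_hand, rel=1e-12)
        assert stat == pytest.approx(284.9239, abs=1e-3)
        assert p < 1e-10

    def test_second_published_scale_table(self):
        stat, _ = cs.chi_square_filter_effect((2209, 480), (1619, 203))
        assert stat == pytest.approx(38.0471, abs=1e-3)

    def test_equal_proportions_give_zero(self):
        stat, p = cs.chi_square_filter_effect((100, 50), (200, 100))
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_row_order_invariance(self):
        s1, _ = cs.chi_square_filter_effect((1818, 1243), (1345, 262))
        s2, _ = cs.chi_square_filter_effect((1345, 262), (1818, 1243))
        assert s1 == pytest.approx(s2)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ParameterError):
            cs.chi_square_filter_effect((0, 0), (10, 5))
        with pytest.raises(ParameterError):
            cs.chi_square_filter_effect((0, 10), (0, 5))


@pytest.fixture(scope="module")
def mosaic_case(trained_matrix, calibration):
    """A mosaic with one real exon, a labeled true and false prediction."""
    spec = cs.MosaicSpec(
        total_length=3_000,
        exon_blocks=[(600, 60, "+")],
        background=cs.NullModel(seq_length=3_000, n_sequences=1, seed=3),
        seed=3,
    )
    aln, annotations = cs.build_mosaic(spec, cs.CodingModel(), rng=np.random.default_rng(3))
    preds = [
        cs.ExonCall("mosaic", 600, 780, "+", name="true_pred"),
        cs.ExonCall("mosaic", 1500, 1700, "+", name="false_pred"),
    ]
    calls = cs.label_predictions(preds, annotations)
    tested = cs.test_exons(calls, aln, trained_matrix, calibration, alpha=0.01)
    return aln, annotations, tested


class TestExonTesting:
    def test_true_exon_passes_false_fails(self, mosaic_case):
        _, _, tested = mosaic_case
        by_name = {c.name: c for c in tested}
        t, f = by_name["true_pred"], by_name["false_pred"]
        assert t.truth == "true_positive" and t.verdict == "pass"
        assert t.p_value < 1e-6
        assert t.best_segment.strand == "+" and t.best_segment.n_codons >= 40
        assert f.truth == "false_positive" and f.verdict == "fail"
        assert f.p_value is None or f.p_value > 0.01

    def test_unmappable_exon_raises(self, mosaic_case, trained_matrix, calibration):
        aln, _, _ = mosaic_case
        bad = cs.ExonCall("mosaic", 5_000, 5_100, "+")
        with pytest.raises(UnmappableExonError):
            cs.test_exon(bad, aln, trained_matrix, calibration)

    def test_batch_converts_unmappable_to_failed_verdict(
        self, mosaic_case, trained_matrix, calibration
    ):
        aln, _, _ = mosaic_case
        bad = cs.ExonCall("mosaic", 5_000, 5_100, "+", name="off_end")
        out = cs.test_exons([bad], aln, trained_matrix, calibration)
        assert out[0].verdict == "fail" and "off_end" in out[0].reason

    def test_flank_extends_window(self, mosaic_case, trained_matrix, calibration):
        aln, _, _ = mosaic_case
        # a 33-nt sliver of the true exon: with a large flank the scan window
        # covers the full exon and the best segment score must not decrease
        sliver = cs.ExonCall("mosaic", 660, 693, "+")
        no_flank = cs.test_exon(sliver, aln, trained_matrix, calibration, flank=0)
        flanked = cs.test_exon(sliver, aln, trained_matrix, calibration, flank=150)
        assert flanked.best_segment.score >= no_flank.best_segment.score

    def test_evaluate_before_after(self, mosaic_case):
        _, annotations, tested = mosaic_case
        before, after = cs.evaluate(tested, annotations)
        assert (before.tp, before.fp, before.fn) == (1, 1, 0)
        assert (after.tp, after.fp, after.fn) == (1, 0, 0)
        assert after.ppv == 1.0 and before.ppv == 0.5

    def test_missed_annotation_counts_as_fn(self, mosaic_case):
        _, annotations, tested = mosaic_case
        only_false = [c for c in tested if c.truth == "false_positive"]
        before, _ = cs.evaluate(only_false, annotations)
        assert before.fn == 1


class TestRoc:
    def test_boundary_alphas_and_monotonicity(self, mosaic_case):
        _, annotations, tested = mosaic_case
        grid = [0.0, 1e-10, 1e-4, 0.01, 0.5, 1.0]
        roc = roc_points(tested, annotations, grid, sequence_length=3_000)
        assert (roc.tpr.diff().dropna() >= 0).all()  # tpr non-decreasing in alpha
        assert (roc.fpr.diff().dropna() >= 0).all()
        at_one = roc[roc.alpha == 1.0].iloc[0]
        # at alpha 1 every call carrying a p-value passes: the true 180-nt
        # prediction fully covers the 180-nt exon
        assert at_one.tpr == 1.0
        assert "fpr_conventional" in roc.columns
        assert (roc.fpr_conventional <= roc.fpr + 1e-12).all()

    def test_tiny_alpha_keeps_only_the_real_exon(self, mosaic_case):
        _, annotations, tested = mosaic_case
        roc = roc_points(tested, annotations, [1e-6])
        assert roc.iloc[0].tpr == 1.0 and roc.iloc[0].fp_nt == 0


class TestLengthBins:
    def test_single_bin_matches_overall_ppv(self, mosaic_case):
        _, _, tested = mosaic_case
        table = bin_ppv_by_exon_length(tested, [0, 10_000])
        before, _ = cs.evaluate(tested)
        assert len(table) == 1
        assert table.iloc[0].ppv_before == pytest.approx(before.ppv)
        assert table.iloc[0].n == len(tested)

    def test_empty_bin_is_nan(self, mosaic_case):
        _, _, tested = mosaic_case
        table = bin_ppv_by_exon_length(tested, [0, 1, 10_000])
        assert table.iloc[0].n == 0 and math.isnan(table.iloc[0].ppv_before)

    def test_calls_to_table_shape(self, mosaic_case):
        _, _, tested = mosaic_case
        df = cs.calls_to_table(tested)
        assert len(df) == len(tested)
        assert {"name", "truth", "best_score", "p_value", "verdict"} <= set(df.columns)
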