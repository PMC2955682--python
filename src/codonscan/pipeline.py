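"""Filtering externally predicted exons and evaluating the effect.

Each predicted exon is tested against the pairwise genomic alignment: the
alignment window spanning the exon (plus an optional flank) is scanned in
all six framings, the best locally maximal segment score S is converted to
a Karlin–Altschul P-value with N equal to the window's nucleotide length,
and the exon passes the filter iff P <= alpha (default 0.01) and a
positive-scoring segment exists at all.

Evaluation reproduces the standard summary statistics.  Note the
false-positive rate is reported with denominator TP + FN, matching the
formula block of the source method, alongside the conventional
FP / (FP + TN) where TN is countable (nucleotide level).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .alignment import PairwiseAlignment
from .errors import MalformedIntervalError, ParameterError, UnmappableExonError
from .kastats import CalibrationResult, is_significant, pvalue
from .matrix import CodonSubstitutionMatrix
from .segments import SegmentPair, scan_alignment


@dataclass
class ExonCall:
    """One predicted exon with its truth label and filter verdict."""

    seq_id: str
    start: int  # 0-based half-open, on the ungapped target row
    end: int
    strand: str
    source: str = ""
    name: str = ""
    truth: str = "unknown"  # true_positive / false_positive / unknown
    best_segment: SegmentPair | None = None
    p_value: float | None = None
    verdict: str | None = None  # pass / fail
    reason: str | None = None

    def __post_init__(self):
        if self.start >= self.end or self.start < 0:
            raise MalformedIntervalError(
                f"{self.name or self.seq_id}: bad interval [{self.start}, {self.end})"
            )

    @property
    def n_codons(self) -> int:
        return (self.end - self.start) // 3


@dataclass
class EvaluationTable:
    """TP/FP/FN counts with the derived rates (exon- or nucleotide-level)."""

    tp: int
    fp: int
    fn: int = 0
    tn: int | None = None
    level: str = "exon"

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def fpr(self) -> float:
        """FP / (TP + FN) — the method's printed definition."""
        return self.fp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def fpr_conventional(self) -> float | None:
        """FP / (FP + TN); only defined where TN is countable."""
        if self.tn is None:
            return None
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else float("nan")


def _calls_from_frame(df: pd.DataFrame) -> list[ExonCall]:
    return [
        ExonCall(
            seq_id=row["seq_id"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"],
            source=str(row.get("source", "")),
            name=str(row.get("name", "")),
        )
        for _, row in df.iterrows()
    ]


def label_predictions(
    predictions: "pd.DataFrame | Sequence[ExonCall]",
    annotations: pd.DataFrame,
    min_overlap: int = 1,
) -> list[ExonCall]:
    """Exon-level truth labels by same-strand overlap with annotations.

    A predicted exon is a true positive iff it overlaps an annotated exon on
    the same strand and sequence by at least ``min_overlap`` nucleotides
    (default 1 bp — boundary mismatches are accepted).
    """
    if isinstance(predictions, pd.DataFrame):
        calls = _calls_from_frame(predictions)
    else:
        calls = list(predictions)
    ann = annotations
    for call in calls:
        hit = False
        sub = ann[(ann.seq_id == call.seq_id) & (ann.strand == call.strand)]
        for _, a in sub.iterrows():
            overlap = min(call.end, a.end) - max(call.start, a.start)
            if overlap >= min_overlap:
                hit = True
                break
        call.truth = "true_positive" if hit else "false_positive"
    return calls


def test_exon(
    exon: ExonCall,
    alignment: PairwiseAlignment,
    matrix: CodonSubstitutionMatrix,
    calib: CalibrationResult,
    alpha: float = 0.01,
    flank: int = 0,
) -> ExonCall:
    """Complete one exon call: best segment, P-value, verdict.

    The exon's declared strand is recorded but does not constrain the scan
    (all six framings are searched regardless).  Raises UnmappableExonError
    if the interval falls outside the alignment's target row.
    """
    len_a = alignment.pos_to_col_a.size
    w_start = max(0, exon.start - flank)
    w_end = min(len_a, exon.end + flank)
    if exon.start >= len_a or exon.end > len_a or w_start >= w_end:
        raise UnmappableExonError(
            f"{exon.name or exon.seq_id}: interval [{exon.start},{exon.end}) "
            f"outside target row of length {len_a}"
        )
    c_start, c_end = alignment.columns_for_interval_a(w_start, w_end)
    window = alignment.slice_columns(c_start, c_end)
    hits = scan_alignment(window, matrix, cutoff=0.0)
    n_window = w_end - w_start
    if not hits:
        return replace(exon, best_segment=None, p_value=None, verdict="fail",
                       reason="no positive-scoring segment")
    best = max(hits, key=lambda h: h.score)
    p = pvalue(best.score, n_window, calib.k, calib.a)
    best.p_value = p
    verdict = "pass" if is_significant(p, alpha) else "fail"
    return replace(exon, best_segment=best, p_value=p, verdict=verdict, reason=None)


def test_exons(
    calls: Iterable[ExonCall],
    alignment: PairwiseAlignment,
    matrix: CodonSubstitutionMatrix,
    calib: CalibrationResult,
    alpha: float = 0.01,
    flank: int = 0,
) -> list[ExonCall]:
    """Batch variant of :func:`test_exon`; unmappable exons fail with a reason."""
    out = []
    for call in calls:
        try:
            out.append(test_exon(call, alignment, matrix, calib, alpha=alpha, flank=flank))
        except UnmappableExonError as exc:
            out.append(replace(call, verdict="fail", reason=str(exc)))
    return out


def _count_fn(calls: list[ExonCall], annotations: pd.DataFrame | None) -> int:
    """Annotated exons not overlapped (same strand) by any call in the list."""
    if annotations is None or annotations.empty:
        return 0
    fn = 0
    for _, a in annotations.iterrows():
        covered = any(
            c.seq_id == a.seq_id
            and c.strand == a.strand
            and min(c.end, a.end) - max(c.start, a.start) >= 1
            for c in calls
        )
        fn += not covered
    return fn


def evaluate(
    calls: list[ExonCall], annotations: pd.DataFrame | None = None
) -> tuple[EvaluationTable, EvaluationTable]:
    """Exon-level counts before (all predictions) and after (verdict pass)."""
    passing = [c for c in calls if c.verdict == "pass"]
    before = EvaluationTable(
        tp=sum(c.truth == "true_positive" for c in calls),
        fp=sum(c.truth == "false_positive" for c in calls),
        fn=_count_fn(calls, annotations),
    )
    after = EvaluationTable(
        tp=sum(c.truth == "true_positive" for c in passing),
        fp=sum(c.truth == "false_positive" for c in passing),
        fn=_count_fn(passing, annotations),
    )
    return before, after


def chi_square_filter_effect(
    before: tuple[int, int], after: tuple[int, int]
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table
    of TP/FP counts before vs after filtering."""
    table = np.array([before, after], dtype=float)
    if (table.sum(axis=0) <= 0).any() or (table.sum(axis=1) <= 0).any():
        raise ParameterError("degenerate 2x2 table: a margin is zero")
    res = chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# nucleotide-level ROC
# ---------------------------------------------------------------------------

def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _total(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)


def _intersection(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def roc_points(
    calls: list[ExonCall],
    annotations: pd.DataFrame,
    alpha_grid: Sequence[float],
    sequence_length: int | None = None,
) -> pd.DataFrame:
    """Nucleotide-level (fpr, tpr) per alpha threshold.

    A base is a true positive when covered by a passing prediction and by an
    annotated exon (strand-agnostic at the nucleotide level).  TPR and FPR
    use the method's denominators: annotated coding nucleotides (TP + FN).
    When ``sequence_length`` is given, TN is countable and the conventional
    FPR is reported too.  Calls must already carry P-values.
    """
    ann = _merge([(int(r.start), int(r.end)) for _, r in annotations.iterrows()])
    ann_nt = _total(ann)
    rows = []
    for alpha in alpha_grid:
        passing = [
            (c.start, c.end)
            for c in calls
            if c.p_value is not None and is_significant(c.p_value, alpha)
        ]
        cov = _merge(passing)
        tp = _intersection(cov, ann)
        pred_nt = _total(cov)
        fp = pred_nt - tp
        fn = ann_nt - tp
        row = {
            "alpha": alpha,
            "tp_nt": tp,
            "fp_nt": fp,
            "fn_nt": fn,
            "tpr": tp / ann_nt if ann_nt else float("nan"),
            "fpr": fp / ann_nt if ann_nt else float("nan"),
        }
        if sequence_length is not None:
            tn = (sequence_length - ann_nt) - fp
            row["tn_nt"] = tn
            row["fpr_conventional"] = fp / (fp + tn) if fp + tn else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def bin_ppv_by_exon_length(
    calls: list[ExonCall], bin_edges_in_codons: Sequence[float]
) -> pd.DataFrame:
    """PPV per exon-length bin (length in codons) before and after filtering.

    Empty bins yield NaN PPVs.
    """
    edges = list(bin_edges_in_codons)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = [c for c in calls if lo <= c.n_codons < hi]
        passing = [c for c in in_bin if c.verdict == "pass"]
        before, _ = evaluate(in_bin)
        after, _ = evaluate(passing)
        rows.append(
            {
                "length_lo": lo,
                "length_hi": hi,
                "n": len(in_bin),
                "ppv_before": before.ppv,
                "ppv_after": after.ppv,
            }
        )
    return pd.DataFrame(rows)


def calls_to_table(calls: list[ExonCall]) -> pd.DataFrame:
    """Per-exon result table (one row per prediction)."""
    rows = []
    for c in calls:
        b = c.best_segment
        rows.append(
            {
                "seq_id": c.seq_id,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "source": c.source,
                "name": c.name,
                "truth": c.truth,
                "best_score": b.score if b else float("nan"),
                "best_frame": b.frame if b else -1,
                "best_strand": b.strand if b else ".",
                "p_value": c.p_value if c.p_value is not None else float("nan"),
                "verdict": c.verdict,
                "reason": c.reason or "",
            }
        )
    return pd.DataFrame(rows)
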