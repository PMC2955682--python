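"""Six-frame codon-pair streams and locally maximal scoring segments.

A pairwise DNA alignment is read in all six framings — reading frames 0, 1
and 2 on the given strand, and the same three frames after reverse
complementing both rows together.  Columns containing a gap or an
ambiguity code in either row split the alignment into gap-free blocks;
codon framing restarts at each block, so segments never span a block
boundary and codon phase stays well defined without a gap penalty.

Within one framing, the region score of a stretch of codons is the sum of
their codon-pair matrix scores, and the segments of interest are the
locally maximal positive-scoring ones: segments whose score cannot be
improved by extending or shortening either end and which are not contained
in a higher-scoring such segment.  These are enumerated exactly with the
linear-time all-maximal-scoring-subsequences algorithm of Ruzzo and Tompa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignment import PairwiseAlignment
from .codons import CODONS
from .matrix import CodonSubstitutionMatrix

_POWERS = np.array([16, 4, 1])


@dataclass
class FrameView:
    """Gap-free codon-pair stream at one (frame, strand) framing.

    ``a_idx``/``b_idx`` are codon indices (0..63) per position; ``col_starts``
    holds, for each codon pair, the leftmost ORIGINAL alignment column of the
    three columns it came from (decreasing along the view on the '-' strand).
    """

    frame: int
    strand: str  # '+' or '-'
    a_idx: np.ndarray
    b_idx: np.ndarray
    col_starts: np.ndarray

    def __len__(self) -> int:
        return int(self.a_idx.size)

    @property
    def codon_pairs(self) -> list[tuple[str, str]]:
        return [(CODONS[a], CODONS[b]) for a, b in zip(self.a_idx, self.b_idx)]

    def scores(self, matrix: CodonSubstitutionMatrix) -> np.ndarray:
        return matrix.scores[self.a_idx, self.b_idx]


@dataclass
class SegmentPair:
    """A locally maximal scoring segment in one framing.

    ``start_codon``/``end_codon`` are 0-based half-open indices into the
    originating FrameView; ``col_start``/``col_end`` the half-open span of
    original alignment columns it covers.
    """

    frame: int
    strand: str
    start_codon: int
    end_codon: int
    score: float
    col_start: int
    col_end: int
    p_value: float | None = None

    @property
    def n_codons(self) -> int:
        return self.end_codon - self.start_codon


def _valid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open runs of True in a boolean array."""
    if valid.size == 0:
        return []
    v = valid.astype(np.int8)
    change = np.flatnonzero(np.diff(v)) + 1
    bounds = np.concatenate(([0], change, [v.size]))
    return [
        (int(bounds[i]), int(bounds[i + 1]))
        for i in range(len(bounds) - 1)
        if valid[bounds[i]]
    ]


def frame_views(alignment: PairwiseAlignment) -> list[FrameView]:
    """The six framed codon-pair streams of an alignment.

    Returns frames 0/1/2 on '+' then frames 0/1/2 on '-' (reverse complement
    of both rows).  A framing with fewer than 3 gap-free columns simply has
    zero codon pairs.
    """
    n = len(alignment)
    views: list[FrameView] = []
    for strand in "+-":
        if strand == "+":
            a, b = alignment.codes_a, alignment.codes_b
        else:
            a = np.where(alignment.codes_a >= 0, 3 - alignment.codes_a, -1)[::-1]
            b = np.where(alignment.codes_b >= 0, 3 - alignment.codes_b, -1)[::-1]
        runs = _valid_runs((a >= 0) & (b >= 0))
        for frame in range(3):
            ai_parts, bi_parts, col_parts = [], [], []
            for s, e in runs:
                s2 = s + frame
                m = (e - s2) // 3
                if m <= 0:
                    continue
                ai_parts.append(a[s2 : s2 + 3 * m].reshape(m, 3) @ _POWERS)
                bi_parts.append(b[s2 : s2 + 3 * m].reshape(m, 3) @ _POWERS)
                starts = s2 + 3 * np.arange(m)
                if strand == "-":
                    starts = n - 3 - starts
                col_parts.append(starts)
            cat = lambda parts: (
                np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
            )
            views.append(
                FrameView(
                    frame=frame,
                    strand=strand,
                    a_idx=cat(ai_parts),
                    b_idx=cat(bi_parts),
                    col_starts=cat(col_parts),
                )
            )
    return views


def region_score(
    view: FrameView, matrix: CodonSubstitutionMatrix, start: int, end: int
) -> float:
    """Sum of codon-pair scores over view positions [start, end)."""
    if not (0 <= start <= end <= len(view)):
        raise IndexError(f"range [{start}, {end}) out of bounds for view of {len(view)}")
    if start == end:
        return 0.0
    return float(matrix.scores[view.a_idx[start:end], view.b_idx[start:end]].sum())


def _ruzzo_tompa(sums: Sequence[float]) -> list[tuple[int, int, float]]:
    """All maximal scoring subsequences of a score vector (indices half-open).

    The search for the rightmost pending segment with a smaller left
    cumulative sum follows back-pointer chains (``prev``) rather than a
    linear stack walk, which keeps the whole pass linear-time even on long
    negative-drift inputs where a naive walk degrades to quadratic.
    """
    starts: list[int] = []
    ends: list[int] = []
    lsum: list[float] = []  # cumulative sum just before each pending segment
    rsum: list[float] = []  # cumulative sum at the end of each pending segment
    prev: list[int] = []  # index of rightmost earlier entry with smaller lsum
    cum = 0.0
    for i, x in enumerate(sums):
        if x <= 0:
            cum += x
            continue
        s0, s1, sl, sr = i, i + 1, cum, cum + x
        cum += x
        while True:
            j = len(lsum) - 1
            while j >= 0 and lsum[j] >= sl:
                j = prev[j]
            if j < 0 or rsum[j] >= sr:
                starts.append(s0)
                ends.append(s1)
                lsum.append(sl)
                rsum.append(sr)
                prev.append(j)
                break
            s0, sl = starts[j], lsum[j]
            del starts[j:], ends[j:], lsum[j:], rsum[j:], prev[j:]
    return [(s, e, r - l) for s, e, l, r in zip(starts, ends, lsum, rsum)]


def all_maximal_segments(
    scores: Sequence[float], cutoff: float = 0.0
) -> list[tuple[int, int, float]]:
    """Locally maximal scoring segments with score > cutoff, left to right.

    Consecutive same-sign scores are collapsed into runs first (a maximal
    segment always contains whole positive runs), then the Ruzzo–Tompa
    algorithm runs on the run sums.
    """
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        return []
    pos = (x > 0).astype(np.int8)
    change = np.flatnonzero(np.diff(pos)) + 1
    bounds = np.concatenate(([0], change, [x.size]))
    run_sums = np.add.reduceat(x, bounds[:-1])
    # a run of nonpositive elements can sum to exactly 0; force it nonpositive
    run_sums[pos[bounds[:-1]] == 0] = np.minimum(run_sums[pos[bounds[:-1]] == 0], 0.0)
    segs = _ruzzo_tompa(run_sums.tolist())
    return [
        (int(bounds[i]), int(bounds[j]), float(sc)) for i, j, sc in segs if sc > cutoff
    ]


def best_msp(view: FrameView, matrix: CodonSubstitutionMatrix) -> SegmentPair | None:
    """Single maximum-score segment of a view, or None if no positive segment.

    Ties are broken to the leftmost start, then the shortest segment.
    """
    if len(view) == 0:
        return None
    x = view.scores(matrix)
    best = 0.0
    best_span: tuple[int, int] | None = None
    cum = 0.0
    min_val, min_idx = 0.0, 0
    for j, v in enumerate(x, start=1):
        cum += v
        if cum - min_val > best:
            best = cum - min_val
            best_span = (min_idx, j)
        if cum < min_val:
            min_val, min_idx = cum, j
    if best_span is None:
        return None
    s, e = best_span
    return _segment(view, s, e, best)


def _segment(view: FrameView, s: int, e: int, score: float) -> SegmentPair:
    starts = view.col_starts[s:e]
    return SegmentPair(
        frame=view.frame,
        strand=view.strand,
        start_codon=int(s),
        end_codon=int(e),
        score=float(score),
        col_start=int(starts.min()),
        col_end=int(starts.max()) + 3,
    )


def scan_alignment(
    alignment: PairwiseAlignment,
    matrix: CodonSubstitutionMatrix,
    cutoff: float = 0.0,
) -> list[SegmentPair]:
    """All locally maximal segments above ``cutoff`` across the six framings.

    Results are sorted by alignment column span then (strand, frame) for
    determinism; framings are reported independently, with no overlap
    resolution between them.
    """
    hits: list[SegmentPair] = []
    for view in frame_views(alignment):
        scores = view.scores(matrix)
        for s, e, sc in all_maximal_segments(scores, cutoff):
            hits.append(_segment(view, s, e, sc))
    hits.sort(key=lambda h: (h.col_start, h.col_end, h.strand, h.frame))
    return hits
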