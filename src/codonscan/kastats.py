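"""Extreme-value statistics for segment scores.

Under a non-coding null model, the best local region score S found in a
search of length N nucleotides follows one-dimensional Karlin–Altschul
statistics: the probability that the null produces a locally maximal
segment scoring above S is approximately

    P = k * N * exp(-a * S),

with constants k and a that depend on the scoring matrix and the null
base composition.  The constants are estimated purely by simulation, as
the method prescribes: synthetic non-coding alignment pairs are scanned
with the same six-framing segment search used on real queries, the scores
of all locally maximal segments are pooled and binned, and a log-linear
least-squares fit of the bin proportions against score yields a from the
slope and k from the intercept.

Because calibration uses the very scan applied at query time, the
six-fold framing multiplicity is absorbed into k, and N is always the
nucleotide length of the region searched.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .alignment import PairwiseAlignment
from .codons import decode_bases
from .errors import CalibrationError, ParameterError
from .matrix import CodonSubstitutionMatrix
from .segments import scan_alignment


@dataclass
class NullModel:
    """Parameters of the simulated non-coding (null) alignment model.

    Defaults emulate mammalian intergenic comparison: GC content 0.40 and
    30% substituted sites (so 70% pairwise identity), searched as 100
    sequences of 100 kb.
    """

    gc_content: float = 0.40
    divergence: float = 0.30
    seq_length: int = 100_000
    n_sequences: int = 100
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.gc_content <= 1.0):
            raise ParameterError(f"gc_content must be in [0,1], got {self.gc_content}")
        if not (0.0 <= self.divergence <= 1.0):
            raise ParameterError(f"divergence must be in [0,1], got {self.divergence}")
        if self.seq_length <= 0 or self.n_sequences <= 0:
            raise ParameterError("seq_length and n_sequences must be positive")


def replacement_kernel(gc_content: float) -> np.ndarray:
    """Substitution kernel used at mutated sites, rows indexed A,C,G,T.

    Zero on the diagonal (a substituted site always changes) and chosen so
    the distribution of the new base, averaged over the stationary
    composition, equals the stationary composition itself — the expected GC
    content of the mutated sequence is exactly preserved.  Among kernels
    with that property the maximum-entropy one is used; it reduces to the
    uniform choice over the three alternatives at GC = 0.5.
    """
    g = float(gc_content)
    K = np.zeros((4, 4))
    if g <= 0.0:  # pure A/T background
        K[0, 3] = K[3, 0] = 1.0
        K[1] = K[2] = [0.5, 0.0, 0.0, 0.5]
        return K
    if g >= 1.0:  # pure G/C background
        K[1, 2] = K[2, 1] = 1.0
        K[0] = K[3] = [0.0, 0.5, 0.5, 0.0]
        return K

    # rows A/T: prob t to the complementary AT base, c to each GC base;
    # rows C/G: prob u to the complementary GC base, v to each AT base.
    # Stationarity forces c = g*v/(1-g); entropy is maximal when t*u = c*v.
    def _f(v: float) -> float:
        c = g * v / (1.0 - g)
        return (1.0 - 2.0 * c) * (1.0 - 2.0 * v) - c * v

    v_hi = min(0.5, (1.0 - g) / (2.0 * g))
    v = brentq(_f, 1e-12, v_hi - 1e-12)
    c = g * v / (1.0 - g)
    t, u = 1.0 - 2.0 * c, 1.0 - 2.0 * v
    K[0] = [0.0, c, c, t]  # A
    K[3] = [t, c, c, 0.0]  # T
    K[1] = [v, 0.0, u, v]  # C
    K[2] = [v, u, 0.0, v]  # G
    return K


def simulate_noncoding_pair(
    model: NullModel, rng: np.random.Generator | None = None
) -> PairwiseAlignment:
    """One gapless null alignment pair.

    An ancestral sequence is drawn i.i.d. with P(G)=P(C)=gc/2 and
    P(A)=P(T)=(1-gc)/2, then exactly round(divergence * length) positions,
    chosen uniformly without replacement, are replaced with a different
    base via :func:`replacement_kernel`, so realized identity is exactly
    1 - divergence and expected GC is unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    L = model.seq_length
    g = model.gc_content
    p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    anc = rng.choice(4, size=L, p=p).astype(np.int8)
    n_sub = int(round(model.divergence * L))
    if n_sub > L:
        raise ParameterError("divergence * length exceeds sequence length")
    der = anc.copy()
    if n_sub:
        sites = rng.choice(L, size=n_sub, replace=False)
        K = replacement_kernel(g)
        old = anc[sites]
        new = np.empty(n_sub, dtype=np.int8)
        for base in range(4):
            mask = old == base
            cnt = int(mask.sum())
            if cnt:
                new[mask] = rng.choice(4, size=cnt, p=K[base]).astype(np.int8)
        der[sites] = new
    return PairwiseAlignment(
        decode_bases(anc), decode_bases(der), id_a="null_a", id_b="null_b"
    )


def collect_null_segments(
    model: NullModel,
    matrix: CodonSubstitutionMatrix,
    score_cutoff: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Scores of every locally maximal segment found in n_sequences null pairs."""
    if rng is None:
        rng = np.random.default_rng(model.seed)
    scores: list[float] = []
    for _ in range(model.n_sequences):
        aln = simulate_noncoding_pair(model, rng)
        scores.extend(h.score for h in scan_alignment(aln, matrix, cutoff=score_cutoff))
    return np.asarray(scores, dtype=float)


@dataclass
class CalibrationResult:
    """Fitted Karlin–Altschul constants with regression diagnostics."""

    k: float
    a: float
    r_squared: float
    regression_points: list[tuple[float, float]]
    bin_width: float = 1.0
    n_segments: int = 0
    null_model: NullModel | None = None
    matrix_id: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regression_points"] = [list(p) for p in self.regression_points]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        d = dict(d)
        if d.get("null_model") is not None:
            d["null_model"] = NullModel(**d["null_model"])
        d["regression_points"] = [tuple(p) for p in d["regression_points"]]
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_karlin_altschul(
    scores: np.ndarray,
    bin_width: float = 1.0,
    *,
    n_sequences: int = 1,
    search_length: int = 1,
    min_bin_count: int = 10,
    null_model: NullModel | None = None,
    matrix_id: str = "",
) -> CalibrationResult:
    """Estimate (k, a) from pooled null segment scores by log-linear regression.

    Scores are binned with the given width; the proportion of segments per
    bin is regressed (ordinary least squares on its natural log) against the
    bin-center score.  Bins with fewer than ``min_bin_count`` segments are
    excluded: a near-empty far-tail bin carries a log proportion with huge
    sampling error and would otherwise get full leverage on the slope.  The
    slope gives a = -slope.  For the intercept c,
    the expected bin proportion under P = k N exp(-a S) with M pooled
    segments from n_sequences searches of length N is

        proportion(s) = n_sequences * k * N * exp(-a s) * 2 sinh(a w / 2) / M,

    so k = exp(c) * M / (n_sequences * N * 2 sinh(a w / 2)).  Empty bins are
    dropped (their log is undefined).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise CalibrationError("no segment scores to calibrate on")
    if np.any(scores < 0):
        raise CalibrationError("segment scores must be non-negative")
    idx = np.floor(scores / bin_width).astype(int)
    counts = np.bincount(idx)
    centers = (np.arange(counts.size) + 0.5) * bin_width
    mask = counts >= max(1, min_bin_count)
    if mask.sum() < 2:
        mask = counts > 0  # tiny samples: fall back to all occupied bins
    if mask.sum() < 2:
        raise CalibrationError("need at least 2 non-empty score bins")
    props = counts[mask] / scores.size
    x, y = centers[mask], np.log(props)
    res = stats.linregress(x, y)
    a = -res.slope
    if a <= 0:
        raise CalibrationError(f"no exponential decay in score distribution (a={a:.4g})")
    k = (
        math.exp(res.intercept)
        * scores.size
        / (n_sequences * search_length * 2.0 * math.sinh(a * bin_width / 2.0))
    )
    return CalibrationResult(
        k=k,
        a=a,
        r_squared=float(res.rvalue**2),
        regression_points=list(zip(centers[mask].tolist(), np.log(props).tolist())),
        bin_width=bin_width,
        n_segments=int(scores.size),
        null_model=null_model,
        matrix_id=matrix_id,
    )


def calibrate(
    model: NullModel,
    matrix: CodonSubstitutionMatrix,
    score_cutoff: float = 0.0,
    bin_width: float = 1.0,
    rng: np.random.Generator | None = None,
    matrix_id: str = "",
) -> CalibrationResult:
    """Simulate the null, collect segment scores, and fit (k, a)."""
    scores = collect_null_segments(model, matrix, score_cutoff=score_cutoff, rng=rng)
    return fit_karlin_altschul(
        scores,
        bin_width=bin_width,
        n_sequences=model.n_sequences,
        search_length=model.seq_length,
        null_model=model,
        matrix_id=matrix_id,
    )


def pvalue(score: float, search_length_nt: int, k: float, a: float) -> float:
    """P that a null search of N nucleotides yields a segment scoring > S.

    Computed as min(1, k * N * exp(-a * S)); monotone decreasing in S and
    linear in N below the cap.
    """
    if search_length_nt <= 0:
        raise ParameterError("search length must be positive")
    if k <= 0 or a <= 0:
        raise ParameterError("k and a must be positive")
    if not math.isfinite(score):
        raise ParameterError("score must be finite")
    return min(1.0, k * search_length_nt * math.exp(-a * score))


def is_significant(p: float, alpha: float) -> bool:
    """True iff p <= alpha (boundary inclusive)."""
    if not (0.0 <= p <= 1.0 and 0.0 <= alpha <= 1.0):
        raise ParameterError("p and alpha must lie in [0, 1]")
    return p <= alpha
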