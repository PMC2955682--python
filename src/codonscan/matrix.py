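"""Empirical codon-pair log-odds scoring matrices.

The scoring core of the method: aligned in-frame codon pairs from
orthologous coding sequences are tallied into a 64x64 count table; each
pair's score is the natural-log ratio of its (symmetrized) observed
frequency to its expected frequency,

    score(a, b) = ln( q(a, b) / e(a, b) ).

The expected frequency is built from the observed aligned NUCLEOTIDE-pair
frequencies of the same training columns, averaged over the three codon
positions: for codons a = x1 x2 x3 and b = y1 y2 y3,

    e(a, b) = p(x1, y1) * p(x2, y2) * p(x3, y3),

with p the pooled per-site pair frequency.  This cancels overall sequence
similarity and base composition, so the score measures how the three
aligned sites behave *jointly* relative to sites behaving independently —
the periodic, third-position-biased substitution pattern of coding
regions.  Raw identity is therefore roughly score-neutral: a run of
identical codons in diverged non-coding homology gains little, while the
synonymous-substitution pattern of real coding alignments scores strongly
positive (the mean score under the training pair distribution is the
Kullback-Leibler divergence KL(q || e) > 0), which is what makes
Karlin-Altschul statistics applicable to the null (its expected score is
negative).

Scores are kept in nats as plain floats; no integer scaling is applied,
so downstream extreme-value constants are estimated on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alignment import PairwiseAlignment
from .codons import CODONS, codon_index, encode_bases
from .errors import EmptyCountsError, MalformedAlignmentError, MatrixFormatError

AlignmentLike = "PairwiseAlignment | tuple[str, str]"


def _rows(aln) -> tuple[str, str]:
    if isinstance(aln, PairwiseAlignment):
        return aln.seq_a, aln.seq_b
    a, b = aln
    return a, b


@dataclass
class CodonPairCounts:
    """Raw tally of aligned codon pairs, indexed (codon_a, codon_b)."""

    counts: np.ndarray
    total_pairs: int = 0

    @classmethod
    def zeros(cls) -> "CodonPairCounts":
        return cls(np.zeros((64, 64), dtype=np.int64), 0)


def count_codon_pairs(alignments: Iterable) -> CodonPairCounts:
    """Tally codon pairs from in-frame aligned CDS pairs.

    Alignment columns are grouped into consecutive triplets starting at the
    first column (frame 0 of row 1 is the reading frame).  A codon column
    contributes one count only when both triplets consist solely of
    {A,C,G,T}: any gap or ambiguity code (N etc.) in either row excludes
    that column.  A trailing partial triplet is ignored.
    """
    out = CodonPairCounts.zeros()
    for aln in alignments:
        sa, sb = _rows(aln)
        if len(sa) != len(sb):
            raise MalformedAlignmentError(
                f"rows differ in gapped length: {len(sa)} vs {len(sb)}"
            )
        n = (len(sa) // 3) * 3
        if n == 0:
            continue
        a = encode_bases(sa)[:n].reshape(-1, 3)
        b = encode_bases(sb)[:n].reshape(-1, 3)
        ok = (a >= 0).all(axis=1) & (b >= 0).all(axis=1)
        ai = a[ok] @ np.array([16, 4, 1])
        bi = b[ok] @ np.array([16, 4, 1])
        np.add.at(out.counts, (ai, bi), 1)
        out.total_pairs += int(ok.sum())
    return out


@dataclass
class CodonSubstitutionMatrix:
    """64x64 symmetric log-odds scores (nats) with frequency metadata.

    ``marginals`` are the codon frequencies of the symmetrized training
    table; ``nt_pair_freqs`` the 4x4 pooled aligned nucleotide-pair
    frequencies the expectation was built from.
    """

    scores: np.ndarray
    marginals: np.ndarray
    pseudocount: float = 0.5
    provenance: str = ""
    nt_pair_freqs: np.ndarray | None = None

    def score(self, codon_a: str, codon_b: str) -> float:
        return float(self.scores[codon_index(codon_a), codon_index(codon_b)])

    def write(self, path: str | Path) -> None:
        write_matrix(self, path)

    @classmethod
    def read(cls, path: str | Path) -> "CodonSubstitutionMatrix":
        return read_matrix(path)


# per-position one-hot maps: _SITE_ONEHOT[s] is 64x4, codon -> base at site s
_SITE_CODES = np.array(
    [["ACGT".index(ch) for ch in codon] for codon in CODONS]
)  # 64x3
_SITE_ONEHOT = [np.eye(4)[_SITE_CODES[:, s]] for s in range(3)]


def nt_pair_freqs_from_q(q: np.ndarray) -> np.ndarray:
    """Pooled aligned nucleotide-pair frequencies of a codon-pair distribution.

    Averages the per-position pair frequencies over the three codon sites;
    symmetric whenever q is, and its cells sum to 1.
    """
    p = np.zeros((4, 4))
    for s in range(3):
        p += _SITE_ONEHOT[s].T @ q @ _SITE_ONEHOT[s]
    return p / 3.0


def lod_from_counts(counts: CodonPairCounts, pseudocount: float = 0.5) -> CodonSubstitutionMatrix:
    """Turn a codon-pair count table into a log-odds matrix.

    Counts are symmetrized as (c(a,b) + c(b,a)) / 2 first — the direction
    of the genome comparison is arbitrary — then a pseudocount is added to
    every cell and the normalizer adjusted so frequencies still sum to 1.
    The expected frequency of a pair is the product of its three pooled
    nucleotide-pair frequencies (see module docstring).  With pseudocount
    0 an unobserved pair yields a -inf score (permitted).
    """
    if counts.total_pairs <= 0:
        raise EmptyCountsError("cannot build a log-odds matrix from zero codon pairs")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    sym = (counts.counts + counts.counts.T) / 2.0
    total = sym.sum()
    q = (sym + pseudocount) / (total + pseudocount * 64 * 64)
    marginals = q.sum(axis=1)
    p = nt_pair_freqs_from_q(q)
    expected = np.ones((64, 64))
    for s in range(3):
        expected *= p[_SITE_CODES[:, None, s], _SITE_CODES[None, :, s]]
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.log(q) - np.log(expected)
    scores[q == 0] = -np.inf  # only possible with pseudocount 0
    return CodonSubstitutionMatrix(
        scores=scores,
        marginals=marginals,
        pseudocount=pseudocount,
        nt_pair_freqs=p,
    )


def score_codon_pair(matrix: CodonSubstitutionMatrix, codon_a: str, codon_b: str) -> float:
    """Score of one aligned codon pair; symmetric in its arguments."""
    return matrix.score(codon_a, codon_b)


# ---------------------------------------------------------------------------
# TSV serialization: '#' metadata lines, a header row of the 64 codon labels,
# then 64 data rows (row label + 64 scores).  Cells are written with 17
# significant digits so a round trip reproduces scores exactly.
# ---------------------------------------------------------------------------

def write_matrix(matrix: CodonSubstitutionMatrix, path: str | Path) -> None:
    lines = [
        "# codon-pair log-odds matrix",
        "# log_base=e",
        f"# pseudocount={float(matrix.pseudocount)!r}",
        f"# provenance={matrix.provenance.replace(chr(10), ' ')}",
        "# marginals=" + ",".join(f"{m:.17g}" for m in matrix.marginals),
        "# nt_pair_freqs="
        + (
            ",".join(f"{v:.17g}" for v in matrix.nt_pair_freqs.ravel())
            if matrix.nt_pair_freqs is not None
            else ""
        ),
        "codon\t" + "\t".join(CODONS),
    ]
    for i, label in enumerate(CODONS):
        lines.append(label + "\t" + "\t".join(f"{s:.17g}" for s in matrix.scores[i]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix(path: str | Path) -> CodonSubstitutionMatrix:
    meta: dict[str, str] = {}
    header: Sequence[str] | None = None
    rows: dict[str, np.ndarray] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            if fields[0].lower() != "codon" or len(fields) != 65:
                raise MatrixFormatError(
                    f"{path}:{lineno}: expected header 'codon' + 64 codon labels"
                )
            header = fields[1:]
            if sorted(header) != sorted(CODONS):
                raise MatrixFormatError(f"{path}:{lineno}: header is not the 64 codons")
            continue
        if len(fields) != 65:
            raise MatrixFormatError(f"{path}:{lineno}: expected 65 fields, found {len(fields)}")
        try:
            rows[fields[0]] = np.array([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise MatrixFormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if header is None:
        raise MatrixFormatError(f"{path}: missing header row")
    if sorted(rows) != sorted(CODONS):
        raise MatrixFormatError(f"{path}: expected 64 data rows, found {len(rows)}")

    # map by codon label, not file position
    col_order = np.array([codon_index(c) for c in header])
    scores = np.empty((64, 64))
    for label, values in rows.items():
        scores[codon_index(label), col_order] = values

    marg_txt = meta.get("marginals")
    if marg_txt is None:
        raise MatrixFormatError(f"{path}: missing '# marginals=' metadata line")
    marginals_in_header_order = np.array([float(x) for x in marg_txt.split(",")])
    if marginals_in_header_order.size != 64:
        raise MatrixFormatError(f"{path}: marginals line must carry 64 values")
    marginals = np.empty(64)
    marginals[col_order] = marginals_in_header_order
    ntp_txt = meta.get("nt_pair_freqs", "")
    nt_pair_freqs = (
        np.array([float(x) for x in ntp_txt.split(",")]).reshape(4, 4) if ntp_txt else None
    )
    return CodonSubstitutionMatrix(
        scores=scores,
        marginals=marginals,
        pseudocount=float(meta.get("pseudocount", "nan")),
        provenance=meta.get("provenance", ""),
        nt_pair_freqs=nt_pair_freqs,
    )
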