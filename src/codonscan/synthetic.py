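"""Synthetic data: coding alignments, null alignments, and genomic mosaics.

The coding generator produces the qualitative substitution signature that
separates coding from non-coding homology — synonymous exchanges (mostly
third-position changes) far outnumbering amino-acid-changing ones — using
synonymous classes from the standard genetic code rather than a full
parametric codon model.  Mosaics embed such coding blocks in a simulated
non-coding background with truth annotations, giving a complete miniature
benchmark for the filtering pipeline with no external data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .alignment import PairwiseAlignment
from .errors import ParameterError
from . import io as _io
from .kastats import NullModel, calibrate, simulate_noncoding_pair
from .matrix import count_codon_pairs, lod_from_counts

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS: tuple[str, ...] = tuple(_STANDARD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.forward_table))
AMINO_ACID: dict[str, str] = dict(_STANDARD.forward_table)

#: codon -> tuple of OTHER codons encoding the same amino acid
SYNONYMS: dict[str, tuple[str, ...]] = {
    c: tuple(sorted(x for x in SENSE_CODONS if x != c and AMINO_ACID[x] == AMINO_ACID[c]))
    for c in SENSE_CODONS
}

_BASES = "ACGT"
_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class CodingModel:
    """Generator settings for one orthologous CDS alignment.

    Rates are per-codon event probabilities: ``synonymous_rate`` is the
    chance a codon undergoes one synonymous codon exchange, and
    ``nonsynonymous_rate`` the chance of one amino-acid-changing single
    nucleotide substitution; synonymous_rate > nonsynonymous_rate gives the
    third-position-biased difference pattern of real coding alignments.
    """

    n_codons: int = 200
    synonymous_rate: float = 0.4
    nonsynonymous_rate: float = 0.05
    codon_usage: np.ndarray | None = None  # 61 frequencies over SENSE_CODONS
    seed: int = 0

    def __post_init__(self):
        for name in ("synonymous_rate", "nonsynonymous_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise ParameterError(f"{name} must be in [0,1] (per-codon probability)")
        if self.n_codons <= 0:
            raise ParameterError("n_codons must be positive")
        if self.codon_usage is not None:
            u = np.asarray(self.codon_usage, dtype=float)
            if u.size != len(SENSE_CODONS) or abs(u.sum() - 1.0) > 1e-9 or (u < 0).any():
                raise ParameterError("codon_usage must be 61 non-negative values summing to 1")
            self.codon_usage = u


def simulate_coding_alignment(
    model: CodingModel, rng: np.random.Generator | None = None
) -> PairwiseAlignment:
    """One gapless in-frame CDS alignment pair; never contains in-frame stops."""
    if rng is None:
        rng = np.random.default_rng(model.seed)
    usage = model.codon_usage
    if usage is None:
        usage = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    anc = [SENSE_CODONS[i] for i in rng.choice(len(SENSE_CODONS), size=model.n_codons, p=usage)]
    der: list[str] = []
    for codon in anc:
        cur = codon
        if SYNONYMS[cur] and rng.random() < model.synonymous_rate:
            alts = SYNONYMS[cur]
            cur = alts[rng.integers(len(alts))]
        if rng.random() < model.nonsynonymous_rate:
            for _ in range(20):  # rejection: must change the amino acid, never a stop
                pos = int(rng.integers(3))
                base = _BASES[int(rng.integers(4))]
                if base == cur[pos]:
                    continue
                cand = cur[:pos] + base + cur[pos + 1 :]
                if cand not in STOP_CODONS and AMINO_ACID[cand] != AMINO_ACID[cur]:
                    cur = cand
                    break
        der.append(cur)
    return PairwiseAlignment("".join(anc), "".join(der), id_a="cds_a", id_b="cds_b")


def build_training_set(
    model: CodingModel, n_pairs: int, rng: np.random.Generator | None = None
) -> list[PairwiseAlignment]:
    """Independent coding alignment pairs for matrix training."""
    if rng is None:
        rng = np.random.default_rng(model.seed)
    return [simulate_coding_alignment(model, rng) for _ in range(n_pairs)]


@dataclass
class MosaicSpec:
    """Layout of a synthetic genomic alignment: coding blocks in null background."""

    total_length: int
    exon_blocks: list[tuple[int, int, str]]  # (start position, n_codons, strand)
    background: NullModel = field(default_factory=NullModel)
    seed: int = 0

    def __post_init__(self):
        spans = sorted((p, p + 3 * n) for p, n, _ in self.exon_blocks)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if e1 > s2:
                raise ParameterError(f"exon blocks overlap: [{s1},{e1}) and [{s2},{e2})")
        for s, e in spans:
            if s < 0 or e > self.total_length:
                raise ParameterError(f"exon block [{s},{e}) outside [0,{self.total_length})")


def build_mosaic(
    spec: MosaicSpec,
    coding_model: CodingModel,
    rng: np.random.Generator | None = None,
    seq_id: str = "mosaic",
) -> tuple[PairwiseAlignment, pd.DataFrame]:
    """Null background with coding blocks spliced in; returns truth annotations.

    Minus-strand blocks are generated as coding alignments and reverse
    complemented before insertion.  Annotations are 0-based half-open
    intervals on the (gapless) target row.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    bg_model = NullModel(
        gc_content=spec.background.gc_content,
        divergence=spec.background.divergence,
        seq_length=spec.total_length,
        n_sequences=1,
        seed=spec.background.seed,
    )
    bg = simulate_noncoding_pair(bg_model, rng)
    row_a, row_b = list(bg.seq_a), list(bg.seq_b)
    records = []
    for i, (pos, n_codons, strand) in enumerate(spec.exon_blocks):
        block = simulate_coding_alignment(
            CodingModel(
                n_codons=n_codons,
                synonymous_rate=coding_model.synonymous_rate,
                nonsynonymous_rate=coding_model.nonsynonymous_rate,
                codon_usage=coding_model.codon_usage,
            ),
            rng,
        )
        sa, sb = block.seq_a, block.seq_b
        if strand == "-":
            sa = "".join(_RC[c] for c in reversed(sa))
            sb = "".join(_RC[c] for c in reversed(sb))
        row_a[pos : pos + 3 * n_codons] = sa
        row_b[pos : pos + 3 * n_codons] = sb
        records.append(
            {
                "seq_id": seq_id,
                "start": pos,
                "end": pos + 3 * n_codons,
                "strand": strand,
                "name": f"exon_{i}",
                "source": "truth",
            }
        )
    aln = PairwiseAlignment(
        "".join(row_a), "".join(row_b), id_a=seq_id, id_b=seq_id + "_informant"
    )
    annotations = pd.DataFrame(
        records, columns=["seq_id", "start", "end", "strand", "name", "source"]
    )
    return aln, annotations


def _jitter_interval(start, end, total, rng, max_shift=6):
    s = max(0, start + int(rng.integers(-max_shift, max_shift + 1)))
    e = min(total, end + int(rng.integers(-max_shift, max_shift + 1)))
    if e - s < 30:
        s, e = start, end
    return s, e


def make_predictions(
    annotations: pd.DataFrame,
    spec: MosaicSpec,
    rng: np.random.Generator,
    n_false: int = 8,
    false_len_range: tuple[int, int] = (60, 300),
) -> pd.DataFrame:
    """Exon predictions: the true blocks with jittered boundaries plus false
    intervals placed in the un-annotated background."""
    rows = []
    for _, ann in annotations.iterrows():
        s, e = _jitter_interval(ann.start, ann.end, spec.total_length, rng)
        rows.append((ann.seq_id, s, e, ann.strand, f"pred_{ann['name']}"))
    blocks = sorted((p, p + 3 * n) for p, n, _ in spec.exon_blocks)
    made = 0
    attempts = 0
    seq_id = annotations.seq_id.iloc[0] if len(annotations) else "mosaic"
    while made < n_false and attempts < 50 * n_false:
        attempts += 1
        length = int(rng.integers(false_len_range[0], false_len_range[1] + 1))
        start = int(rng.integers(0, max(1, spec.total_length - length)))
        end = start + length
        if any(start < be and bs < end for bs, be in blocks):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((seq_id, start, end, strand, f"pred_false_{made}"))
        made += 1
    df = pd.DataFrame(rows, columns=["seq_id", "start", "end", "strand", "name"])
    df["source"] = "synthetic_finder"
    return df.sort_values(["start", "end"]).reset_index(drop=True)


def make_fixture_bundle(outdir: str | Path, seed: int = 42) -> dict:
    """Write a complete miniature experiment and its manifest.

    Contents: matrix training alignments, the trained matrix, a null
    calibration, a mosaic alignment with truth annotations, and exon
    predictions containing planted true and false positives.  Everything is
    deterministic per seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    coding = CodingModel(n_codons=200)
    training = build_training_set(coding, n_pairs=60, rng=rng)
    _io.write_paired_fasta(training, outdir / "training_alignments.fasta")
    mat = lod_from_counts(count_codon_pairs(training), pseudocount=0.5)
    mat.provenance = f"synthetic training set, seed={seed}"
    mat.write(outdir / "matrix.tsv")

    null = NullModel(seq_length=5_000, n_sequences=60, seed=seed)
    calib = calibrate(null, mat, rng=np.random.default_rng(rng.integers(2**31)))
    calib.save(outdir / "calibration.json")

    spec = MosaicSpec(
        total_length=12_000,
        exon_blocks=[(1_500, 80, "+"), (4_000, 50, "-"), (7_500, 120, "+")],
        background=NullModel(seq_length=12_000, n_sequences=1, seed=seed),
        seed=seed,
    )
    mosaic, annotations = build_mosaic(spec, coding, rng=rng)
    mosaic.to_fasta(outdir / "mosaic.fasta")
    _io.write_gff3(annotations, outdir / "annotations.gff3", source="truth")
    _io.write_bed(annotations, outdir / "annotations.bed")
    predictions = make_predictions(annotations, spec, rng, n_false=6)
    _io.write_gff3(predictions, outdir / "predictions.gff3", source="synthetic_finder")

    files = sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "seed": seed,
        "files": {
            name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
            for name in files
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
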