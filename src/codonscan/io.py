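"""Readers and writers for the tabular interchange formats.

Interval tables are held as pandas DataFrames with 0-based half-open
``start``/``end`` columns internally; BED stays 0-based half-open on disk
and GFF3 is converted to/from its 1-based closed convention.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import PairwiseAlignment
from .errors import MalformedAlignmentError

INTERVAL_COLUMNS = ["seq_id", "start", "end", "strand", "name", "source"]


def read_paired_fasta(path: str | Path) -> list[PairwiseAlignment]:
    """Aligned FASTA with 2n records paired consecutively."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2:
        raise MalformedAlignmentError(f"{path}: odd number of records ({len(records)})")
    return [
        PairwiseAlignment(
            str(records[i].seq), str(records[i + 1].seq), records[i].id, records[i + 1].id
        )
        for i in range(0, len(records), 2)
    ]


def write_paired_fasta(alignments: list[PairwiseAlignment], path: str | Path) -> None:
    records = []
    for i, aln in enumerate(alignments):
        records.append(SeqRecord(Seq(aln.seq_a), id=f"{aln.id_a}_{i}", description=""))
        records.append(SeqRecord(Seq(aln.seq_b), id=f"{aln.id_b}_{i}", description=""))
    SeqIO.write(records, str(path), "fasta")


def read_intervals(path: str | Path) -> pd.DataFrame:
    """Load BED6 or GFF3 intervals by file extension into the internal table."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return read_gff3(path)
    if path.suffix.lower() == ".bed":
        return read_bed(path)
    raise ValueError(f"unrecognised interval format: {path.suffix!r} (want .bed/.gff3)")


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["seq_id", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    df["source"] = "bed"
    return df[INTERVAL_COLUMNS]


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["score"] = out.get("score", 0)
    out[["seq_id", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gff3(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=[
            "seq_id", "source", "type", "start", "end",
            "score", "strand", "phase", "attributes",
        ],
    )
    raw = raw[raw["type"].isin(["exon", "CDS"])].copy()
    raw["start"] = raw["start"].astype(int) - 1  # to 0-based half-open
    raw["end"] = raw["end"].astype(int)
    names = raw["attributes"].str.extract(r"ID=([^;]+)", expand=False)
    fallback = pd.Series([f"feature_{i}" for i in range(len(raw))], index=raw.index)
    raw["name"] = names.fillna(fallback)
    return raw[INTERVAL_COLUMNS].reset_index(drop=True)


def write_gff3(
    df: pd.DataFrame, path: str | Path, source: str = "codonscan", feature: str = "exon"
) -> None:
    lines = ["##gff-version 3"]
    for i, row in df.reset_index(drop=True).iterrows():
        name = row["name"] if "name" in row and pd.notna(row["name"]) else f"feature_{i}"
        score = row["score"] if "score" in row and pd.notna(row.get("score")) else "."
        lines.append(
            "\t".join(
                [
                    str(row["seq_id"]), source, feature,
                    str(int(row["start"]) + 1), str(int(row["end"])),
                    str(score), str(row["strand"]), ".", f"ID={name}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_hits(hits, alignment: PairwiseAlignment, path: str | Path) -> None:
    """Segment hits as a TSV with alignment-column and per-sequence coordinates."""
    rows = []
    for h in hits:
        cols = alignment.col_to_pos_a[h.col_start : h.col_end]
        pos_a = cols[cols >= 0]
        cols = alignment.col_to_pos_b[h.col_start : h.col_end]
        pos_b = cols[cols >= 0]
        rows.append(
            {
                "alignment_id": alignment.id_a,
                "strand": h.strand,
                "frame": h.frame,
                "col_start": h.col_start,
                "col_end": h.col_end,
                "start_a": int(pos_a.min()) if pos_a.size else -1,
                "end_a": int(pos_a.max()) + 1 if pos_a.size else -1,
                "start_b": int(pos_b.min()) if pos_b.size else -1,
                "end_b": int(pos_b.max()) + 1 if pos_b.size else -1,
                "n_codons": h.n_codons,
                "score": h.score,
                "p_value": h.p_value if h.p_value is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
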