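"""Pairwise alignment container with column/sequence coordinate maps."""

from __future__ import annotations

from functools import cached_property
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import encode_bases
from .errors import MalformedAlignmentError

GAP = "-"


class PairwiseAlignment:
    """Two gapped DNA sequences of equal length.

    Row ``a`` is conventionally the target genome (the one carrying exon
    coordinates); row ``b`` the informant genome.  Coordinate maps between
    alignment columns and ungapped sequence positions are built lazily.
    """

    def __init__(self, seq_a: str, seq_b: str, id_a: str = "seq_a", id_b: str = "seq_b"):
        if len(seq_a) != len(seq_b):
            raise MalformedAlignmentError(
                f"rows differ in gapped length: {len(seq_a)} vs {len(seq_b)}"
            )
        self.seq_a = seq_a.upper()
        self.seq_b = seq_b.upper()
        self.id_a = id_a
        self.id_b = id_b

    def __len__(self) -> int:
        return len(self.seq_a)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PairwiseAlignment({self.id_a!r}, {self.id_b!r}, columns={len(self)})"

    # -- per-row nucleotide codes (gap/ambiguity = -1) -------------------
    @cached_property
    def codes_a(self) -> np.ndarray:
        return encode_bases(self.seq_a)

    @cached_property
    def codes_b(self) -> np.ndarray:
        return encode_bases(self.seq_b)

    # -- coordinate maps --------------------------------------------------
    @staticmethod
    def _nongap_mask(seq: str) -> np.ndarray:
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        return (raw != ord(GAP)) & (raw != ord("."))

    @cached_property
    def col_to_pos_a(self) -> np.ndarray:
        """Ungapped position of each column in row a; -1 at gap columns."""
        m = self._nongap_mask(self.seq_a)
        return np.where(m, np.cumsum(m) - 1, -1)

    @cached_property
    def col_to_pos_b(self) -> np.ndarray:
        m = self._nongap_mask(self.seq_b)
        return np.where(m, np.cumsum(m) - 1, -1)

    @cached_property
    def pos_to_col_a(self) -> np.ndarray:
        return np.flatnonzero(self._nongap_mask(self.seq_a))

    @cached_property
    def pos_to_col_b(self) -> np.ndarray:
        return np.flatnonzero(self._nongap_mask(self.seq_b))

    @property
    def ungapped_a(self) -> str:
        return self.seq_a.replace(GAP, "").replace(".", "")

    @property
    def ungapped_b(self) -> str:
        return self.seq_b.replace(GAP, "").replace(".", "")

    # -- derived alignments ------------------------------------------------
    def reverse_complement(self) -> "PairwiseAlignment":
        """Both rows complemented and reversed together (columns stay paired)."""
        return PairwiseAlignment(
            str(Seq(self.seq_a).reverse_complement()),
            str(Seq(self.seq_b).reverse_complement()),
            id_a=self.id_a,
            id_b=self.id_b,
        )

    def slice_columns(self, start: int, end: int) -> "PairwiseAlignment":
        """Sub-alignment over columns [start, end)."""
        return PairwiseAlignment(
            self.seq_a[start:end], self.seq_b[start:end], id_a=self.id_a, id_b=self.id_b
        )

    def columns_for_interval_a(self, start: int, end: int) -> tuple[int, int]:
        """Alignment-column span covering positions [start, end) of ungapped row a."""
        pos = self.pos_to_col_a
        if start < 0 or end > pos.size or start >= end:
            raise MalformedAlignmentError(
                f"interval [{start}, {end}) outside row a of length {pos.size}"
            )
        return int(pos[start]), int(pos[end - 1]) + 1

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path) -> "PairwiseAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 2:
            raise MalformedAlignmentError(
                f"{path}: expected exactly 2 aligned records, found {len(records)}"
            )
        return cls(str(records[0].seq), str(records[1].seq), records[0].id, records[1].id)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(self.seq_a), id=self.id_a, description=""),
            SeqRecord(Seq(self.seq_b), id=self.id_b, description=""),
        ]
        SeqIO.write(records, str(path), "fasta")
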