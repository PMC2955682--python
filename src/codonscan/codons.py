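"""Codon alphabet utilities.

Codons are indexed lexicographically over A < C < G < T, so index 0 is AAA
and index 63 is TTT; nucleotide codes are A=0, C=1, G=2, T=3.  The code for
the reverse complement of a base b is therefore 3 - b.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidCodonError

BASES = "ACGT"

#: the 64 codons in fixed lexicographic order, AAA ... TTT
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

CODON_TO_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode_bases(seq: str) -> np.ndarray:
    """Map a string to nucleotide codes; gaps, N and other ambiguity become -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def decode_bases(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_bases` for arrays with no -1 entries."""
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def codon_index(codon: str) -> int:
    """Index of a codon in the fixed AAA..TTT order.

    Raises
    ------
    InvalidCodonError
        If the argument is not a triplet over {A,C,G,T} (case-insensitive).
    """
    try:
        return CODON_TO_INDEX[codon.upper()]
    except (KeyError, AttributeError):
        raise InvalidCodonError(f"not an unambiguous codon: {codon!r}") from None
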