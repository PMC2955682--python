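"""Exception hierarchy."""


class CodonScanError(Exception):
    """Base class for all package errors."""


class MalformedAlignmentError(CodonScanError):
    """Alignment rows have unequal gapped length or are otherwise unusable."""


class InvalidCodonError(CodonScanError):
    """A codon argument is not a triplet over {A,C,G,T}."""


class EmptyCountsError(CodonScanError):
    """A log-odds matrix was requested from a count table with no pairs."""


class MatrixFormatError(CodonScanError):
    """A matrix file violates the documented TSV dialect."""


class CalibrationError(CodonScanError):
    """Null-model calibration could not be performed (too few bins, no decay)."""


class ParameterError(CodonScanError):
    """A numeric parameter is outside its admissible range."""


class UnmappableExonError(CodonScanError):
    """A predicted exon interval does not map into the supplied alignment."""


class MalformedIntervalError(CodonScanError):
    """An interval has start >= end or negative coordinates."""
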