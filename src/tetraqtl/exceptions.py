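"""Exception hierarchy for tetraqtl."""


class TetraQTLError(Exception):
    """Base class for all tetraqtl errors."""


class FormatError(TetraQTLError):
    """A file does not conform to the expected format."""


class SizingError(TetraQTLError):
    """A request cannot be satisfied by the available data (too few
    genotypes, genes that do not fit on a chromosome, ...)."""


class ConfigurationError(TetraQTLError):
    """Inconsistent or impossible configuration values."""


class DataError(TetraQTLError):
    """Invalid data values (negative counts, off-chromosome positions)."""


class DegenerateGroupError(TetraQTLError):
    """A statistical operation received a group too small to test."""


class AlignmentError(TetraQTLError):
    """Per-trait result sets do not share the same SNP universe."""


class NumericError(TetraQTLError):
    """A numerical prerequisite failed (e.g. a kinship matrix that is not
    positive semidefinite within tolerance)."""
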