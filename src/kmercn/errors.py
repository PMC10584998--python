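"""Exception hierarchy shared across the package."""


class KmerCNError(Exception):
    """Base class for all kmercn errors."""


class ConfigError(KmerCNError):
    """Invalid parameter combination or region configuration."""


class CoordinateError(KmerCNError):
    """Region coordinates fall outside the reference sequence."""


class FormatError(KmerCNError):
    """Malformed input file (FASTA/FASTQ/TSV database)."""


class EstimationError(KmerCNError):
    """Copy-number estimation impossible (e.g. zero flank coverage)."""
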