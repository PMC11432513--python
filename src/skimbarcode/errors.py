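"""Exception hierarchy shared across the package."""


class SkimBarcodeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SkimBarcodeError):
    """Malformed input file (FASTA, TSV, YAML, newick)."""


class AlignmentError(SkimBarcodeError):
    """Sequences that should form an alignment do not (e.g. ragged lengths)."""


class MissingSampleError(SkimBarcodeError):
    """A sample expected in every region is absent from one of them."""


class ConfigError(SkimBarcodeError):
    """Invalid simulation or pipeline configuration."""


class SaturationError(SkimBarcodeError):
    """K2P distance undefined: substitution saturation or no comparable sites."""


class DelimitationError(SkimBarcodeError):
    """A delimitation criterion cannot be evaluated (e.g. masked distances)."""
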