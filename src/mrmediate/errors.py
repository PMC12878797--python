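"""Exception hierarchy shared across the pipeline."""


class MRError(Exception):
    """Base class for all package errors."""


class FormatError(MRError):
    """Malformed or incomplete input table."""


class DomainError(MRError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class InsufficientInstrumentsError(MRError):
    """Too few retained variants for the requested method."""


class MissingSampleSizeError(MRError):
    """Operation requires per-trait sample sizes that were not supplied."""


class NoOverlapError(MRError):
    """Exposure and outcome tables share no variants."""
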