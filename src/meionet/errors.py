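"""Exception types shared across the pipeline."""


class MeionetError(Exception):
    """Base class for all pipeline errors."""


class ParseError(MeionetError):
    """A malformed input file; carries the offending line/cell location."""


class ConfigError(MeionetError):
    """Inconsistent or incomplete configuration."""


class WindowError(MeionetError):
    """A prophase window leaves too few timepoints for correlation."""


class UndefinedCorrelationError(MeionetError):
    """Pearson correlation undefined (zero-variance expression vector)."""


class UnannotatedGeneError(MeionetError):
    """A gene has no annotation in the requested GO namespace."""
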