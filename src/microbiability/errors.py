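"""Exception hierarchy for the pipeline."""


class MicrobiabilityError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MicrobiabilityError):
    """Invalid parameter, threshold, or config-file content."""


class EmptyTableError(MicrobiabilityError):
    """A filter or intersection left no rows/columns."""


class SimulationError(MicrobiabilityError):
    """Synthetic-data generation failed (e.g. non-PSD kernel after jitter)."""


class FitError(MicrobiabilityError):
    """Model fitting failed (singular design, degenerate inputs)."""


class TableFormatError(MicrobiabilityError):
    """Malformed input file; message carries row/column coordinates."""
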