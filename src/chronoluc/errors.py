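"""Exception hierarchy used across the package."""


class ChronolucError(Exception):
    """Base class for all package errors."""


class SchemaError(ChronolucError):
    """A table is missing required columns or violates the trace schema."""


class AlignmentError(ChronolucError):
    """Wells in one trace set do not share a common time grid."""


class RegimeError(ChronolucError):
    """A light-regime description is malformed (gaps, overlaps, bad segments)."""


class SimulationError(ChronolucError):
    """Invalid generative parameters or a diverged integration."""


class AnalysisError(ChronolucError):
    """An analysis precondition is not met (missing window, too few peaks...)."""
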