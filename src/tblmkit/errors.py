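"""Exception hierarchy.

All validation failures derive from :class:`ValidationError` and name the
offending field in their message.
"""


class TblmError(Exception):
    """Base class for all package errors."""


class ValidationError(TblmError, ValueError):
    """An input violated a documented invariant; message names the field."""


class InsufficientDataError(TblmError, ValueError):
    """Too few samples for the requested operation."""


class DegenerateTraceError(TblmError, ValueError):
    """Trace carries no usable signal (e.g. non-positive onset current)."""


class ComparabilityError(TblmError, ValueError):
    """Two results were produced under incompatible protocols."""


class DomainError(TblmError, ValueError):
    """A physically meaningless parameter combination."""


class RangeError(TblmError, ValueError):
    """A root-finding target outside the attainable range of the model."""


class PresetLookupError(TblmError, KeyError):
    """Unknown scenario preset or barrier-model name."""


class ParseError(TblmError, ValueError):
    """Malformed input file; message carries line numbers where possible."""


class ConfigError(TblmError, ValueError):
    """Invalid or unknown pipeline configuration key."""


class PipelineStageError(TblmError, RuntimeError):
    """A pipeline stage failed; message carries stage name and input digest."""
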