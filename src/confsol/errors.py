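"""Exception hierarchy.

Every error raised by the library derives from :class:`ConfsolError` so
callers can catch the whole family at a pipeline boundary.
"""


class ConfsolError(Exception):
    """Base class for all confsol errors."""


class ParameterError(ConfsolError, ValueError):
    """A parameter is outside its allowed range."""


class DataError(ConfsolError, ValueError):
    """Input data violate a contract (non-finite target, negative half-width...)."""


class SchemaError(ConfsolError, KeyError):
    """Tables or matrices do not share the expected columns/IDs."""


class DegenerateInputError(ConfsolError, ValueError):
    """The input is formally valid but leaves nothing to compute on."""


class DegenerateNormalizationError(ConfsolError, ValueError):
    """A nonconformity denominator is exactly zero for some calibration sample."""

    def __init__(self, message: str, offending_ids=None):
        super().__init__(message)
        self.offending_ids = list(offending_ids) if offending_ids is not None else []


class StateError(ConfsolError, RuntimeError):
    """An object is used before the state it requires exists (unfitted model...)."""


class TableIOError(ConfsolError, ValueError):
    """A descriptor table could not be parsed; message carries row/column context."""
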