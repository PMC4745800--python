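"""Exception hierarchy for rppamet."""


class RppametError(Exception):
    """Base class for all rppamet errors."""


class DataError(RppametError, ValueError):
    """Malformed or inconsistent input data (parse failures, duplicate ids, NaNs)."""


class InsufficientDataError(DataError):
    """Too few observations to perform the requested operation."""


class DegenerateDataError(DataError):
    """Input is degenerate for the operation (constant vector, empty class, no events)."""


class CoverageError(RppametError, ValueError):
    """Too few metagene members present in an expression dataset to compute a score."""
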