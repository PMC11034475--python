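"""Exception hierarchy.

All package errors derive from :class:`PoremechError` so callers can catch
one base class.  The CLI maps :class:`ConfigError` to exit code 2 and
:class:`DataError` (and subclasses) to exit code 3.
"""


class PoremechError(Exception):
    """Base class for all errors raised by poremech."""


class ConfigError(PoremechError):
    """Invalid configuration, unknown model kind, missing calibration."""


class DataError(PoremechError):
    """Problem with input data (files, arrays, manifests)."""


class FormatError(DataError):
    """A file does not conform to the documented dialect.

    Carries the offending path and, where known, the line number.
    """

    def __init__(self, message: str, path=None, line=None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class SolverError(PoremechError):
    """The FvK boundary-value solver failed to converge.

    The parameter set is attached so a flagged curve can be reproduced.
    """

    def __init__(self, message: str, params: dict | None = None):
        super().__init__(message if params is None else f"{message} (params: {params})")
        self.params = params or {}
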