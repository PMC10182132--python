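"""Exception and warning types shared across the package."""


class DTDSMILError(Exception):
    """Base class for package errors."""


class ConfigurationError(DTDSMILError):
    """A config object or parameter combination is invalid."""


class DataError(DTDSMILError):
    """Input data violates a documented invariant (coords, shapes, ranges)."""


class NoTissueError(DataError):
    """An operation that requires at least one tissue patch received none."""


class ParseError(DTDSMILError):
    """A file could not be parsed; the message names the offending field/row."""


class DegenerateWarning(UserWarning):
    """A computation hit a documented degenerate case (e.g. all-equal scores)."""
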