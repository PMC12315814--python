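"""Exception types shared across the package."""


class SersmlError(Exception):
    """Base class for all package errors."""


class ParseError(SersmlError, ValueError):
    """A spectral or label file contains a malformed field."""


class AxisError(SersmlError, ValueError):
    """Wavenumber axis is non-monotonic or inconsistent across spectra."""


class EmptyInputError(SersmlError, ValueError):
    """An operation received an empty file or empty spectrum set."""


class ConfigurationError(SersmlError, ValueError):
    """A parameter value violates an operation's preconditions."""


class InputError(SersmlError, ValueError):
    """Numeric input is non-finite or shaped inconsistently."""


class LabelError(SersmlError, ValueError):
    """Class labels are degenerate (single class) or inconsistent."""


class DomainError(SersmlError, ValueError):
    """A quantity is outside its mathematical domain (e.g. zero mean for RSD)."""
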