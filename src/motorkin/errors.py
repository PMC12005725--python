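"""Exception hierarchy.

``MotorkinError`` is the base for everything the CLI maps to exit code 1
(user error); anything else escaping is an internal error (exit code 2).
"""


class MotorkinError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MotorkinError, ValueError):
    """A parameter violates its documented invariant."""


class InvalidInputError(MotorkinError, ValueError):
    """Input data violates a precondition (too short, wrong shape, ...)."""


class InsufficientDataError(MotorkinError, ValueError):
    """Not enough usable observations for the requested estimate."""


class FitError(MotorkinError, RuntimeError):
    """A least-squares or maximum-likelihood fit failed to converge."""


class ParseError(MotorkinError, ValueError):
    """A data file does not conform to its documented format."""


class ConfigError(MotorkinError, ValueError):
    """A run configuration violates the schema."""
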