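"""Exception hierarchy.

All failures raised by this package derive from :class:`PbkraError` so callers
can catch one base class; the CLI maps validation-type errors to exit code 2
and numerical failures to exit code 3.
"""


class PbkraError(Exception):
    """Base class for all package errors."""


class ValidationError(PbkraError, ValueError):
    """A parameter set violates a declared invariant or is missing a field."""


class SchemaError(ValidationError):
    """A config file is structurally malformed (duplicate ids, bad types)."""


class LookupFixtureError(PbkraError, KeyError):
    """An unknown fixture, tracker, family or parameter path was requested."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return str(self.args[0]) if self.args else ""


class ConfigurationError(PbkraError):
    """Model assembly failed (incompatible physiology/chemical combination)."""


class IntegrationError(PbkraError):
    """The ODE solver failed; carries the time at which it stopped."""

    def __init__(self, message: str, failure_time: float | None = None):
        super().__init__(message)
        self.failure_time = failure_time


class InputError(PbkraError, ValueError):
    """An operation received an empty or out-of-range argument."""
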