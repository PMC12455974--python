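"""Exception hierarchy shared across the package."""


class MgeBurdenError(Exception):
    """Base class for all package errors."""


class ValidationError(MgeBurdenError, ValueError):
    """An input object violates its structural invariants."""


class TargetNotFoundError(MgeBurdenError, KeyError):
    """A gene, reaction or metabolite id does not resolve."""


class SolverError(MgeBurdenError, RuntimeError):
    """The LP solver failed or returned a non-optimal status where one was required."""

    def __init__(self, message: str, status: str = "failed"):
        super().__init__(message)
        self.status = status


class IntegrationError(MgeBurdenError, ValueError):
    """Attaching a pseudoreaction or editing a model failed (missing species, id collision)."""


class ConfigurationError(MgeBurdenError, ValueError):
    """A run configuration or carriage state is inconsistent."""


class FormatError(MgeBurdenError, ValueError):
    """A file could not be parsed in the declared dialect."""
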