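"""Exception hierarchy shared across the package."""


class LakecohortsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LakecohortsError):
    """A simulation or analysis configuration is invalid."""


class DomainError(LakecohortsError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class InputError(LakecohortsError, ValueError):
    """An input table violates a structural precondition (e.g. duplicate ids)."""


class EstimationError(LakecohortsError):
    """An estimator cannot produce a value (e.g. zero marker hits)."""


class ParseError(LakecohortsError, ValueError):
    """A module DEFINITION string is malformed.

    Carries ``position``, the 0-based offset at which parsing failed.
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message if position is None else f"{message} (at position {position})")
        self.position = position


class DependencyError(LakecohortsError):
    """A required upstream artifact is missing from a run directory."""
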