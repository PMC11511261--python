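"""Exception hierarchy shared across the package."""


class PeonyforceError(Exception):
    """Base class for all package errors."""


class ValidationError(PeonyforceError, ValueError):
    """A table, design or rubric violates a structural invariant."""


class DomainError(PeonyforceError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class DesignError(ValidationError):
    """The group/factor assignment is not a valid orthogonal design."""
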