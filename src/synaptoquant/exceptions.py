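"""Exception hierarchy shared by all analysis stages."""


class SynaptoQuantError(Exception):
    """Base class for all package errors."""


class ValidationError(SynaptoQuantError, ValueError):
    """Malformed or inconsistent input data."""


class EmptyInputError(ValidationError):
    """An operation received an empty collection where at least one item is required."""


class DomainError(SynaptoQuantError, ValueError):
    """An argument is outside its mathematical domain."""


class FitFailureError(SynaptoQuantError, RuntimeError):
    """Model fitting failed to produce any usable candidate."""


class PipelineOrderError(SynaptoQuantError, RuntimeError):
    """A pipeline stage was invoked out of its documented order."""


class DegenerateCrossError(SynaptoQuantError, ValueError):
    """Every progeny class of a cross is lethal; no viable distribution exists."""
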