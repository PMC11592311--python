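"""Exception types for sensitivity computations."""


class LifsensError(Exception):
    """Base class for all package-specific errors."""


class NotFiredError(LifsensError):
    """A concrete spike train never drives the membrane potential to threshold."""


class NotFiredInExpectationError(LifsensError):
    """No index has an expected membrane potential reaching the threshold."""


class NoPredecessorError(LifsensError):
    """The firing index is 1, so no pre-firing moment exists."""


class SampleExcludedError(LifsensError):
    """A Monte-Carlo sample does not satisfy the firing preconditions."""


class EstimationUnreliableError(LifsensError):
    """More than half of the Monte-Carlo samples had to be excluded."""


class ConfigError(LifsensError):
    """A sweep configuration is malformed."""
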