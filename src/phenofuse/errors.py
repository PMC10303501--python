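"""Exception hierarchy used across the pipeline.

Every stage raises one of these so that the pipeline driver can tag
failures with the stage that produced them.
"""


class PhenofuseError(Exception):
    """Base class for all package errors."""


class ConfigError(PhenofuseError, ValueError):
    """Invalid or inconsistent configuration (unknown backbone, missing threshold, ...)."""


class DataError(PhenofuseError, ValueError):
    """Input data violates a stage precondition (empty group, missing class, ...)."""


class FormatError(PhenofuseError, ValueError):
    """An image or file does not have the expected format (e.g. not 3-channel RGB)."""


class ShapeError(PhenofuseError, ValueError):
    """Array shape mismatch between producer and consumer."""


class SizeError(PhenofuseError, ValueError):
    """An object does not fit the target canvas and overflow handling forbids rescale."""


class CapacityError(PhenofuseError, RuntimeError):
    """Object placement could not satisfy the non-overlap constraint within the attempt cap."""
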