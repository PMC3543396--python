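"""Exception hierarchy shared across the package.

Every error raised on purpose derives from :class:`MotionGateError`, so
callers (and the CLI) can separate expected failure modes from bugs.
"""


class MotionGateError(Exception):
    """Base class for all errors raised by motiongate."""


class StackFormatError(MotionGateError):
    """An input image stack violates the supported format contract
    (mixed dimensions, unsupported bit depth, unreadable pages)."""


class MetadataError(MotionGateError):
    """An acquisition-metadata sidecar is missing a required key or
    holds an invalid value."""


class ConfigurationError(MotionGateError):
    """A policy / filter / pipeline configuration violates an invariant."""


class ConsistencyError(MotionGateError):
    """Two objects that must describe the same frames disagree
    (e.g. a selection referencing unknown origin indices)."""


class DegenerateFrameError(MotionGateError):
    """A frame is unusable for estimation (blank or zero variance)."""
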