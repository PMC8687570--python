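"""Exception hierarchy for the posefreq pipeline.

Every stage raises a subclass of :class:`PosefreqError`, so callers (and the
command-line interface) can distinguish pipeline failures from programming
errors and report them with a nonzero exit status.
"""


class PosefreqError(Exception):
    """Base class for all posefreq pipeline errors."""


class KeypointFormatError(PosefreqError):
    """A keypoint JSON document violates the OpenPose dialect."""


class KeypointParseError(KeypointFormatError):
    """A keypoint JSON document is not syntactically valid JSON."""


class InsufficientDataError(PosefreqError):
    """Too few observed samples/events for the requested computation."""


class ParameterError(PosefreqError):
    """A configuration or simulation parameter is out of range."""


class TaskConfigError(PosefreqError):
    """A task specification cannot be applied to the given trajectories."""
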