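"""Exception hierarchy for the trajectory-morphometry pipeline.

Every anticipated failure mode maps to a distinct subclass of
:class:`TranssylvianError` so callers can catch narrowly and error
messages can name the offending subject, side, or landmark.
"""


class TranssylvianError(Exception):
    """Base class for all package-specific errors."""


class FrameMismatchError(TranssylvianError):
    """Operation mixed points carrying different coordinate-frame tags."""


class DegenerateLandmarkError(TranssylvianError):
    """Landmarks too close or collinear to define the requested geometry.

    Signals an unusable annotation (e.g. coincident AC and PC, or a
    mid-sagittal point lying on the AC-PC line).
    """


class DegenerateProjectionError(TranssylvianError):
    """Approach displacement nearly perpendicular to the left-right axis.

    The projection-plane angle is then dominated by annotation noise, so
    the measurement is refused rather than reported at ~90 degrees.
    """


class DegenerateLineError(TranssylvianError):
    """A reference line whose axial projection is too short to orient."""


class CoronalMismatchError(TranssylvianError):
    """Target-defining sulci were placed on different coronal slices."""


class UnknownLandmarkError(TranssylvianError):
    """A landmark name outside the canonical vocabulary."""


class MissingLandmarkError(TranssylvianError):
    """A required landmark is absent from a subject's set."""


class LandmarkParseError(TranssylvianError):
    """A landmark table could not be parsed; message identifies the record."""


class MaskFormatError(TranssylvianError):
    """A mask volume is unreadable or not a 3D image."""


class StatisticsError(TranssylvianError):
    """Invalid input to a cohort statistic (empty, mismatched, constant...)."""


class InvalidConfigError(TranssylvianError):
    """A generator or run configuration violates its invariants."""


class InvalidProfileError(TranssylvianError):
    """An inferior-horn profile violates its invariants."""
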