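"""Exception hierarchy for the screening pipeline.

Every module raises subclasses of :class:`DystoniaScreenError`, so callers can
catch one base type at a pipeline boundary while tests can assert on the
specific failure mode.
"""


class DystoniaScreenError(Exception):
    """Base class for all package-specific errors."""


# --- file / dialect validation -------------------------------------------------

class MalformedRow(DystoniaScreenError):
    """A CSV row does not parse under the declared dialect."""


class MissingLandmark(DystoniaScreenError):
    """A video frame lacks one of the 21 canonical hand landmarks."""


class NonMonotoneTime(DystoniaScreenError):
    """Timestamps are not strictly increasing."""


class NonUniformSampling(DystoniaScreenError):
    """Key-trace rows are not on a uniform 1 ms grid."""


class NegativeDisplacement(DystoniaScreenError):
    """A key displacement sample is below zero."""


class NoTemporalOverlap(DystoniaScreenError):
    """Landmark trajectory and key trace share no time span."""


class TaskTempoMismatch(DystoniaScreenError):
    """A fixed-tempo trial violates the 100 bpm (tasks 1-6) / 80 bpm (tasks 7-11) rule."""


# --- preprocessing -------------------------------------------------------------

class NoKeystrokeDetected(DystoniaScreenError):
    """No key excursion rises above the press threshold."""


class SegmentTooShort(DystoniaScreenError):
    """Fewer than 4 frames in the trial window; spline is underdetermined."""


class InvalidScale(DystoniaScreenError):
    """Augmentation scale factor is not strictly positive."""


# --- anomaly detector ----------------------------------------------------------

class TooFewParticipants(DystoniaScreenError):
    """Participant-level split needs at least 2 distinct participants."""


class TooFewErrors(DystoniaScreenError):
    """Threshold calibration needs at least 2 validation errors."""


class NonFiniteLoss(DystoniaScreenError):
    """Training loss became NaN or infinite."""


class ShapeMismatch(DystoniaScreenError):
    """Tensor shape does not match the model's expected input shape."""


class EmptyGroup(DystoniaScreenError):
    """A statistical comparison or evaluation group is empty."""


# --- biomechanics --------------------------------------------------------------

class ZeroMaxForce(DystoniaScreenError):
    """Maximum finger strength is zero; reduction ratio undefined."""


class ZeroDesignatedForce(DystoniaScreenError):
    """Designated-finger force is zero; independence index undefined."""


class ZeroReferenceSD(DystoniaScreenError):
    """Reference SD is zero; z-score undefined."""


class LengthMismatch(DystoniaScreenError):
    """Finger z-score vectors differ in length."""


class OutOfRangeP(DystoniaScreenError):
    """A p-value lies outside [0, 1]."""


# --- temporal order judgment ---------------------------------------------------

class DegeneratePrior(DystoniaScreenError):
    """ZEST prior has zero total mass."""


class OutOfGridSOA(DystoniaScreenError):
    """SOA lies outside the ZEST threshold grid."""
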