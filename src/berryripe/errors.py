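"""Exception hierarchy for berryripe.

Every error raised by the library derives from :class:`BerryRipeError`, so
callers (notably the batch pipeline, which must never abort on a single bad
instance) can catch one base class.
"""


class BerryRipeError(Exception):
    """Base class for all berryripe errors."""


class EmptyMask(BerryRipeError):
    """A mask contains no foreground pixels."""


class TooSmall(BerryRipeError):
    """The largest foreground component is below the minimum-area threshold."""


class DegenerateShape(BerryRipeError):
    """The mask boundary is too small to trace a meaningful contour."""


class CoincidentPoints(BerryRipeError):
    """Two distinct points were required but the same point was given twice."""


class NoOppositePoint(BerryRipeError):
    """No contour point lies on the far side of the centroid (pathological shape)."""


class EmptyRegion(BerryRipeError):
    """A quartile bin of the partition received zero pixels."""


class BadImage(BerryRipeError):
    """An image does not have the expected number of channels or dtype."""


class BadShape(BerryRipeError):
    """Invalid tensor or kernel shape for the self-calibrated convolution."""


class BadShapeParams(BerryRipeError):
    """Invalid parameters for the synthetic fruit-shape generator."""


class SchemaMismatch(BerryRipeError):
    """Prediction-time features do not match the schema the model was fitted on."""


class TooFewSamples(BerryRipeError):
    """Not enough samples per class for the requested cross-validation."""
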