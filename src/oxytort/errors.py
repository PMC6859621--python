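"""Exception hierarchy.

All domain errors derive from :class:`OxytortError`; most are also
``ValueError`` subclasses so that generic callers can catch them uniformly.
"""


class OxytortError(Exception):
    """Base class for all package errors."""


class ConfigError(OxytortError, ValueError):
    """Invalid or incomplete pipeline configuration."""


class InvalidSpecError(OxytortError, ValueError):
    """A synthetic vessel specification violates its invariants."""


class RenderRangeError(OxytortError, ValueError):
    """Requested SO2 falls outside the invertible range of the forward model."""


class InvalidGeometryError(OxytortError, ValueError):
    """Degenerate geometric parameters (e.g. annulus inner >= outer)."""


class NoVesselError(OxytortError, ValueError):
    """An intensity profile contains no usable vessel dip."""


class NoProfilesError(OxytortError, ValueError):
    """Too few usable intensity profiles to measure a segment."""


class InvalidMeasurementError(OxytortError, ValueError):
    """A measured quantity (ODR, SO2, ...) is non-finite or out of range."""


class InvalidSubjectError(OxytortError, ValueError):
    """Subject vitals are out of physiological range."""


class InvalidVitalsError(InvalidSubjectError):
    """Blood-pressure readings are inconsistent (e.g. DBP > SBP)."""


class TooShortError(OxytortError, ValueError):
    """A centerline has too few points for spline smoothing."""


class JoinError(OxytortError, ValueError):
    """Tables cannot be joined consistently (missing or duplicate ids)."""


class ModelError(OxytortError, ValueError):
    """A statistical model cannot be fit on the given table."""
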