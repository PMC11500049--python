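"""Exception hierarchy shared across the package."""


class VesselTortError(Exception):
    """Base class for all vesseltort errors."""


class EmptyMaskError(VesselTortError):
    """Raised when a segmentation map contains no vessel pixels."""


class TooShortError(VesselTortError):
    """Raised when a curve has too few samples / too little arc length."""


class DegenerateChordError(VesselTortError):
    """Raised when an arc-over-chord style ratio meets a (near-)zero chord."""


class DegenerateSpeedError(VesselTortError):
    """Raised when the curve parameterization has zero speed at a sample."""


class InvalidInputError(VesselTortError):
    """Raised for malformed inputs (bad rasters, bad specs, bad tables)."""


class ZeroVarianceError(VesselTortError):
    """Raised when a statistic is undefined because the data has no spread."""
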