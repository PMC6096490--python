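"""Typed exceptions raised across the package."""


class SharpmaxError(Exception):
    """Base class for all package-specific errors."""


class MapFormatError(SharpmaxError):
    """A map or model file could not be read, or violates v1 restrictions
    (non-orthogonal cell, degenerate grid)."""


class ResolutionError(SharpmaxError):
    """A resolution limit is inconsistent with the grid (below Nyquist) or
    with the available Fourier terms."""


class DegenerateMapError(SharpmaxError):
    """An operation requires a non-constant map (kurtosis, thresholding,
    molecule-mask detection) but the input has no contrast."""


class NotApplicableError(SharpmaxError):
    """The adjusted-surface-area criterion cannot be applied to this map
    (degenerate calibration or failed signal-to-noise test); callers should
    fall back to an alternative sharpening target or leave the map as is."""
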