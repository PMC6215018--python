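"""Exception and warning types shared across the package."""


class HiLoError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(HiLoError, ValueError):
    """A numeric parameter is outside its valid range."""


class ShapeError(HiLoError, ValueError):
    """Array dimensions do not match what an operation requires."""


class DataError(HiLoError, ValueError):
    """Input data violates a basic validity requirement (NaN, negative, ...)."""


class ConfigurationError(HiLoError, ValueError):
    """A combination of settings is internally inconsistent or infeasible."""


class GeometryError(HiLoError, ValueError):
    """A phantom/measurement geometry is physically inconsistent."""


class FitError(HiLoError, RuntimeError):
    """A curve fit failed to find a usable peak or to converge."""


class PairingError(HiLoError, ValueError):
    """Uniform/speckle sources could not be matched one-to-one."""


class FormatError(HiLoError, ValueError):
    """An image file is in an unsupported format or layout."""


class DegenerateSpectrumWarning(UserWarning):
    """The low-frequency spectrum vanished; the seam factor eta fell back to 1."""


class DegenerateGeometryWarning(UserWarning):
    """A degenerate geometry (e.g. zero tilt) makes a measurement trivially 0."""


class SpeckleLeakageWarning(UserWarning):
    """Speckle structure is likely to leak into the reconstructed image."""
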