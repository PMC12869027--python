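"""Typed exceptions shared across the package."""


class PatQuantError(Exception):
    """Base class for all package-specific errors."""


class ChromophoreLookupError(PatQuantError, KeyError):
    """Requested chromophore is not present in the extinction table."""


class WavelengthRangeError(PatQuantError, ValueError):
    """Requested wavelengths fall outside the tabulated range (no extrapolation)."""


class DegenerateMediumError(PatQuantError, ValueError):
    """Medium has zero scattering and zero absorption everywhere."""


class DegenerateSampleError(PatQuantError, ValueError):
    """Eigenspectra sampling mask selects voxels with zero fluence."""


class ConfigurationError(PatQuantError, ValueError):
    """Invalid run configuration (too few photons, bad wavelength count, ...)."""


class CompensationDomainError(PatQuantError, ValueError):
    """Compensating fluence spectrum is non-positive somewhere on the grid."""


class LogDomainError(PatQuantError, ValueError):
    """Non-positive fluence inside a log-linear fit range."""
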