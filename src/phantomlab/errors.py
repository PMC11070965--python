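"""Structured exceptions shared across the package."""


class PhantomLabError(Exception):
    """Base class for all package errors."""


class ParameterError(PhantomLabError, ValueError):
    """An argument is outside its documented domain."""


class GridMismatchError(PhantomLabError, ValueError):
    """Two spectral objects do not share wavelength grid and/or shape."""


class DivisionGuardError(PhantomLabError, ValueError):
    """A normalization denominator is non-positive; message names the offender."""


class SpectralRangeError(PhantomLabError, ValueError):
    """Requested wavelengths fall outside the available span."""


class ConfigurationError(PhantomLabError, ValueError):
    """An object is missing required configuration (scale, material, ...)."""


class UnsupportedRegimeError(PhantomLabError, ValueError):
    """Input is outside the numerically supported regime (e.g. extreme size parameter)."""


class ContractError(PhantomLabError, ValueError):
    """Caller violated an inter-operation contract (e.g. coated solver on a solid sphere)."""


class DensityError(PhantomLabError, RuntimeError):
    """Synthetic scene could not be packed at the requested density."""
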