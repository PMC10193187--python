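"""Exception types shared across the package."""


class MRKitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MRKitError):
    """Malformed input file, column mapping, or analysis configuration."""


class UndefinedRatioError(MRKitError):
    """Wald ratio requested for an instrument with zero exposure effect."""


class InsufficientInstrumentsError(MRKitError):
    """Too few instruments for the requested estimator."""


class MulticollinearityError(MRKitError):
    """Exposure effect matrix is rank deficient (collinear exposures)."""
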