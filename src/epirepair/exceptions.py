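"""Exception hierarchy for epirepair."""


class EpirepairError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(EpirepairError):
    """Invalid sheet geometry (e.g. ablation gap covering the whole sheet)."""


class CoincidentCellsError(EpirepairError):
    """Two cells at zero (or negative) separation; interaction undefined."""


class WindowError(EpirepairError):
    """A smoothing/binning window longer than the available trace."""


class InsufficientDataError(EpirepairError):
    """Not enough points, tracks or replicates for the requested analysis."""


class DegenerateDesignError(EpirepairError):
    """Regression design with no variation in the predictor."""


class NoInterceptError(EpirepairError):
    """Stretch-profile slope is non-negative; an x-intercept would be an
    extrapolation in the wrong direction and is not reported."""


class PairingError(EpirepairError):
    """Paired test requested on vectors of unequal length."""


class SchemaError(EpirepairError):
    """A CSV input is missing required columns or has invalid values."""


class ProfileError(EpirepairError):
    """Unknown or malformed parameter profile."""
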