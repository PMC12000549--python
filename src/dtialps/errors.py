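"""Exception hierarchy shared across the pipeline."""


class DtialpsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DtialpsError):
    """Invalid configuration (bad counts, non-PSD correlation matrix, ...)."""


class GeometryError(DtialpsError):
    """Regions or ROIs fall outside the image grid."""


class InputError(DtialpsError):
    """Malformed numeric input (negative b-value, singular affine, ...)."""


class RankDeficiencyError(InputError):
    """Too few usable diffusion directions for a tensor fit."""


class RoiFailureError(DtialpsError):
    """An ROI is empty or below the minimum usable voxel count."""

    def __init__(self, message: str, mask_name: str | None = None):
        super().__init__(message)
        self.mask_name = mask_name


class UndefinedIndexError(DtialpsError):
    """ALPS denominator is non-positive; the index is undefined."""


class DegenerateDesignError(DtialpsError):
    """Statistical design is degenerate (zero variance, singular matrix)."""


class SchemaError(DtialpsError):
    """A required column is missing from a table."""
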