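"""Exception types shared across the pipeline."""


class ScnetError(Exception):
    """Base class for all package-specific errors."""


class SpecificationError(ScnetError, ValueError):
    """A synthetic-cohort specification is invalid (e.g. non-PSD covariance)."""


class DataError(ScnetError, ValueError):
    """An input table violates a structural requirement."""


class DensityError(ScnetError, ValueError):
    """A requested graph density is unachievable for the given network."""
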