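"""Exception hierarchy for the eduquant pipeline.

Every failure mode the pipeline can hit on valid-looking but unusable input
gets its own class, so callers (and the CLI exit-code mapping) can tell
configuration mistakes apart from data-driven stage failures.
"""


class EduQuantError(Exception):
    """Base class for all eduquant errors."""


class ValidationError(EduQuantError):
    """Invalid arguments, inconsistent metadata, or malformed inputs."""


class ConfigError(ValidationError):
    """Experiment configuration file is missing fields or references."""


class FormatError(ValidationError):
    """An image file could not be read, names the offending file."""


class GeometryError(EduQuantError):
    """Synthetic region geometry could not be satisfied."""


class DegenerateThresholdError(EduQuantError):
    """A channel is uniformly constant, so no threshold separates it."""


class MaskConsistencyError(ValidationError):
    """Compartment masks violate the partition contract."""


class EmptyMaskError(EduQuantError):
    """An operation that needs a non-empty mask received an empty one."""


class InfeasibleRadiusError(EduQuantError):
    """Requested ROI radius does not fit inside the mask anywhere.

    ``largest_feasible_px`` is a strict upper bound on radii that do fit.
    """

    def __init__(self, radius_px: float, largest_feasible_px: float):
        self.radius_px = float(radius_px)
        self.largest_feasible_px = float(largest_feasible_px)
        super().__init__(
            f"no circle of radius {radius_px:g} px fits inside the mask; "
            f"feasible radii are < {largest_feasible_px:g} px"
        )


class UndefinedFractionError(EduQuantError):
    """Overlap fraction is undefined because there are no detections."""


class UndefinedComparisonError(EduQuantError):
    """Percent change is undefined because the control density is zero."""


class StageError(EduQuantError):
    """A pipeline stage failed; carries the stage name and sample id."""

    def __init__(self, stage: str, sample_id: str | None, cause: Exception):
        self.stage = stage
        self.sample_id = sample_id
        self.cause = cause
        where = f" on sample '{sample_id}'" if sample_id else ""
        super().__init__(f"stage '{stage}'{where} failed: {cause}")
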