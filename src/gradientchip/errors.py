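"""Exception hierarchy for the gradientchip pipeline."""


class GradientChipError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GradientChipError):
    """Invalid geometry, fluid, perfusion or pipeline configuration."""


class SolverError(GradientChipError):
    """Diffusion solver misuse, e.g. an unstable explicit step."""


class SteadyStateTimeoutError(GradientChipError):
    """Requested steady-state tolerance not reached within the time budget."""


class DensityError(GradientChipError):
    """Too many cells requested for non-overlapping placement."""


class RegistrationError(GradientChipError):
    """Image registration cannot proceed (e.g. zero-variance frame)."""


class DegenerateGradientError(GradientChipError):
    """Source and sink reference intensities are indistinguishable."""


class ExtrapolationError(GradientChipError):
    """Position outside the profiled span of the gradient axis."""


class InsufficientDataError(GradientChipError):
    """Not enough time points / cells for the requested statistic."""


class DegenerateDesignError(GradientChipError):
    """No concentration spread in the dose-response design."""


class FormatError(GradientChipError):
    """Malformed input file (wrong TIFF layout, truncated data, ...)."""


class PipelineError(GradientChipError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
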