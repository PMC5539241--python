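"""Exception hierarchy shared across the package."""


class CeusVVError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CeusVVError, ValueError):
    """A model or operation parameter violates its contract."""


class ConfigurationError(CeusVVError, ValueError):
    """A phantom, cohort, or run configuration is inconsistent."""


class EmptyRoiError(CeusVVError, ValueError):
    """A polygon ROI rasterizes to zero pixels on the target image."""

    def __init__(self, label: str, message: str | None = None):
        self.label = label
        super().__init__(message or f"ROI {label!r} covers no pixel centers")


class InvalidWindowError(CeusVVError, ValueError):
    """A background reference window contains no frames."""


class IntegrityError(CeusVVError, ValueError):
    """A cohort table violates a structural invariant."""


class DegenerateReferenceError(CeusVVError, ValueError):
    """Luminal enhancement is non-positive; normalization is undefined."""


class UndefinedCorrelationError(CeusVVError, ValueError):
    """Correlation requested on a constant variable."""


class StageError(CeusVVError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")
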