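"""Exception hierarchy shared across the pipeline stages."""


class CongradError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(CongradError):
    """Grids, affines or matrix shapes do not agree."""


class EmptyMaskError(CongradError):
    """A mask selects no voxels."""


class ArgumentError(CongradError, ValueError):
    """An argument is outside its documented domain."""


class ConfigurationError(CongradError):
    """A scenario or pipeline configuration violates an invariant."""


class ConnectivityError(CongradError):
    """The affinity graph is disconnected.

    Carries the component sizes so the caller can diagnose which part of
    the ROI broke off.
    """

    def __init__(self, component_sizes):
        self.component_sizes = tuple(sorted(component_sizes, reverse=True))
        super().__init__(
            f"affinity graph is disconnected: {len(self.component_sizes)} "
            f"components with sizes {self.component_sizes}"
        )


class DegenerateModeError(CongradError):
    """A gradient mode (or input field) is constant and cannot be scaled."""


class CollinearityError(CongradError):
    """A regression design matrix is rank deficient."""


class UndefinedCorrelationError(CongradError):
    """Correlation is undefined because one input is constant."""
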