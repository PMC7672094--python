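"""Exception hierarchy shared across the package."""


class ArchaeostyleError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ArchaeostyleError, ValueError):
    """An argument violates a documented precondition."""


class InfeasibleGeometryError(ArchaeostyleError, ValueError):
    """The requested geometric configuration cannot be realised."""


class UnreachableGapeError(InfeasibleGeometryError):
    """A gape angle beyond the maximum depression the hinge axis allows."""

    def __init__(self, requested: float, maximum: float):
        self.requested = requested
        self.maximum = maximum
        super().__init__(
            f"gape {requested:.3f} deg unreachable: maximum depression for this "
            f"hinge axis is {maximum:.3f} deg"
        )


class NoFitError(ArchaeostyleError, RuntimeError):
    """Axis calibration could not match any feasible hinge geometry."""


class MeshParseError(ArchaeostyleError, ValueError):
    """Malformed STL input; carries a best-effort byte offset."""

    def __init__(self, message: str, byte_offset: int | None = None):
        self.byte_offset = byte_offset
        if byte_offset is not None:
            message = f"{message} (at byte offset {byte_offset})"
        super().__init__(message)


class DegenerateConfigurationError(ArchaeostyleError, ValueError):
    """Landmark configuration is rank-deficient (e.g. collinear points)."""


class ReflectionRequiredError(ArchaeostyleError, ValueError):
    """Optimal landmark alignment would need an improper (reflecting) map."""


class NexusParseError(ArchaeostyleError, ValueError):
    """Structural problem in a NEXUS character matrix."""


class UndefinedIndexError(ArchaeostyleError, ZeroDivisionError):
    """Ensemble fit index undefined (no observed steps on any character)."""


class LeafSetMismatchError(ArchaeostyleError, ValueError):
    """Trees passed to a consensus do not share one leaf set."""


class ConfigError(ArchaeostyleError, ValueError):
    """Invalid pipeline configuration."""
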