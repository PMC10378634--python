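"""Exception hierarchy shared across the package."""


class ProtonbandError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ProtonbandError, ValueError):
    """An input value violates a documented precondition."""


class ConfigurationError(ProtonbandError, ValueError):
    """A cohort / run configuration is inconsistent or incomplete."""


class EmptyStructureError(ConfigurationError):
    """A structure mask is empty at the requested grid resolution."""

    def __init__(self, name: str, detail: str = ""):
        self.structure = name
        msg = f"structure {name!r} has an empty mask"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class NormalizationError(ProtonbandError, ValueError):
    """Plan normalization is impossible (e.g. zero dose on the primary target)."""


class DegenerateSampleError(ValidationError):
    """A statistical test received a sample it cannot handle."""

    def __init__(self, group: str, detail: str):
        self.group = group
        super().__init__(f"group {group!r}: {detail}")


class GeometryMismatchError(ValidationError):
    """Two voxel grids that must agree do not."""


class MissingFractionsError(ValidationError):
    """A shift log or dose archive has gaps in its fraction sequence."""
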