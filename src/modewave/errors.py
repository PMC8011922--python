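"""Exception hierarchy shared across the package."""


class ModewaveError(Exception):
    """Base class for all package-specific errors."""


class TrajectoryFormatError(ModewaveError):
    """Malformed trajectory file (bad frame header, inconsistent atom count, ...)."""


class UnknownElementError(ModewaveError, KeyError):
    """Element symbol not resolvable to an atomic mass."""


class InsufficientDataError(ModewaveError, ValueError):
    """Not enough frames/samples for the requested operation."""


class DimensionMismatchError(ModewaveError, ValueError):
    """Array dimensions of two objects do not line up."""


class InstabilityError(ModewaveError, ValueError):
    """A model that should be bound/PSD is not (negative force-constant eigenvalue,
    unbound Morse energy, ...)."""


class ResolutionWarning(UserWarning):
    """Spectral resolution of the available window is coarser than requested."""
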