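"""Exception types shared across the package."""


class CTDirNetError(Exception):
    """Base class for all package-specific errors."""


class DimensionalityError(CTDirNetError, ValueError):
    """An image file or array does not have the expected number of dimensions."""


class ConsistencyError(CTDirNetError, ValueError):
    """Two objects that must live on the same grid (or share names) do not."""


class ParameterError(CTDirNetError, ValueError):
    """A user-supplied parameter is outside its valid range."""


class GenerationError(CTDirNetError, RuntimeError):
    """A synthetic-data generator produced a degenerate object (e.g. an empty structure)."""


class ConvergenceError(CTDirNetError, RuntimeError):
    """An iterative procedure (rigid registration) failed to converge."""


class DegenerateInputError(CTDirNetError, ValueError):
    """Statistical input with no usable variation (e.g. zero-variance paired differences)."""


class WeightsFormatError(CTDirNetError, ValueError):
    """A saved-weights file is corrupt or inconsistent with the requested configuration."""
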