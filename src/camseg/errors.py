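"""Exception hierarchy.

Each failure mode the pipeline can hit on user data gets its own class so
callers (and the CLI) can report them distinctly.
"""


class CamsegError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedFormatError(CamsegError):
    """File extension is not a supported volume format (.nii/.nii.gz/.mha/.mhd)."""


class NonVolumePayloadError(CamsegError):
    """File payload is not a 3D scalar volume."""


class OutOfVocabularyLabelError(CamsegError):
    """A mask voxel holds a value outside the declared label set."""


class GeometryMismatchError(CamsegError):
    """Two grids that must share geometry (shape/spacing/origin) do not."""


class DegenerateInputError(CamsegError):
    """Input is degenerate for the requested operation (e.g. constant volume z-scored)."""


class ShapeError(CamsegError):
    """Array shapes are inconsistent with the operation's contract."""


class ConfigError(CamsegError):
    """Invalid configuration value or combination."""
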