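"""Exception hierarchy shared across phasefuse modules."""


class PhasefuseError(Exception):
    """Base class for all phasefuse errors."""


class ShapeError(PhasefuseError):
    """Image or array dimensions do not match what the operation requires."""


class ChannelError(PhasefuseError):
    """Operation received an image with the wrong channel kind (e.g. RGB expected)."""


class InvalidSizeError(PhasefuseError):
    """A requested output size is degenerate (below the minimum usable extent)."""


class InvalidBoxError(PhasefuseError):
    """Bounding box is malformed or falls outside the image bounds."""


class EmptyMaskError(PhasefuseError):
    """A binary mask with at least one foreground pixel was required."""


class DegenerateInputError(PhasefuseError):
    """Image content is degenerate for spectral analysis (e.g. all-zero)."""


class TransformError(PhasefuseError):
    """Affine transform is singular or otherwise unusable."""


class NoValidRegistrationError(PhasefuseError):
    """A scale sweep produced no registration that passed the validity gate.

    Carries per-scale diagnostics in ``diagnostics`` (list of dicts with
    ``scale``, ``peak_height`` and ``valid`` entries).
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class ConfigError(PhasefuseError):
    """Configuration file could not be parsed or contains unknown keys."""


class EmptyInputError(PhasefuseError):
    """An operation over a collection received an empty collection."""
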