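"""Exception hierarchy for the pspdti pipeline.

Every stage raises a subclass of :class:`PspdtiError` so callers (and the
CLI) can surface the failing stage without matching on message text.
"""


class PspdtiError(Exception):
    """Base class for all pspdti errors."""


class SizingError(PspdtiError):
    """The requested grid cannot accommodate the atlas structures."""


class ProtocolError(PspdtiError):
    """Diffusion acquisition scheme is insufficient for a tensor fit."""


class ParameterError(PspdtiError):
    """A numeric parameter is outside its admissible range."""


class ConfigurationError(PspdtiError):
    """Masks, paths, or run configuration are inconsistent."""


class SampleSizeError(PspdtiError):
    """A statistical comparison was requested with too few subjects."""


class DegenerateDesignError(PspdtiError):
    """A regression design is singular (e.g. all control ages equal)."""


class ScoringError(PspdtiError):
    """Pattern scoring is impossible (too many missing structures)."""


class StructuralError(PspdtiError):
    """A tract of interest has no underlying voxels."""


class FormatError(PspdtiError):
    """A file on disk does not parse as the expected format."""
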