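"""Exception hierarchy for the mmpso_s package."""


class MMPSOError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MMPSOError, ValueError):
    """An image, mask or threshold argument violates its contract."""


class ConfigError(MMPSOError, ValueError):
    """A configuration value violates its constraint."""


class DegenerateImageError(MMPSOError):
    """The image has a single intensity level; no meaningful thresholds exist."""


class ImageIOError(MMPSOError, IOError):
    """Reading or writing an image file failed; the message names the path."""


class PipelineError(MMPSOError):
    """A pipeline stage failed; the message names the stage."""
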