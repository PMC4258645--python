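"""Exception hierarchy for fringe analysis and reconstruction."""


class SwFringeError(Exception):
    """Base class for all package-specific errors."""


class CenterNotFoundError(SwFringeError):
    """No radially symmetric structure found in the image."""


class NoPeaksFoundError(SwFringeError):
    """No fringe peaks above the prominence threshold."""


class EnvelopeNotFoundError(SwFringeError):
    """Fewer than two envelope maxima in the peak-amplitude sequence."""


class AmbiguousTopologyError(SwFringeError):
    """Contours do not form a strictly nested family."""


class ConfigError(SwFringeError):
    """Invalid or incomplete run configuration."""
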