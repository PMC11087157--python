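"""Exception hierarchy.

All package-specific failures derive from :class:`IcmReduceError` so CLI
entry points can map them to a nonzero exit with a readable message.
"""


class IcmReduceError(Exception):
    """Base class for all icmreduce errors."""


class ConfigError(IcmReduceError):
    """Invalid configuration: geometry, grid, missing config block, bad ROI layout."""


class EnergyRangeError(ConfigError, ValueError):
    """Photon energy outside the range covered by the attenuation table."""


class DetectionError(IcmReduceError):
    """Automatic ROI detection failed to find an expected insert."""


class DegenerateInputError(IcmReduceError):
    """Input is degenerate for the requested statistic (e.g. zero background SD)."""


class InsufficientDesignError(IcmReduceError):
    """Calibration design cannot identify the model (e.g. a single concentration)."""


class SchemaError(IcmReduceError):
    """CSV schema header missing, malformed, or of an unsupported major version."""
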