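"""Exception hierarchy.

All package-specific failures derive from :class:`PetromicsError` so callers
can distinguish data problems (bad inputs, exit code 1 in the CLI) from
configuration problems (exit code 2).
"""


class PetromicsError(Exception):
    """Base class for all petromics errors."""


class DataError(PetromicsError):
    """Malformed or inconsistent input data (volumes, tables, pairs)."""


class ConfigError(PetromicsError):
    """Invalid configuration or specification parameters."""


class GeometryError(ConfigError):
    """Phantom geometry that cannot be realized on the requested grid."""


class SegmentationError(DataError):
    """Delineation failed: undefined lesion or empty mask."""


class DegenerateInputError(DataError):
    """A statistic is undefined for the given input (too few values, zero spread)."""
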