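"""Exception hierarchy.

``ConfigError`` signals invalid user input (CLI exit code 2); everything
else derived from :class:`GfabricError` is a runtime failure (exit code 3).
"""


class GfabricError(Exception):
    """Base class for all package errors."""


class ConfigError(GfabricError, ValueError):
    """An invalid configuration field; the message names the field."""


class SpotTableError(GfabricError):
    """A malformed spot-level table (missing column, bad row)."""


class NormalizationError(GfabricError):
    """An array with no positive background-subtracted signal."""


class GeneLookupError(GfabricError, KeyError):
    """A gene id absent from the tensor it was requested from."""


class PairingError(GfabricError):
    """Cross-region replica (animal) identifiers do not match."""
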