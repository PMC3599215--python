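"""Exception hierarchy for the ivimfit pipeline.

Exit-code mapping used by the CLI: :class:`ConfigurationError` -> 1,
:class:`DataError` (including :class:`ParseError`) -> 2.
"""


class IvimfitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IvimfitError):
    """Invalid configuration: bad phantom spec, unknown scheme, bad thresholds."""


class DataError(IvimfitError):
    """Invalid or inconsistent input data."""


class ParseError(DataError):
    """A dataset on disk is malformed; the message names the offending component."""
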