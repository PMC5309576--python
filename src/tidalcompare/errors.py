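"""Exception hierarchy.

``ConfigError`` covers invalid user-supplied settings; ``DataError`` covers
defects in the recordings themselves.  The CLI maps them to distinct exit
codes so batch callers can tell them apart.
"""


class TidalCompareError(Exception):
    """Base class for all package errors."""


class ConfigError(TidalCompareError):
    """Invalid configuration (bad parameter values, impossible settings)."""


class DataError(TidalCompareError):
    """Invalid or inconsistent input data (traces, markers, samples)."""
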