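"""Exception hierarchy shared across the pipeline.

The CLI maps :class:`ConfigError` to exit code 2 and :class:`DataError`
to exit code 3; library callers can catch :class:`VocPanelError` for both.
"""


class VocPanelError(Exception):
    """Base class for all vocpanel errors."""


class ConfigError(VocPanelError):
    """Invalid parameter, study design or run configuration."""


class DataError(VocPanelError):
    """Malformed, inconsistent or insufficient input data."""
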