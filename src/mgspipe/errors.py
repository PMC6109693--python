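"""Exception hierarchy.

``MgsDataError`` maps to CLI exit code 1 (malformed or inconsistent input
data), ``MgsConfigError`` to exit code 2 (invalid parameters or config).
"""


class MgsError(Exception):
    """Base class for all pipeline errors."""


class MgsDataError(MgsError):
    """Malformed or internally inconsistent input data."""


class MgsConfigError(MgsError):
    """Invalid configuration or parameter value."""
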