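"""Exception hierarchy.

ValidationError: bad arguments/configuration (CLI exit code 2).
FormatError: unreadable or inconsistent on-disk artifacts (also exit 2).
DivergenceError: non-finite loss during optimization (exit 1).
"""


class NTFAError(Exception):
    """Base class for package errors."""


class ValidationError(NTFAError, ValueError):
    """Invalid argument, configuration value, or data invariant."""


class FormatError(NTFAError, IOError):
    """On-disk artifact is missing, unreadable, or inconsistent."""


class DivergenceError(NTFAError, RuntimeError):
    """Optimization produced a non-finite objective."""
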