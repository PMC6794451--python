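"""Exception hierarchy shared across the package.

``InputError`` marks contract violations in user-supplied data (bad files,
unknown classes, degenerate geometry); everything else is an internal error.
The CLI maps ``InputError`` to exit code 2 and any other failure to 3.
"""


class SeqstainError(Exception):
    """Base class for all package-specific errors."""


class InputError(SeqstainError):
    """User input violates a documented contract (file, value, or geometry)."""
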