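"""Exception hierarchy shared across the package.

``InputError`` covers anything the caller could have validated up front
(bad file contents, out-of-range indices, degenerate parameters) and maps
to exit code 2 in the CLI; ``ComputationError`` covers failures discovered
mid-computation and maps to exit code 3.
"""


class SpecmapError(Exception):
    """Base class for all package-specific errors."""


class InputError(SpecmapError, ValueError):
    """Invalid user-supplied data or parameters."""


class ParseError(InputError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ComputationError(SpecmapError, RuntimeError):
    """A stage failed while computing (e.g. non-convergence treated as fatal)."""
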