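"""Exceptions shared across the package."""

from __future__ import annotations


class DataFormatError(ValueError):
    """A malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class RosterMismatchError(ValueError):
    """A partition and a distance graph do not cover the same sequences."""
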