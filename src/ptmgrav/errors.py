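"""Exception hierarchy for the ptmgrav pipeline.

Parse problems that refer to individual rows carry the 1-based data-row
number so error reports can point back into the source file.
"""

from __future__ import annotations


class PtmgravError(Exception):
    """Base class for all ptmgrav errors."""


class TableFormatError(PtmgravError):
    """A table is structurally unusable (e.g. a mandatory column is missing)."""


class RowParseError(PtmgravError):
    """A single data row could not be parsed.

    Attributes
    ----------
    row : int
        1-based data-row number (header excluded).
    """

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


class ValidationError(PtmgravError):
    """Parsed content violates a domain invariant."""


class UsageError(PtmgravError):
    """The caller combined arguments in an unsupported way."""
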