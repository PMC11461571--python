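"""Exception hierarchy for the aircheck package.

All package errors derive from :class:`AircheckError` so callers can catch
one base class; most also derive from the closest built-in (``ValueError``,
``KeyError``) so generic handling keeps working.
"""

from __future__ import annotations


class AircheckError(Exception):
    """Base class for all aircheck errors."""


class UnknownCompoundError(AircheckError, KeyError):
    """A compound id is not present in the reference table being queried."""

    def __init__(self, compound_id: str) -> None:
        super().__init__(compound_id)
        self.compound_id = compound_id

    def __str__(self) -> str:  # KeyError quotes its arg; give a real message
        return f"unknown compound id: {self.compound_id!r}"


class ScenarioError(AircheckError, ValueError):
    """An exposure scenario violates its physical constraints.

    ``field`` names the offending parameter so callers (and the CLI) can
    point at it directly.
    """

    def __init__(self, field: str, message: str) -> None:
        super().__init__(f"invalid scenario: {field}: {message}")
        self.field = field


class CampaignValidationError(AircheckError, ValueError):
    """A campaign file row failed validation; ``row`` is the 1-based data row."""

    def __init__(self, row: int | None, message: str) -> None:
        where = f"row {row}: " if row is not None else ""
        super().__init__(f"{where}{message}")
        self.row = row


class EmptyGroupError(AircheckError, ValueError):
    """An aggregation was requested over zero matching records."""


class DomainError(AircheckError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ConsistencyWarning(UserWarning):
    """A record is internally inconsistent (e.g. ACD state vs. week) but usable."""
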