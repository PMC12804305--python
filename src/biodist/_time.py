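"""Single-clock timestamp handling.

All times in one study must come from one clock. Timestamps are ISO 8601;
naive values are assumed to share that clock, and mixing naive with
offset-aware values is an error rather than a silent assumption.
"""

from __future__ import annotations

from datetime import datetime

from .errors import ClockMixError

Timestamp = datetime


def parse_timestamp(value: str | datetime) -> datetime:
    """Parse an ISO 8601 timestamp (pass-through for datetime objects)."""
    if isinstance(value, datetime):
        return value
    try:
        return datetime.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ValueError(f"invalid ISO 8601 timestamp {value!r}") from exc


def elapsed_seconds(later: str | datetime, earlier: str | datetime) -> float:
    """Signed seconds from ``earlier`` to ``later`` on the shared clock."""
    a = parse_timestamp(later)
    b = parse_timestamp(earlier)
    if (a.tzinfo is None) != (b.tzinfo is None):
        raise ClockMixError(
            f"cannot mix offset-aware and naive timestamps: {a!r} vs {b!r}"
        )
    return (a - b).total_seconds()
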