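"""Calendar-month arithmetic.

Every date in the pipeline is truncated to month precision and represented
internally as an integer month index (``year * 12 + month - 1``), so that
differences between two indices are signed month counts.
"""

from __future__ import annotations

import re

_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})(?:-(\d{2}))?$")


def month_index(date: str) -> int:
    """Parse ``YYYY-MM`` or ``YYYY-MM-DD`` into a month index.

    Day-of-month information, if present, is discarded.
    """
    m = _MONTH_RE.match(date.strip())
    if m is None:
        raise ValueError(f"not an ISO year-month date: {date!r}")
    year, month = int(m.group(1)), int(m.group(2))
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range in {date!r}")
    return year * 12 + month - 1


def month_str(index: int) -> str:
    """Format a month index as ``YYYY-MM``."""
    year, month = divmod(int(index), 12)
    return f"{year:04d}-{month + 1:02d}"


def month_range(start: str | int, end: str | int) -> range:
    """Inclusive range of month indices from *start* to *end*."""
    lo = start if isinstance(start, int) else month_index(start)
    hi = end if isinstance(end, int) else month_index(end)
    if hi < lo:
        raise ValueError(f"end month {month_str(hi)} before start {month_str(lo)}")
    return range(lo, hi + 1)
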