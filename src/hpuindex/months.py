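"""Year-month keys.

The whole pipeline works at monthly resolution and serializes months as
``"YYYY-MM"`` strings, which sort lexicographically in calendar order.
"""

from __future__ import annotations

import re

from .errors import ValidationError

_YM_RE = re.compile(r"^(\d{4})-(\d{1,2})$")
_Y_RE = re.compile(r"^(\d{4})$")

YEAR_MIN, YEAR_MAX = 1900, 2100


def month_key(year: int, month: int) -> str:
    """Build the canonical ``"YYYY-MM"`` key, validating ranges."""
    if not (YEAR_MIN <= year <= YEAR_MAX):
        raise ValidationError(f"year {year} outside [{YEAR_MIN}, {YEAR_MAX}]")
    if not (1 <= month <= 12):
        raise ValidationError(f"month {month} outside [1, 12]")
    return f"{year:04d}-{month:02d}"


def parse_month(key: str) -> tuple[int, int]:
    """Parse ``"YYYY-MM"`` (or ``"YYYY-M"``) into ``(year, month)``."""
    m = _YM_RE.match(str(key).strip())
    if not m:
        raise ValidationError(f"not a year-month key: {key!r}")
    year, month = int(m.group(1)), int(m.group(2))
    month_key(year, month)  # range check
    return year, month


def month_span(first: str, last: str) -> list[str]:
    """All month keys from *first* to *last*, inclusive."""
    fy, fm = parse_month(first)
    ly, lm = parse_month(last)
    if (fy, fm) > (ly, lm):
        raise ValidationError(f"month range reversed: {first} > {last}")
    out = []
    y, m = fy, fm
    while (y, m) <= (ly, lm):
        out.append(month_key(y, m))
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return out


def expand_gap_token(token: str) -> list[str]:
    """Expand a gap-declaration token: ``"YYYY-MM"`` stays a single month,
    a bare ``"YYYY"`` expands to the 12 months of that year."""
    token = str(token).strip()
    if _Y_RE.match(token):
        year = int(token)
        return [month_key(year, m) for m in range(1, 13)]
    return [month_key(*parse_month(token))]
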