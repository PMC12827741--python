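"""Field normalization applied before any record comparison.

Name-like fields are uppercased, Unicode-compatibility decomposed,
stripped of diacritics, and reduced to A-Z/0-9 so that trivial
data-entry variation ("Müller" vs "MUELLER" vs "Mueller ") does not
defeat the matcher.  Dates are decomposed into day/month/year components
normalized to plain integer strings.
"""

from __future__ import annotations

import unicodedata
from typing import Mapping, Optional

#: Default identity field schema: decomposed birth date plus name/address fields.
DEFAULT_FIELDS: tuple[str, ...] = (
    "first_name",
    "last_name",
    "birth_day",
    "birth_month",
    "birth_year",
    "city",
)

#: Fields normalized as names (free text); the rest are date components.
NAME_FIELDS: frozenset[str] = frozenset({"first_name", "last_name", "city"})

_SPECIAL = {"ß": "SS", "ẞ": "SS", "Æ": "AE", "æ": "AE", "Ø": "O", "ø": "O", "Đ": "D", "đ": "D"}


def normalize_name(value: str) -> str:
    """Uppercase, strip diacritics and non-alphanumeric characters."""
    for src, dst in _SPECIAL.items():
        value = value.replace(src, dst)
    decomposed = unicodedata.normalize("NFKD", value)
    stripped = "".join(ch for ch in decomposed if not unicodedata.combining(ch))
    return "".join(ch for ch in stripped.upper() if ch.isalnum() and ch.isascii())


def normalize_component(value) -> str:
    """Normalize a date component (or other integer-like value) to a bare int string."""
    text = str(value).strip()
    try:
        return str(int(text))
    except ValueError:
        return text.upper()


def normalize_value(field_name: str, value) -> Optional[str]:
    """Normalize one field value; empty / None / NaN collapse to missing (None)."""
    if value is None:
        return None
    if not isinstance(value, str) and value != value:  # NaN
        return None
    if field_name in NAME_FIELDS or not _is_component(field_name):
        out = normalize_name(str(value))
    else:
        out = normalize_component(value)
    return out or None


def _is_component(field_name: str) -> bool:
    return field_name.startswith("birth_") or field_name.endswith(("_day", "_month", "_year"))


def normalize_record(fields: Mapping[str, object]) -> dict[str, Optional[str]]:
    """Normalize every field of a raw record; preserves key order."""
    return {name: normalize_value(name, value) for name, value in fields.items()}
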