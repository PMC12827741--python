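"""Vocabulary-based pseudonyms (ElasticIDs).

An ElasticID is built from a pattern such as ``"{word}-{word}{digit}"``
whose slots draw from a project-defined vocabulary (word slots) or the
decimal digits (digit slots).  Generation is a mixed-radix decomposition
of a counter, so it is deterministic, injective up to the pattern's
capacity, and needs no stored mapping.  A maximum length can be
enforced so identifiers fit, e.g., on a biosample tube label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from math import prod
from typing import Sequence

from .errors import CapacityError, ConfigError

_SLOT_RE = re.compile(r"\{(word|digit)\}")
_DIGITS = "0123456789"


@dataclass(frozen=True)
class ElasticIDConfig:
    vocabulary: tuple[str, ...]
    pattern: str = "{word}-{word}"
    max_length: int | None = None

    def __post_init__(self) -> None:
        if not self.vocabulary:
            raise ConfigError("vocabulary must be non-empty")
        if not _SLOT_RE.search(self.pattern):
            raise ConfigError("pattern must contain at least one {word} or {digit} slot")

    @property
    def capacity(self) -> int:
        sizes = [len(self.vocabulary) if kind == "word" else 10 for kind in _SLOT_RE.findall(self.pattern)]
        return prod(sizes)


def elasticid_generate(
    vocabulary: Sequence[str],
    pattern: str,
    seed_counter: int,
    max_length: int | None = None,
) -> str:
    """Deterministically expand ``seed_counter`` through the pattern's slots."""
    config = ElasticIDConfig(tuple(vocabulary), pattern, max_length)
    if seed_counter < 0 or seed_counter >= config.capacity:
        raise CapacityError(
            f"counter {seed_counter} exceeds pattern capacity {config.capacity}"
        )
    kinds = _SLOT_RE.findall(pattern)
    # Mixed-radix digits, most significant slot first.
    sizes = [len(vocabulary) if kind == "word" else 10 for kind in kinds]
    indices = []
    rest = seed_counter
    for size in reversed(sizes):
        rest, idx = divmod(rest, size)
        indices.append(idx)
    indices.reverse()

    fills = iter(indices)
    parts = []
    cursor = 0
    for match in _SLOT_RE.finditer(pattern):
        parts.append(pattern[cursor : match.start()])
        idx = next(fills)
        parts.append(vocabulary[idx] if match.group(1) == "word" else _DIGITS[idx])
        cursor = match.end()
    parts.append(pattern[cursor:])
    result = "".join(parts)
    if max_length is not None and len(result) > max_length:
        raise CapacityError(
            f"generated ElasticID {result!r} exceeds maximum length {max_length}"
        )
    return result
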