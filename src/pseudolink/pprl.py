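"""Privacy-preserving field encoding with Bloom filters.

A name field is decomposed into overlapping, padded character n-grams,
and every gram sets ``k`` bit positions of an ``m``-bit filter computed
by keyed double hashing:

    position_i(g) = (h1(g) + i * h2(g)) mod m,   i = 0 .. k-1

where ``h1``/``h2`` are HMAC-SHA256 hashes under a shared secret, so
only parties holding the secret can produce comparable filters.  The
Dice coefficient of two filters, 2|a AND b| / (|a| + |b|), approximates
the clear-text Dice coefficient of the underlying gram sets and plugs
into the linkage scoring exactly like a clear-text comparator — the
matcher never sees the plaintext.

For blocking on encoded fields, ``lsh_keys`` samples fixed random bit
positions (``bands`` bands of ``band_bits`` bits each): similar filters
agree on most bits and therefore share at least one band key with high
probability.
"""

from __future__ import annotations

import hmac
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import ConfigError


def extract_ngrams(value: str, n: int = 2, padding: bool = True) -> tuple[str, ...]:
    """Multiset (order-preserving tuple) of overlapping n-grams; '' -> ()."""
    if n < 1:
        raise ConfigError("gram size n must be >= 1")
    if not value:
        return ()
    if padding:
        pad = "_" * (n - 1)
        value = f"{pad}{value}{pad}"
    if len(value) < n:
        return ()
    return tuple(value[i : i + n] for i in range(len(value) - n + 1))


@dataclass(frozen=True)
class BloomFilterConfig:
    hmac_secret: bytes
    m: int = 500
    k: int = 10
    n: int = 2
    padding: bool = True

    def __post_init__(self) -> None:
        if self.m <= 0 or self.k < 1 or self.n < 1:
            raise ConfigError("require m > 0, k >= 1, n >= 1")
        if not self.hmac_secret:
            raise ConfigError("hmac_secret is required")


@dataclass(frozen=True)
class BloomField:
    """Fixed-length bitset stored as a big int; bit p is filter position p."""

    bits: int
    m: int

    @property
    def cardinality(self) -> int:
        return self.bits.bit_count()

    def to_hex(self) -> str:
        """Lowercase hex; MSB of byte 0 is filter position 0."""
        nbytes = (self.m + 7) // 8
        out = 0
        for p in range(self.m):
            if (self.bits >> p) & 1:
                out |= 1 << (8 * nbytes - 1 - p)
        return out.to_bytes(nbytes, "big").hex()

    @classmethod
    def from_hex(cls, text: str, m: int) -> "BloomField":
        raw = int(text, 16)
        nbytes = (m + 7) // 8
        bits = 0
        for p in range(m):
            if (raw >> (8 * nbytes - 1 - p)) & 1:
                bits |= 1 << p
        return cls(bits, m)


def _gram_positions(gram: str, config: BloomFilterConfig) -> list[int]:
    h1 = int.from_bytes(hmac.digest(config.hmac_secret + b"\x01", gram.encode(), "sha256")[:8], "big")
    h2 = int.from_bytes(hmac.digest(config.hmac_secret + b"\x02", gram.encode(), "sha256")[:8], "big")
    return [(h1 + i * h2) % config.m for i in range(config.k)]


def bloom_encode(grams, config: BloomFilterConfig) -> BloomField:
    """Set k double-hashed positions per gram; deterministic for a fixed secret."""
    bits = 0
    for gram in set(grams):
        for pos in _gram_positions(gram, config):
            bits |= 1 << pos
    return BloomField(bits, config.m)


@lru_cache(maxsize=65536)
def encode_value(value: str, config: BloomFilterConfig) -> BloomField:
    """Normalize-then-encode convenience with caching (config is hashable)."""
    return bloom_encode(extract_ngrams(value, config.n, config.padding), config)


def dice_similarity(a: BloomField, b: BloomField) -> float:
    if a.m != b.m:
        raise ConfigError("Bloom filters have different lengths")
    total = a.cardinality + b.cardinality
    if total == 0:
        return 1.0
    return 2.0 * (a.bits & b.bits).bit_count() / total


def dice_cleartext(a_grams, b_grams) -> float:
    """Clear-text Dice on gram multisets (the oracle the filters approximate)."""
    from collections import Counter

    ca, cb = Counter(a_grams), Counter(b_grams)
    total = sum(ca.values()) + sum(cb.values())
    if total == 0:
        return 1.0
    shared = sum(min(n, cb.get(g, 0)) for g, n in ca.items())
    return 2.0 * shared / total


@lru_cache(maxsize=64)
def _lsh_positions(m: int, bands: int, band_bits: int, seed: int) -> tuple[tuple[int, ...], ...]:
    if band_bits > m:
        raise ConfigError("band_bits exceeds filter length")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(bands):
        out.append(tuple(int(p) for p in rng.choice(m, size=band_bits, replace=False)))
    return tuple(out)


def lsh_keys(field: BloomField, bands: int, band_bits: int, seed: int) -> list[tuple[int, int]]:
    """One key per band: (band index, integer of the sampled bit values)."""
    keys = []
    for q, positions in enumerate(_lsh_positions(field.m, bands, band_bits, seed)):
        value = 0
        for p in positions:
            value = (value << 1) | ((field.bits >> p) & 1)
        keys.append((q, value))
    return keys
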