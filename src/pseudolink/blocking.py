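"""Blocking: cut the quadratic comparison space before scoring.

Records are bucketed by approximate keys — the American Soundex code of
a name field, the plain value of the birth year, or LSH band keys of a
Bloom-encoded field — and only patients sharing at least one tagged key
with the probe are scored.  Keys from different blocking variables are
combined with union (OR) semantics, so a typo in one blocked field
cannot hide a record that still agrees on another.  Alias identities
contribute keys alongside MAIN identities.  A probe with no derivable
key at all falls back to comparing against everyone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

from . import pprl
from .errors import ConfigError
from .model import Identity, Patient

_SOUNDEX_CODES = {}
for _digit, _letters in {
    "1": "BFPV", "2": "CGJKQSXZ", "3": "DT", "4": "L", "5": "MN", "6": "R",
}.items():
    for _ch in _letters:
        _SOUNDEX_CODES[_ch] = _digit


def soundex_encode(value: str) -> str:
    """Classic 4-character American Soundex (H/W transparent, vowels break runs)."""
    letters = [ch for ch in value.upper() if "A" <= ch <= "Z"]
    if not letters:
        return "0000"
    first = letters[0]
    prev = _SOUNDEX_CODES.get(first, "")
    digits: list[str] = []
    for ch in letters[1:]:
        if ch in "HW":
            continue  # transparent: does not break an adjacent run
        code = _SOUNDEX_CODES.get(ch)
        if code is None:  # vowel (or Y): emits nothing but breaks the run
            prev = ""
            continue
        if code != prev:
            digits.append(code)
            prev = code
        if len(digits) == 3:
            break
    return first + "".join(digits).ljust(3, "0")


class BlockingMethod(str, Enum):
    SOUNDEX = "SOUNDEX"
    LSH = "LSH"
    EXACT_YEAR = "EXACT_YEAR"


@dataclass(frozen=True)
class BlockingVariable:
    field_name: str
    method: BlockingMethod


@dataclass(frozen=True)
class BlockingConfig:
    """Blocking variables plus the LSH parameters used for Bloom fields.

    The default blocks on Soundex(last name), the birth year, and LSH
    keys of the Bloom-encoded first name.  Name filters are sparse, so a
    band must be wide (32 bits at m = 500) before agreement stops being
    dominated by shared zero bits; 8 such bands keep bucket collisions
    between unrelated records rare while a single-typo variant still
    shares a band with useful probability — and the union with the
    Soundex and birth-year variables retains essentially all true
    duplicates.
    """

    variables: tuple[BlockingVariable, ...] = (
        BlockingVariable("last_name", BlockingMethod.SOUNDEX),
        BlockingVariable("birth_year", BlockingMethod.EXACT_YEAR),
        BlockingVariable("first_name", BlockingMethod.LSH),
    )
    lsh_bands: int = 8
    lsh_band_bits: int = 32
    lsh_seed: int = 20210

    def __post_init__(self) -> None:
        if not self.variables:
            raise ConfigError("blocking requires at least one variable")


def block_keys(
    identity: Identity | Mapping[str, Optional[str]],
    config: BlockingConfig,
    bloom_config: Optional[pprl.BloomFilterConfig] = None,
) -> set[tuple]:
    """Tagged blocking keys of one identity; missing fields contribute none."""
    fields = identity.field_values if isinstance(identity, Identity) else identity
    keys: set[tuple] = set()
    for variable in config.variables:
        value = fields.get(variable.field_name)
        if value is None:
            continue
        if variable.method is BlockingMethod.SOUNDEX:
            keys.add((variable.field_name, "soundex", soundex_encode(value)))
        elif variable.method is BlockingMethod.EXACT_YEAR:
            keys.add((variable.field_name, "year", value))
        else:
            if bloom_config is None:
                raise ConfigError("LSH blocking variable requires a BloomFilterConfig")
            bloom = pprl.encode_value(value, bloom_config)
            for band, bits in pprl.lsh_keys(
                bloom, config.lsh_bands, config.lsh_band_bits, config.lsh_seed
            ):
                keys.add((variable.field_name, "lsh", band, bits))
    return keys


class BlockIndex:
    """Incremental bucket index over a patient store."""

    def __init__(
        self,
        config: BlockingConfig | None = None,
        bloom_config: Optional[pprl.BloomFilterConfig] = None,
    ) -> None:
        self.config = config or BlockingConfig()
        self.bloom_config = bloom_config
        self.buckets: dict[tuple, set[int]] = {}
        self.all_keys: set[int] = set()

    def add_identity(self, patient_key: int, identity: Identity | Mapping) -> None:
        self.all_keys.add(patient_key)
        for key in block_keys(identity, self.config, self.bloom_config):
            self.buckets.setdefault(key, set()).add(patient_key)

    def add_patient(self, patient: Patient) -> None:
        self.all_keys.add(patient.internal_key)
        for identity in patient.identities:
            self.add_identity(patient.internal_key, identity)

    def candidates(self, probe: Identity | Mapping) -> set[int]:
        """Union of buckets sharing a key with the probe; full scan fallback
        when the probe yields no key at all."""
        probe_keys = block_keys(probe, self.config, self.bloom_config)
        if not probe_keys:
            return set(self.all_keys)
        out: set[int] = set()
        for key in probe_keys:
            out |= self.buckets.get(key, set())
        return out
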