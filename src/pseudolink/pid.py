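"""Check-character patient identifiers (PIDs).

A PID is a short, human-readable identifier minted from a monotone
counter.  Two properties make it safe to handle on paper or on a sample
tube label:

* the counter is scrambled by a keyed bijective permutation, so
  consecutive counters do not yield visually consecutive identifiers and
  the identifier leaks nothing about registration order without the key;
* two check characters extend the payload to a codeword of a
  Reed-Solomon-style [8, 6] code over GF(32) with minimum distance 3, so
  any single mistyped character can be *corrected* (CORRECT1 mode) or,
  alternatively, any two mistyped characters are reliably *detected*
  (DETECT2 mode).  Distance 3 cannot deliver both guarantees at once,
  so the operating mode is part of the configuration.

The 32-character alphabet contains the digits and the latin letters
without B, I, O and S, which are easily confused with 8, 1, 0 and 5.
"""

from __future__ import annotations

import hmac
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .errors import CapacityError, ConfigError

#: Canonical 32-symbol alphabet (no B, I, O, S).
PID_ALPHABET = "0123456789ACDEFGHJKLMNPQRTUVWXYZ"

# ---------------------------------------------------------------------------
# GF(32) arithmetic, primitive polynomial x^5 + x^2 + 1, generator alpha = 2.
# ---------------------------------------------------------------------------

_EXP = [0] * 31
_LOG = [0] * 32
_x = 1
for _i in range(31):
    _EXP[_i] = _x
    _LOG[_x] = _i
    _x <<= 1
    if _x & 0x20:
        _x ^= 0x25


def _gmul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return _EXP[(_LOG[a] + _LOG[b]) % 31]


def _gdiv(a: int, b: int) -> int:
    if a == 0:
        return 0
    return _EXP[(_LOG[a] - _LOG[b]) % 31]


# Generator polynomial g(x) = (x - a)(x - a^2) = x^2 + g1 x + g0 over GF(32).
_G1 = _EXP[1] ^ _EXP[2]
_G0 = _EXP[3]


class PIDMode(str, Enum):
    """Error-handling mode of the check code (mutually exclusive)."""

    CORRECT1 = "CORRECT1"  #: correct any single-character substitution
    DETECT2 = "DETECT2"  #: detect (never silently accept) up to two substitutions


class PIDStatus(str, Enum):
    VALID = "VALID"
    CORRECTED = "CORRECTED"
    INVALID = "INVALID"


@dataclass(frozen=True)
class PIDConfig:
    """Parameters of the PID scheme.

    ``mixing_key`` drives the keyed payload permutation; it is a secret
    and must be identical wherever the same PID namespace is decoded.
    """

    mixing_key: bytes
    alphabet: str = PID_ALPHABET
    payload_length: int = 6
    check_length: int = 2
    mode: PIDMode = PIDMode.CORRECT1

    def __post_init__(self) -> None:
        if len(self.alphabet) != 32 or len(set(self.alphabet)) != 32:
            raise ConfigError("PID alphabet must contain exactly 32 distinct characters")
        if any(ch in self.alphabet for ch in "BIOS"):
            raise ConfigError("PID alphabet must exclude the ambiguous letters B, I, O, S")
        if self.check_length != 2:
            raise ConfigError("the distance-3 check code uses exactly 2 check characters")
        if self.payload_length < 2 or self.payload_length > 29:
            raise ConfigError("payload_length out of range")
        if (5 * self.payload_length) % 2 != 0:
            raise ConfigError("payload bit width must be even for the keyed permutation")
        if not self.mixing_key:
            raise ConfigError("mixing_key must be non-empty")

    @property
    def total_length(self) -> int:
        return self.payload_length + self.check_length

    @property
    def capacity(self) -> int:
        """Number of distinct counters: 32 ** payload_length."""
        return 32**self.payload_length


@dataclass(frozen=True)
class VerificationResult:
    status: PIDStatus
    counter: Optional[int] = None
    corrected_pid: Optional[str] = None

    def __post_init__(self) -> None:
        ok = self.status in (PIDStatus.VALID, PIDStatus.CORRECTED)
        assert (self.counter is not None) == ok
        assert (self.corrected_pid is not None) == (self.status == PIDStatus.CORRECTED)


# ---------------------------------------------------------------------------
# Keyed payload permutation: balanced Feistel network on 5*payload_length bits.
# ---------------------------------------------------------------------------

_ROUNDS = 4


def _round_fn(key: bytes, rnd: int, half: int, half_bits: int) -> int:
    msg = b"pid-feistel" + bytes([rnd]) + half.to_bytes(8, "big")
    digest = hmac.digest(key, msg, "sha256")
    return int.from_bytes(digest[:8], "big") & ((1 << half_bits) - 1)


def _permute(value: int, key: bytes, bits: int, inverse: bool = False) -> int:
    half_bits = bits // 2
    mask = (1 << half_bits) - 1
    left, right = value >> half_bits, value & mask
    if not inverse:
        for rnd in range(_ROUNDS):
            left, right = right, left ^ _round_fn(key, rnd, right, half_bits)
    else:
        for rnd in reversed(range(_ROUNDS)):
            left, right = right ^ _round_fn(key, rnd, left, half_bits), left
    return (left << half_bits) | right


# ---------------------------------------------------------------------------
# Systematic Reed-Solomon-style encoding and syndrome decoding.
# ---------------------------------------------------------------------------


def _rs_check_symbols(message: list[int]) -> tuple[int, int]:
    """Remainder of m(x)*x^2 modulo g(x); message[j] is the coefficient of x^j."""
    r1 = r0 = 0
    for coeff in reversed(message):  # highest degree first
        top = r1 ^ coeff
        r1 = r0 ^ _gmul(top, _G1)
        r0 = _gmul(top, _G0)
    return r0, r1


def _syndromes(codeword: list[int]) -> tuple[int, int]:
    """S1 = c(alpha), S2 = c(alpha^2) for codeword coefficients c[0..]."""
    s1 = s2 = 0
    for i, coeff in enumerate(codeword):
        if coeff:
            li = _LOG[coeff]
            s1 ^= _EXP[(li + i) % 31]
            s2 ^= _EXP[(li + 2 * i) % 31]
    return s1, s2


def pid_encode(counter: int, config: PIDConfig) -> str:
    """Encode a non-negative counter into a fixed-length check-charactered PID."""
    if counter < 0 or counter >= config.capacity:
        raise CapacityError(
            f"counter {counter} out of range [0, {config.capacity}) for payload length "
            f"{config.payload_length}"
        )
    bits = 5 * config.payload_length
    scrambled = _permute(counter, config.mixing_key, bits)
    # message[j] = coefficient of x^(j+2); leftmost PID char = highest degree.
    n = config.payload_length
    symbols_msb_first = [(scrambled >> (5 * (n - 1 - j))) & 31 for j in range(n)]
    message = list(reversed(symbols_msb_first))  # message[0] -> coefficient x^2
    r0, r1 = _rs_check_symbols(message)
    codeword = [r0, r1] + message  # codeword[i] = coefficient of x^i
    chars = [config.alphabet[codeword[len(codeword) - 1 - i]] for i in range(len(codeword))]
    return "".join(chars)


def _decode_counter(codeword: list[int], config: PIDConfig) -> int:
    message = codeword[2:]
    scrambled = 0
    for sym in reversed(message):  # highest degree first
        scrambled = (scrambled << 5) | sym
    return _permute(scrambled, config.mixing_key, 5 * config.payload_length, inverse=True)


def pid_verify(pid: str, config: PIDConfig) -> VerificationResult:
    """Check (and in CORRECT1 mode repair) a PID; input is case-insensitive."""
    pid = pid.strip().upper()
    if len(pid) != config.total_length:
        return VerificationResult(PIDStatus.INVALID)
    index = {ch: v for v, ch in enumerate(config.alphabet)}
    try:
        codeword = [index[pid[len(pid) - 1 - i]] for i in range(len(pid))]
    except KeyError:
        return VerificationResult(PIDStatus.INVALID)
    s1, s2 = _syndromes(codeword)
    if s1 == 0 and s2 == 0:
        return VerificationResult(PIDStatus.VALID, counter=_decode_counter(codeword, config))
    if config.mode is PIDMode.DETECT2:
        return VerificationResult(PIDStatus.INVALID)
    # Single-error correction: S1 = e * a^j, S2 = e * a^(2j).
    if s1 == 0 or s2 == 0:
        return VerificationResult(PIDStatus.INVALID)
    j = (_LOG[s2] - _LOG[s1]) % 31
    if j >= len(codeword):
        return VerificationResult(PIDStatus.INVALID)
    magnitude = _gdiv(s1, _EXP[j])
    repaired = list(codeword)
    repaired[j] ^= magnitude
    if _syndromes(repaired) != (0, 0):  # defensive; cannot happen for distance 3
        return VerificationResult(PIDStatus.INVALID)
    corrected = "".join(
        config.alphabet[repaired[len(repaired) - 1 - i]] for i in range(len(repaired))
    )
    return VerificationResult(
        PIDStatus.CORRECTED,
        counter=_decode_counter(repaired, config),
        corrected_pid=corrected,
    )


def make_pid_generator(config: PIDConfig):
    """Return ``counter -> pid`` suitable as an internal pseudonym generator."""

    def _generate(counter: int) -> str:
        return pid_encode(counter, config)

    return _generate
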