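"""Cryptographic pseudonym derivation and transport protection.

Two independent primitives live here:

* **CryptoID** — a *non-persistent* pseudonym derived deterministically
  from a base pseudonym under a shared secret key, and invertible back
  to the base value.  Because derivation is deterministic and keyed, the
  CryptoID never needs to be stored: it is regenerated on every access.
  The construction is SIV-style deterministic authenticated encryption
  built from HMAC-SHA256: a truncated MAC of the plaintext doubles as
  the synthetic IV for an HMAC-counter keystream, and is re-verified on
  inversion so a wrong key fails loudly instead of yielding garbage.

* **Hybrid transport encryption** — for handing pseudonyms to a trusted
  third party: the payload is encrypted under a fresh symmetric key
  (HMAC-counter stream cipher with an encrypt-then-MAC tag) and the key
  agreement uses an ephemeral Diffie-Hellman exchange over the RFC 3526
  2048-bit MODP group against the recipient's long-term public key.
  Equal plaintexts produce distinct envelopes because the ephemeral key
  and nonce are fresh per call.
"""

from __future__ import annotations

import hmac
import json
import secrets
from dataclasses import dataclass
from enum import Enum

from .errors import CodecError, ConfigError, DecryptionError
from .pid import PID_ALPHABET

_TAG_LEN = 10  # 80-bit synthetic IV / authenticity tag for CryptoIDs


def _hkey(secret: bytes, label: bytes) -> bytes:
    return hmac.digest(secret, label, "sha256")


def _keystream(key: bytes, iv: bytes, length: int) -> bytes:
    blocks = []
    for counter in range((length + 31) // 32):
        blocks.append(hmac.digest(key, iv + counter.to_bytes(8, "big"), "sha256"))
    return b"".join(blocks)[:length]


def _xor(data: bytes, stream: bytes) -> bytes:
    return bytes(a ^ b for a, b in zip(data, stream))


# ---------------------------------------------------------------------------
# Base-N text codec over a configurable output alphabet
# ---------------------------------------------------------------------------


def encode_alphabet(raw: bytes, alphabet: str) -> str:
    """Encode bytes as a big-int in base len(alphabet); leading zeros preserved."""
    number = int.from_bytes(b"\x01" + raw, "big")
    base = len(alphabet)
    digits = []
    while number:
        number, rem = divmod(number, base)
        digits.append(alphabet[rem])
    return "".join(reversed(digits))


def decode_alphabet(text: str, alphabet: str) -> bytes:
    base = len(alphabet)
    index = {ch: i for i, ch in enumerate(alphabet)}
    number = 0
    try:
        for ch in text:
            number = number * base + index[ch]
    except KeyError as exc:
        raise CodecError(f"character {exc} not in output alphabet") from exc
    raw = number.to_bytes((number.bit_length() + 7) // 8, "big")
    if not raw or raw[0] != 0x01:
        raise CodecError("malformed encoded value")
    return raw[1:]


# ---------------------------------------------------------------------------
# CryptoID
# ---------------------------------------------------------------------------


class Direction(str, Enum):
    FORWARD = "FORWARD"
    INVERSE = "INVERSE"


@dataclass(frozen=True)
class CryptoIDConfig:
    """Keyed derivation of a CryptoID from a base pseudonym type."""

    base_type: str
    secret_key: bytes
    output_alphabet: str = PID_ALPHABET

    def __post_init__(self) -> None:
        if len(self.secret_key) < 16:
            raise ConfigError("CryptoID secret_key must be at least 16 bytes")
        if len(set(self.output_alphabet)) < 2:
            raise ConfigError("output_alphabet needs at least 2 distinct characters")


def cryptoid_forward(base_value: str, config: CryptoIDConfig) -> str:
    if not base_value:
        raise CodecError("base value must be non-empty")
    plaintext = base_value.encode("utf-8")
    tag = hmac.digest(_hkey(config.secret_key, b"cryptoid-tag"), plaintext, "sha256")[:_TAG_LEN]
    stream = _keystream(_hkey(config.secret_key, b"cryptoid-enc"), tag, len(plaintext))
    return encode_alphabet(tag + _xor(plaintext, stream), config.output_alphabet)


def cryptoid_invert(token: str, config: CryptoIDConfig) -> str:
    if not token:
        raise CodecError("token must be non-empty")
    raw = decode_alphabet(token, config.output_alphabet)
    if len(raw) <= _TAG_LEN:
        raise CodecError("token too short")
    tag, ciphertext = raw[:_TAG_LEN], raw[_TAG_LEN:]
    stream = _keystream(_hkey(config.secret_key, b"cryptoid-enc"), tag, len(ciphertext))
    plaintext = _xor(ciphertext, stream)
    expect = hmac.digest(_hkey(config.secret_key, b"cryptoid-tag"), plaintext, "sha256")[:_TAG_LEN]
    if not hmac.compare_digest(tag, expect):
        raise CodecError("CryptoID authentication failed (wrong key or corrupted token)")
    return plaintext.decode("utf-8")


def cryptoid_derive(value: str, config: CryptoIDConfig, direction: Direction = Direction.FORWARD) -> str:
    """Derive a CryptoID from its base pseudonym, or invert one back."""
    if Direction(direction) is Direction.FORWARD:
        return cryptoid_forward(value, config)
    return cryptoid_invert(value, config)


# ---------------------------------------------------------------------------
# Hybrid transport encryption (ephemeral DH + stream cipher + MAC)
# ---------------------------------------------------------------------------

# RFC 3526 group 14: 2048-bit MODP prime, generator 2.
_DH_PRIME = int(
    "FFFFFFFFFFFFFFFFC90FDAA22168C234C4C6628B80DC1CD129024E088A67CC74"
    "020BBEA63B139B22514A08798E3404DDEF9519B3CD3A431B302B0A6DF25F1437"
    "4FE1356D6D51C245E485B576625E7EC6F44C42E9A637ED6B0BFF5CB6F406B7ED"
    "EE386BFB5A899FA5AE9F24117C4B1FE649286651ECE45B3DC2007CB8A163BF05"
    "98DA48361C55D39A69163FA8FD24CF5F83655D23DCA3AD961C62F356208552BB"
    "9ED529077096966D670C354E4ABC9804F1746C08CA18217C32905E462E36CE3B"
    "E39E772C180E86039B2783A2EC07A28FB5C55DF06F4C52C9DE2BCBF695581718"
    "3995497CEA956AE515D2261898FA051015728E5A8AACAA68FFFFFFFFFFFFFFFF",
    16,
)
_DH_GENERATOR = 2
_DH_BYTES = 256
_NONCE_LEN = 16
_MAC_LEN = 16


@dataclass(frozen=True)
class TransportKeyPair:
    private_key: int
    public_key: int


def generate_transport_keypair(rng: secrets.SystemRandom | None = None) -> TransportKeyPair:
    rand = rng or secrets.SystemRandom()
    private = rand.randrange(2, _DH_PRIME - 2)
    return TransportKeyPair(private, pow(_DH_GENERATOR, private, _DH_PRIME))


@dataclass(frozen=True)
class TransportEnvelope:
    """Serializable hybrid-encryption envelope."""

    ephemeral_public: int
    nonce: bytes
    ciphertext: bytes
    tag: bytes

    def to_json(self) -> str:
        return json.dumps(
            {
                "ephemeral_public": format(self.ephemeral_public, "x"),
                "nonce": self.nonce.hex(),
                "ciphertext": self.ciphertext.hex(),
                "tag": self.tag.hex(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TransportEnvelope":
        obj = json.loads(text)
        return cls(
            int(obj["ephemeral_public"], 16),
            bytes.fromhex(obj["nonce"]),
            bytes.fromhex(obj["ciphertext"]),
            bytes.fromhex(obj["tag"]),
        )


def _transport_keys(shared: int) -> tuple[bytes, bytes]:
    secret = shared.to_bytes(_DH_BYTES, "big")
    return _hkey(secret, b"transport-enc"), _hkey(secret, b"transport-mac")


def transport_encrypt(pseudonym: str, recipient_public_key: int) -> TransportEnvelope:
    """Encrypt a pseudonym to the holder of the matching private key."""
    if not (1 < recipient_public_key < _DH_PRIME - 1):
        raise ConfigError("invalid recipient public key")
    eph = generate_transport_keypair()
    shared = pow(recipient_public_key, eph.private_key, _DH_PRIME)
    key_enc, key_mac = _transport_keys(shared)
    nonce = secrets.token_bytes(_NONCE_LEN)
    plaintext = pseudonym.encode("utf-8")
    ciphertext = _xor(plaintext, _keystream(key_enc, nonce, len(plaintext)))
    header = eph.public_key.to_bytes(_DH_BYTES, "big") + nonce
    tag = hmac.digest(key_mac, header + ciphertext, "sha256")[:_MAC_LEN]
    return TransportEnvelope(eph.public_key, nonce, ciphertext, tag)


def transport_decrypt(envelope: TransportEnvelope, recipient: TransportKeyPair | int) -> str:
    """Open an envelope; raises DecryptionError on any key or integrity mismatch."""
    private = recipient.private_key if isinstance(recipient, TransportKeyPair) else recipient
    if not (1 < envelope.ephemeral_public < _DH_PRIME - 1):
        raise DecryptionError("invalid ephemeral public key")
    shared = pow(envelope.ephemeral_public, private, _DH_PRIME)
    key_enc, key_mac = _transport_keys(shared)
    header = envelope.ephemeral_public.to_bytes(_DH_BYTES, "big") + envelope.nonce
    expect = hmac.digest(key_mac, header + envelope.ciphertext, "sha256")[:_MAC_LEN]
    if not hmac.compare_digest(envelope.tag, expect):
        raise DecryptionError("authentication failed: wrong key or tampered envelope")
    plaintext = _xor(envelope.ciphertext, _keystream(key_enc, envelope.nonce, len(envelope.ciphertext)))
    return plaintext.decode("utf-8")
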