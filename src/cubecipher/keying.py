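"""Key and image hashing, and derivation of chaotic initial conditions.

The cipher is keyed by a 256-bit user key written as 64 hexadecimal
characters.  The key is hex-decoded to its 32 raw bytes and hashed with
SHA-256; the plaintext image is hashed the same way over its row-major,
channel-interleaved byte stream.  The two digests are combined into a single
digest ``SHA-256(H_K || H_I)`` whose first, second and last 64-bit words,
scaled by 2**64, become the initial conditions (x0, y0, z0) of the coupled
logistic map.  Binding the keystream to the plaintext hash is what gives the
scheme its differential-attack strength (one flipped pixel re-seeds the whole
keystream); decryption never needs to re-derive the seeds because the cipher
record persists the derived key material explicitly.
"""

from __future__ import annotations

import hashlib
import string
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

KEY_HEX_LENGTH = 64
KEY_BITS = 256

#: Seeds are clamped into [SEED_EPS, 1 - SEED_EPS] to keep the logistic map
#: away from its absorbing fixed point at 0 and the boundary at 1.
SEED_EPS = 1e-6

_HEX_DIGITS = frozenset(string.hexdigits)


@dataclass(frozen=True)
class SeedTriple:
    """Initial conditions of the chaotic system, each strictly inside (0, 1)."""

    x0: float
    y0: float
    z0: float

    def __post_init__(self) -> None:
        for name, v in (("x0", self.x0), ("y0", self.y0), ("z0", self.z0)):
            if not (0.0 < v < 1.0):
                raise ValidationError(f"seed {name}={v!r} is not inside (0, 1)")


def validate_key(hex_string: str) -> str:
    """Validate a 64-character hexadecimal user key and return it lowercased.

    Raises :class:`ValidationError` naming the offending position for any
    malformed input.
    """
    if not isinstance(hex_string, str):
        raise ValidationError(f"key must be a string, got {type(hex_string).__name__}")
    if len(hex_string) != KEY_HEX_LENGTH:
        raise ValidationError(
            f"key must be exactly {KEY_HEX_LENGTH} hex characters, got {len(hex_string)}"
        )
    for pos, ch in enumerate(hex_string):
        if ch not in _HEX_DIGITS:
            raise ValidationError(
                f"key contains non-hexadecimal character {ch!r} at position {pos}"
            )
    return hex_string.lower()


def hash_key(hex_string: str) -> bytes:
    """SHA-256 digest of the key's 32 raw bytes (hex-decoded, case-insensitive)."""
    key = validate_key(hex_string)
    return hashlib.sha256(bytes.fromhex(key)).digest()


def hash_image(pixels: np.ndarray) -> bytes:
    """SHA-256 digest of an image's row-major, channel-interleaved bytes.

    No header or shape information enters the hash; two images with identical
    byte streams hash identically regardless of on-disk container.
    """
    arr = np.asarray(pixels)
    if arr.size == 0:
        raise ValidationError("cannot hash an empty image")
    if arr.dtype != np.uint8:
        raise ValidationError(f"image must be uint8, got {arr.dtype}")
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).digest()


def _word(hexdigest: str, start: int) -> float:
    v = int(hexdigest[start : start + 16], 16) / 2.0**64
    return min(max(v, SEED_EPS), 1.0 - SEED_EPS)


def derive_seeds(hk: bytes, hi: bytes) -> SeedTriple:
    """Derive (x0, y0, z0) from the key digest and the image digest.

    The two 32-byte digests are concatenated and re-hashed; the combined
    digest's hex rendering H supplies x0 = int(H[0:16], 16) / 2**64,
    y0 from H[16:32] and z0 from H[48:64], each clamped into
    [1e-6, 1 - 1e-6].
    """
    for name, d in (("hk", hk), ("hi", hi)):
        if not isinstance(d, (bytes, bytearray)) or len(d) != 32:
            raise ValidationError(f"{name} must be a 32-byte digest")
    combined = hashlib.sha256(bytes(hk) + bytes(hi)).hexdigest()
    return SeedTriple(_word(combined, 0), _word(combined, 16), _word(combined, 48))


def seeds_for(img: np.ndarray, key_hex: str) -> SeedTriple:
    """Convenience: seeds for an (image, key) pair."""
    return derive_seeds(hash_key(key_hex), hash_image(img))
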