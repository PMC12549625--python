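"""The permutation-diffusion cipher: cube expansion, permutation, layer
rotation, XOR diffusion, and the exact inverse.

Encryption conceptually expands each 8-bit channel into an H x W x D cube
(every depth layer a copy of the channel), permutes columns by A and rows by
B, rotates layer k by C[k] counterclockwise quarter-turns, XORs the cube with
the byte key cube K, and collapses back to 2D by keeping layer 0.  Because
neither permutation nor per-layer rotation mixes depth layers, and the
collapse keeps only layer 0, the whole pipeline is exactly equivalent to a 2D
permute/rotate/XOR using C[0] and the layer-0 key plane K[:, :, 0]; that
reduction (``engine="fast"``) is the default execution path and the full cube
is retained as a verification oracle.

Everything needed to invert the cipher — A, B, C and the key plane — is
persisted in a checksummed :class:`CipherRecord` (``.c3dk`` key file), so
decryption is bit-exact and independent of the floating-point environment and
of the plaintext hash that seeded the keystream.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field

import numpy as np

from . import keying
from .chaos import (
    ChaoticParams,
    IndexArrays,
    generate_orbit,
    key_plane,
    make_index_arrays,
    make_key_cube,
    required_orbit_length,
)
from .exceptions import CapacityError, IntegrityError, ValidationError

MAGIC = b"C3DK"
FORMAT_VERSION = 1

#: Record flag bits.
FLAG_GRAYSCALE_EXPANDED = 0x01
FLAG_ROTATION_RESTRICTED = 0x02

#: Full-cube path refuses cubes above this many elements per channel.
MAX_CUBE_ELEMENTS = 1 << 28

_HEADER = struct.Struct("<4sBBBBIII")


def validate_image(pixels: np.ndarray) -> np.ndarray:
    """Check an 8-bit raster (H x W or H x W x {1,3}, H, W >= 2); return it 3-D."""
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        raise ValidationError(f"image must be uint8, got {arr.dtype}")
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3 or arr.shape[2] not in (1, 3):
        raise ValidationError(
            f"image must be HxW or HxWx{{1,3}}, got shape {np.asarray(pixels).shape}"
        )
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError(f"image too small: {arr.shape[0]}x{arr.shape[1]} (need >= 2x2)")
    return arr


def default_depth(height: int, width: int) -> int:
    """Cube depth policy: D = H for square images up to 256; otherwise 1.

    Under the layer-0 collapse convention deeper layers never reach the
    output, so non-square and very large images use a single layer.
    """
    if height == width and height <= 256:
        return height
    return 1


# ---------------------------------------------------------------------------
# cube primitives
# ---------------------------------------------------------------------------

def expand_to_cube(channel: np.ndarray, depth: int) -> np.ndarray:
    """Replicate a 2D channel into an H x W x D cube (cube[i,j,k] = channel[i,j])."""
    ch = np.asarray(channel)
    if ch.ndim != 2:
        raise ValidationError(f"channel must be 2-D, got shape {ch.shape}")
    if depth < 1:
        raise ValidationError(f"depth={depth!r} must be >= 1")
    if ch.shape[0] * ch.shape[1] * depth > MAX_CUBE_ELEMENTS:
        raise CapacityError(
            f"cube {ch.shape[0]}x{ch.shape[1]}x{depth} exceeds the memory cap; "
            "use the fast engine (encrypt_fast), which is byte-identical"
        )
    return np.repeat(ch[:, :, None], depth, axis=2)


def permute(cube: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Reindex the column axis by A, then the row axis by B; depth untouched."""
    if len(a) != cube.shape[1]:
        raise ValidationError(f"|A|={len(a)} does not match width {cube.shape[1]}")
    if len(b) != cube.shape[0]:
        raise ValidationError(f"|B|={len(b)} does not match height {cube.shape[0]}")
    return cube[:, np.asarray(a)][np.asarray(b)]


def inverse_permute(cube: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`permute` (argsorts of A and B, reverse order)."""
    if len(a) != cube.shape[1]:
        raise ValidationError(f"|A|={len(a)} does not match width {cube.shape[1]}")
    if len(b) != cube.shape[0]:
        raise ValidationError(f"|B|={len(b)} does not match height {cube.shape[0]}")
    return cube[np.argsort(np.asarray(b))][:, np.argsort(np.asarray(a))]


def rotate_layers(cube: np.ndarray, c: np.ndarray, *, restrict_180: bool = False) -> np.ndarray:
    """Rotate layer k by C[k] counterclockwise quarter-turns.

    With ``restrict_180`` (non-square layers) counts are reduced mod 2 and
    applied as 180-degree turns so shapes are preserved.
    """
    c = np.asarray(c)
    if len(c) != cube.shape[2]:
        raise ValidationError(f"|C|={len(c)} does not match depth {cube.shape[2]}")
    if not restrict_180 and cube.shape[0] != cube.shape[1]:
        raise ValidationError("quarter-turns require square layers; use restrict_180")
    out = cube.copy()
    for turns in (1, 2, 3):
        eff = (c % 2) * 2 if restrict_180 else c % 4
        sel = eff == turns
        if sel.any():
            out[:, :, sel] = np.rot90(out[:, :, sel], turns, axes=(0, 1))
    return out


def xor_with_key(cube: np.ndarray, key_cube: np.ndarray) -> np.ndarray:
    """Element-wise bitwise XOR of the cube with the key cube."""
    if cube.shape != key_cube.shape:
        raise ValidationError(
            f"shape mismatch: cube {cube.shape} vs key cube {key_cube.shape}"
        )
    return np.bitwise_xor(cube, key_cube)


def collapse(cubes) -> np.ndarray:
    """Keep layer 0 of each per-channel cube; stack channels into an image."""
    cubes = list(cubes)
    shape = cubes[0].shape
    for c in cubes[1:]:
        if c.shape != shape:
            raise ValidationError(f"mismatched cube shapes: {shape} vs {c.shape}")
    return np.stack([c[:, :, 0] for c in cubes], axis=2)


# ---------------------------------------------------------------------------
# the persisted decryption record
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CipherRecord:
    """Everything decryption needs, with an integrity checksum.

    The record stores explicit key-plane bytes rather than chaotic seeds, so
    a ciphertext decrypts bit-exactly on any platform.  The full rotation
    vector C is kept (one byte per layer) even though only C[0] affects the
    output.
    """

    height: int
    width: int
    depth: int
    channels: int
    flags: int
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    key_plane: np.ndarray
    format_version: int = FORMAT_VERSION

    @property
    def grayscale_expanded(self) -> bool:
        return bool(self.flags & FLAG_GRAYSCALE_EXPANDED)

    @property
    def rotation_restricted(self) -> bool:
        return bool(self.flags & FLAG_ROTATION_RESTRICTED)

    def _body(self) -> bytes:
        header = _HEADER.pack(
            MAGIC,
            self.format_version,
            self.flags,
            self.channels,
            0,
            self.height,
            self.width,
            self.depth,
        )
        return (
            header
            + np.ascontiguousarray(self.a, dtype="<u4").tobytes()
            + np.ascontiguousarray(self.b, dtype="<u4").tobytes()
            + np.ascontiguousarray(self.c, dtype=np.uint8).tobytes()
            + np.ascontiguousarray(self.key_plane, dtype=np.uint8).tobytes()
        )

    @property
    def checksum(self) -> bytes:
        return hashlib.sha256(self._body()).digest()

    def validate(self) -> None:
        if sorted(self.a.tolist()) != list(range(self.width)):
            raise IntegrityError("A is not a permutation of 0..width-1")
        if sorted(self.b.tolist()) != list(range(self.height)):
            raise IntegrityError("B is not a permutation of 0..height-1")
        if self.c.max(initial=0) > 3:
            raise IntegrityError("C contains a rotation count outside 0..3")
        if self.key_plane.shape != (self.height, self.width):
            raise IntegrityError("key plane shape does not match the header")

    def to_bytes(self) -> bytes:
        return self._body() + self.checksum

    @classmethod
    def from_bytes(cls, blob: bytes) -> "CipherRecord":
        if len(blob) < _HEADER.size + 32:
            raise IntegrityError("record truncated")
        magic, version, flags, channels, _, h, w, d = _HEADER.unpack_from(blob, 0)
        if magic != MAGIC:
            raise IntegrityError(f"bad magic {magic!r}; not a cipher record")
        if version != FORMAT_VERSION:
            raise IntegrityError(f"unsupported record version {version}")
        off = _HEADER.size
        need = off + 4 * w + 4 * h + d + h * w + 32
        if len(blob) != need:
            raise IntegrityError(f"record length {len(blob)} != expected {need}")
        a = np.frombuffer(blob, dtype="<u4", count=w, offset=off).astype(np.uint32)
        off += 4 * w
        b = np.frombuffer(blob, dtype="<u4", count=h, offset=off).astype(np.uint32)
        off += 4 * h
        c = np.frombuffer(blob, dtype=np.uint8, count=d, offset=off).copy()
        off += d
        plane = (
            np.frombuffer(blob, dtype=np.uint8, count=h * w, offset=off)
            .reshape(h, w)
            .copy()
        )
        off += h * w
        rec = cls(h, w, d, channels, flags, a, b, c, plane, version)
        if blob[off : off + 32] != rec.checksum:
            raise IntegrityError("checksum mismatch: record corrupted")
        rec.validate()
        return rec

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            fh.write(self.to_bytes())

    @classmethod
    def load(cls, path) -> "CipherRecord":
        with open(path, "rb") as fh:
            return cls.from_bytes(fh.read())


# ---------------------------------------------------------------------------
# encryption / decryption
# ---------------------------------------------------------------------------

def _keystream(img: np.ndarray, key_hex: str, params: ChaoticParams, depth: int):
    h, w = img.shape[:2]
    seeds = keying.seeds_for(img, key_hex)
    orbit = generate_orbit(params, seeds, required_orbit_length(h, w, depth))
    idx = make_index_arrays(orbit, h, w, depth)
    return orbit, idx


def _effective_turns(c0: int, restricted: bool) -> int:
    return (int(c0) % 2) * 2 if restricted else int(c0) % 4


def encrypt(
    img: np.ndarray,
    key_hex: str,
    params: ChaoticParams | None = None,
    *,
    engine: str = "fast",
) -> tuple[np.ndarray, CipherRecord]:
    """Encrypt an 8-bit image; returns the ciphertext and its decryption record.

    Deterministic given (img, key, params).  ``engine="fast"`` runs the
    2D-equivalent reduction; ``engine="full"`` materializes the per-channel
    cubes.  Both produce bitwise-identical ciphertexts and records.
    """
    if engine not in ("fast", "full"):
        raise ValidationError(f"unknown engine {engine!r}; expected 'fast' or 'full'")
    params = params or ChaoticParams()
    arr = validate_image(img)
    h, w, n_ch = arr.shape

    flags = 0
    work = arr
    if n_ch == 1:
        flags |= FLAG_GRAYSCALE_EXPANDED
        work = np.repeat(arr, 3, axis=2)
    restricted = h != w
    if restricted:
        flags |= FLAG_ROTATION_RESTRICTED

    depth = default_depth(h, w)
    orbit, idx = _keystream(arr, key_hex, params, depth)
    plane = key_plane(orbit, h, w, depth)
    turns = _effective_turns(idx.c[0], restricted)

    if engine == "full":
        kcube = make_key_cube(orbit, h, w, depth)
        out_channels = []
        for ci in range(work.shape[2]):
            cube = expand_to_cube(work[:, :, ci], depth)
            cube = permute(cube, idx.a, idx.b)
            cube = rotate_layers(cube, idx.c, restrict_180=restricted)
            cube = xor_with_key(cube, kcube)
            out_channels.append(cube)
        enc = collapse(out_channels)
    else:
        scrambled = permute(work, idx.a, idx.b)
        scrambled = np.rot90(scrambled, turns, axes=(0, 1))
        enc = np.bitwise_xor(scrambled, plane[:, :, None])

    if n_ch == 1:
        # the three expanded channels are byte-identical; keep the input shape
        enc = enc[:, :, :1]
    if img is not None and np.asarray(img).ndim == 2:
        enc = enc[:, :, 0]

    record = CipherRecord(
        height=h,
        width=w,
        depth=depth,
        channels=n_ch,
        flags=flags,
        a=idx.a,
        b=idx.b,
        c=idx.c,
        key_plane=plane,
    )
    return enc, record


def encrypt_fast(
    img: np.ndarray, key_hex: str, params: ChaoticParams | None = None
) -> tuple[np.ndarray, CipherRecord]:
    """The 2D-equivalent reduction of :func:`encrypt` (the default engine)."""
    return encrypt(img, key_hex, params, engine="fast")


def decrypt(cipher: np.ndarray, record: CipherRecord) -> np.ndarray:
    """Exact inverse of :func:`encrypt`, driven entirely by the record."""
    record.validate()
    arr = validate_image(cipher)
    squeeze = np.asarray(cipher).ndim == 2
    h, w, n_ch = arr.shape
    if (h, w) != (record.height, record.width):
        raise ValidationError(
            f"ciphertext {h}x{w} does not match record {record.height}x{record.width}"
        )
    if n_ch != record.channels:
        raise ValidationError(
            f"ciphertext has {n_ch} channel(s), record expects {record.channels}"
        )
    turns = _effective_turns(record.c[0], record.rotation_restricted)
    plain = np.bitwise_xor(arr, record.key_plane[:, :, None])
    plain = np.rot90(plain, (4 - turns) % 4, axes=(0, 1))
    plain = inverse_permute(plain, record.a, record.b)
    if squeeze:
        return plain[:, :, 0]
    return plain


# ---------------------------------------------------------------------------
# avalanche experiment (NPCR / UACI)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AvalancheResult:
    """Per-trial and mean NPCR/UACI of a one-bit/one-pixel perturbation study."""

    mode: str
    trials: int
    npcr_values: list = field(default_factory=list)
    uaci_values: list = field(default_factory=list)

    @property
    def mean_npcr(self) -> float:
        return float(np.mean(self.npcr_values))

    @property
    def mean_uaci(self) -> float:
        return float(np.mean(self.uaci_values))


def _flip_key_bit(key_hex: str, bit: int) -> str:
    raw = bytearray(bytes.fromhex(keying.validate_key(key_hex)))
    raw[bit // 8] ^= 1 << (bit % 8)
    return raw.hex()


def avalanche_experiment(
    img: np.ndarray,
    key_hex: str,
    params: ChaoticParams | None = None,
    *,
    trials: int = 20,
    mode: str = "plaintext",
    seed: int = 0,
) -> AvalancheResult:
    """Measure NPCR and UACI under minimal input or key perturbations.

    mode="plaintext": per trial one uniformly chosen pixel/channel is
    incremented by 1 mod 256 and both versions are encrypted under the same
    key.  mode="key": per trial one uniformly chosen key bit is flipped and
    the image is encrypted under both keys.  Statistics are pooled over all
    channels and averaged across trials; the perturbation RNG is explicit.
    """
    from .metrics import npcr, uaci  # local import to avoid a cycle

    if trials < 1:
        raise ValidationError(f"trials={trials!r} must be >= 1")
    if mode not in ("plaintext", "key"):
        raise ValidationError(f"unknown mode {mode!r}; expected 'plaintext' or 'key'")
    params = params or ChaoticParams()
    arr = validate_image(img)
    rng = np.random.default_rng(seed)
    base, _ = encrypt(arr, key_hex, params)

    npcr_vals, uaci_vals = [], []
    for _ in range(trials):
        if mode == "plaintext":
            i = int(rng.integers(arr.shape[0]))
            j = int(rng.integers(arr.shape[1]))
            ci = int(rng.integers(arr.shape[2]))
            perturbed = arr.copy()
            perturbed[i, j, ci] = np.uint8((int(perturbed[i, j, ci]) + 1) % 256)
            other, _ = encrypt(perturbed, key_hex, params)
        else:
            bit = int(rng.integers(keying.KEY_BITS))
            other, _ = encrypt(arr, _flip_key_bit(key_hex, bit), params)
        npcr_vals.append(npcr(base, other))
        uaci_vals.append(uaci(base, other))
    return AvalancheResult(mode, trials, npcr_vals, uaci_vals)
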