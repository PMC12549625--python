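"""Synthetic plant-image fixtures and lossless image I/O.

Real crop photographs (the scheme's intended plaintexts) are smooth,
green-dominant, and strongly correlated between adjacent pixels — exactly the
statistics that make a cipher's output contrast meaningful.  The generator
reproduces those statistics, not plant appearance: a low-frequency
green-dominant background (Gaussian-smoothed random fields, one shared
luminance field plus per-channel variation), zero or more soft-edged
elliptical lesion blobs with a brownish intensity shift, and mild pixel
speckle.  Output is deterministic per seed; the default 128x128 fixture has
horizontal adjacent-pixel luma correlation well above 0.7.

I/O is restricted to lossless 8-bit containers (PNG, BMP): a ciphertext
written through a lossy codec would be undecryptable, so lossy targets are
refused outright.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .exceptions import ValidationError

_BASE_RGB = (78.0, 122.0, 62.0)  # green-dominant canopy tone
_SHARED_AMP = 22.0  # shared luminance field amplitude
_CHANNEL_AMP = 14.0  # per-channel field amplitude (hue variation)
_LESION_RGB_WEIGHTS = (0.55, 1.0, 0.45)  # lesions hit green hardest (browning)

_LOSSLESS_SUFFIXES = {".png", ".bmp"}
_LOSSY_SUFFIXES = {".jpg", ".jpeg", ".webp"}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic plant image.

    ``smoothness`` is the Gaussian sigma (pixels) of the background fields;
    ``lesion_shift`` is the peak intensity change (8-bit levels, negative =
    darkening) inside a lesion; ``noise`` is the speckle standard deviation.
    """

    seed: int
    height: int = 128
    width: int = 128
    n_lesions: int = 3
    lesion_shift: int = -60
    smoothness: float = 8.0
    noise: float = 2.0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValidationError(
                f"fixture dimensions {self.height}x{self.width} too small (need >= 16)"
            )
        if self.n_lesions < 0:
            raise ValidationError("n_lesions must be >= 0")
        if self.smoothness <= 0:
            raise ValidationError("smoothness must be > 0")
        if self.noise < 0:
            raise ValidationError("noise must be >= 0")


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_plant_image(spec: FixtureSpec) -> np.ndarray:
    """Render one synthetic plant image (H x W x 3 uint8) from its spec."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    shared = _smooth_field(rng, (h, w), spec.smoothness)
    img = np.empty((h, w, 3), dtype=np.float64)
    for ci in range(3):
        own = _smooth_field(rng, (h, w), spec.smoothness)
        img[:, :, ci] = _BASE_RGB[ci] + _SHARED_AMP * shared + _CHANNEL_AMP * own

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    for _ in range(spec.n_lesions):
        cy = rng.uniform(0.15 * h, 0.85 * h)
        cx = rng.uniform(0.15 * w, 0.85 * w)
        ry = rng.uniform(0.04, 0.14) * h
        rx = rng.uniform(0.04, 0.14) * w
        theta = rng.uniform(0, np.pi)
        u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
        v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
        d = np.sqrt((u / rx) ** 2 + (v / ry) ** 2)
        mask = np.clip(1.25 - d, 0.0, 1.0)  # soft-edged ellipse
        for ci in range(3):
            img[:, :, ci] += spec.lesion_shift * _LESION_RGB_WEIGHTS[ci] * mask

    if spec.noise > 0:
        img += rng.normal(0.0, spec.noise, size=img.shape)
    return np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)


def fixture_suite(seed: int = 0, height: int = 128, width: int = 128) -> dict[str, np.ndarray]:
    """Eight deterministic fixtures: four lesion-free, four lesioned."""
    suite: dict[str, np.ndarray] = {}
    for i in range(4):
        spec = FixtureSpec(seed=seed * 100 + i, height=height, width=width, n_lesions=0)
        suite[f"healthy_{i + 1}"] = generate_plant_image(spec)
    for i in range(4):
        spec = FixtureSpec(seed=seed * 100 + 50 + i, height=height, width=width, n_lesions=4)
        suite[f"lesioned_{i + 1}"] = generate_plant_image(spec)
    return suite


def write_fixture_suite(outdir, seed: int = 0) -> Path:
    """Write the eight-image suite as PNGs plus a JSON manifest; returns its path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "images": {}}
    for i, (name, img) in enumerate(fixture_suite(seed).items()):
        path = out / f"{name}.png"
        write_image(img, path)
        manifest["images"][name] = {
            "file": path.name,
            "sha256": hashlib.sha256(img.tobytes()).hexdigest(),
            "shape": list(img.shape),
        }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


# ---------------------------------------------------------------------------
# lossless I/O
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Read an 8-bit grayscale or RGB image from a PNG or BMP file."""
    p = Path(path)
    if p.suffix.lower() not in _LOSSLESS_SUFFIXES:
        raise ValidationError(
            f"unsupported container {p.suffix!r}; only PNG and BMP are supported"
        )
    if not p.exists():
        raise FileNotFoundError(f"no such image file: {p}")
    with Image.open(p) as im:
        if im.mode not in ("L", "RGB"):
            raise ValidationError(
                f"unsupported image mode {im.mode!r} (bit depth != 8 or extra "
                "channels); only 8-bit grayscale (L) and RGB are supported"
            )
        return np.asarray(im, dtype=np.uint8)


def write_image(img: np.ndarray, path) -> None:
    """Write an 8-bit image losslessly; lossy targets are refused.

    Writing through a lossy codec silently destroys decryptability, so .jpg,
    .jpeg and .webp raise a :class:`ValidationError`.
    """
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix in _LOSSY_SUFFIXES:
        raise ValidationError(
            f"refusing to write {suffix!r}: lossy compression corrupts encrypted "
            "pixel data and makes the image undecryptable; use .png or .bmp"
        )
    if suffix not in _LOSSLESS_SUFFIXES:
        raise ValidationError(
            f"unsupported container {suffix!r}; only PNG and BMP are supported"
        )
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        raise ValidationError(f"image must be uint8, got {arr.dtype}")
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim == 2:
        im = Image.fromarray(arr, mode="L")
    elif arr.ndim == 3 and arr.shape[2] == 3:
        im = Image.fromarray(arr, mode="RGB")
    else:
        raise ValidationError(f"cannot write image of shape {arr.shape}")
    im.save(p)
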