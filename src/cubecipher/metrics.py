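"""Security statistics for (plaintext, ciphertext) image pairs.

Implements the full evaluation battery a cipher designer reports: Shannon
entropy of the 256-bin histogram, GLCM texture statistics (contrast, energy,
homogeneity) from a normalized co-occurrence matrix, global SSIM, MSE,
structural content, NPCR/UACI differential metrics, adjacent-pixel Pearson
correlation, a chi-square histogram-uniformity test, and key-space /
brute-force reporting.

Conventions: texture, entropy and correlation statistics operate on the
BT.601 luma conversion of an RGB image; NPCR and UACI pool all channels.
The histogram-uniformity check in :func:`evaluate` runs on the pooled raw
channel bytes rather than the luma, because with a key stream shared across
channels each channel's byte histogram is uniform while the luma of the
channel triple is not (a weighted sum of dependent uniforms concentrates).
Structural content follows the printed nonstandard form
``sum(orig^2) / sum((orig-enc)^2)``; the classical denominator
``sum(enc^2)`` is available behind ``classical=True``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from decimal import Context
from typing import Optional

import numpy as np
from scipy import stats

from .exceptions import UndefinedMetricError, ValidationError

_LUMA = (0.299, 0.587, 0.114)
_C1 = (0.01 * 255.0) ** 2
_C2 = (0.03 * 255.0) ** 2


def _as_uint8(img: np.ndarray, name: str = "image") -> np.ndarray:
    arr = np.asarray(img)
    if arr.size == 0:
        raise ValidationError(f"{name} is empty")
    if arr.dtype != np.uint8:
        raise ValidationError(f"{name} must be uint8, got {arr.dtype}")
    return arr


def to_gray(img: np.ndarray) -> np.ndarray:
    """BT.601 luma (0.299 R + 0.587 G + 0.114 B), rounded half-up to uint8.

    Grayscale input (2-D or single-channel) passes through unchanged.
    """
    arr = _as_uint8(img)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] == 1:
        return arr[:, :, 0]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected HxW or HxWx{{1,3}} image, got {arr.shape}")
    luma = (
        _LUMA[0] * arr[:, :, 0].astype(np.float64)
        + _LUMA[1] * arr[:, :, 1]
        + _LUMA[2] * arr[:, :, 2]
    )
    return np.clip(np.floor(luma + 0.5), 0, 255).astype(np.uint8)


def shannon_entropy(gray: np.ndarray) -> float:
    """Shannon entropy in bits of the 256-bin histogram; empty bins contribute 0."""
    arr = _as_uint8(gray, "gray")
    counts = np.bincount(arr.ravel(), minlength=256)
    p = counts[counts > 0] / arr.size
    return float(-(p * np.log2(p)).sum())


def cooccurrence(gray: np.ndarray, offset: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Normalized 256x256 gray-level co-occurrence matrix at the given offset.

    Non-symmetric, counts (gray[i, j], gray[i+di, j+dj]) pairs; entries sum
    to 1.  Default offset (0, 1) is the horizontal neighbour.
    """
    arr = _as_uint8(gray, "gray")
    if arr.ndim != 2:
        raise ValidationError(f"gray image must be 2-D, got {arr.shape}")
    di, dj = offset
    h, w = arr.shape
    if abs(di) >= h or abs(dj) >= w:
        raise ValidationError(f"offset {offset} does not fit a {h}x{w} image")
    src = arr[max(0, -di) : h - max(0, di), max(0, -dj) : w - max(0, dj)]
    dst = arr[max(0, di) : h + min(0, di), max(0, dj) : w + min(0, dj)]
    idx = src.astype(np.int64).ravel() * 256 + dst.astype(np.int64).ravel()
    counts = np.bincount(idx, minlength=65536).reshape(256, 256).astype(np.float64)
    return counts / counts.sum()


def _check_normalized(o: np.ndarray) -> np.ndarray:
    o = np.asarray(o, dtype=np.float64)
    if o.shape != (256, 256):
        raise ValidationError(f"co-occurrence matrix must be 256x256, got {o.shape}")
    if not math.isclose(o.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValidationError("co-occurrence matrix is not normalized")
    return o


_LEVELS = np.arange(256, dtype=np.float64)
_ABS_DIFF = np.abs(_LEVELS[:, None] - _LEVELS[None, :])


def glcm_contrast(o: np.ndarray) -> float:
    """sum_{a,b} |a-b|^2 O(a,b)."""
    return float((_ABS_DIFF**2 * _check_normalized(o)).sum())


def glcm_energy(o: np.ndarray) -> float:
    """sum_{a,b} O(a,b)^2."""
    return float((_check_normalized(o) ** 2).sum())


def glcm_homogeneity(o: np.ndarray) -> float:
    """sum_{a,b} O(a,b) / (1 + |a-b|)."""
    return float((_check_normalized(o) / (1.0 + _ABS_DIFF)).sum())


def _pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    aa = _as_uint8(a, "first image")
    bb = _as_uint8(b, "second image")
    if aa.shape != bb.shape:
        raise ValidationError(f"shape mismatch: {aa.shape} vs {bb.shape}")
    return aa, bb


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared pixel difference."""
    aa, bb = _pair(a, b)
    d = aa.astype(np.float64) - bb.astype(np.float64)
    return float(np.mean(d * d))


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Global-statistics SSIM (single window = whole image, 8-bit constants)."""
    aa, bb = _pair(a, b)
    x = aa.astype(np.float64)
    y = bb.astype(np.float64)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    return float(
        (2 * mx * my + _C1)
        * (2 * cov + _C2)
        / ((mx * mx + my * my + _C1) * (vx + vy + _C2))
    )


def structural_content(orig: np.ndarray, enc: np.ndarray, *, classical: bool = False) -> float:
    """Structural content, as printed: sum(orig^2) / sum((orig - enc)^2).

    ``classical=True`` uses the textbook denominator sum(enc^2) instead.
    Raises :class:`UndefinedMetricError` when the denominator is zero.
    """
    oo, ee = _pair(orig, enc)
    num = float((oo.astype(np.float64) ** 2).sum())
    if classical:
        den = float((ee.astype(np.float64) ** 2).sum())
    else:
        d = oo.astype(np.float64) - ee.astype(np.float64)
        den = float((d * d).sum())
    if den == 0.0:
        raise UndefinedMetricError(
            "structural content undefined: zero denominator (identical images)"
            if not classical
            else "structural content undefined: all-zero encrypted image"
        )
    return num / den


def npcr(c1: np.ndarray, c2: np.ndarray) -> float:
    """Number of Pixel Change Rate, %: positions (all channels pooled) that differ."""
    a, b = _pair(c1, c2)
    return float(100.0 * np.mean(a != b))


def uaci(c1: np.ndarray, c2: np.ndarray) -> float:
    """Unified Average Changing Intensity, %: mean |c1 - c2| / 255, pooled."""
    a, b = _pair(c1, c2)
    diff = np.abs(a.astype(np.int16) - b.astype(np.int16))
    return float(100.0 * diff.mean() / 255.0)


_DIRECTIONS = {"horizontal": (0, 1), "vertical": (1, 0), "diagonal": (1, 1)}


def adjacent_correlation(gray: np.ndarray, direction: str = "horizontal") -> float:
    """Pearson correlation of all adjacent pixel pairs in a direction.

    Deterministic (no pair sampling).  Raises
    :class:`UndefinedMetricError` for zero variance in either pair member.
    """
    arr = _as_uint8(gray, "gray")
    if arr.ndim != 2:
        raise ValidationError(f"gray image must be 2-D, got {arr.shape}")
    try:
        di, dj = _DIRECTIONS[direction]
    except KeyError:
        raise ValidationError(
            f"unknown direction {direction!r}; expected one of {sorted(_DIRECTIONS)}"
        ) from None
    h, w = arr.shape
    if h - di < 1 or w - dj < 1:
        raise ValidationError(f"image {h}x{w} too small for direction {direction!r}")
    x = arr[: h - di, : w - dj].astype(np.float64).ravel()
    y = arr[di:, dj:].astype(np.float64).ravel()
    if x.std() == 0.0 or y.std() == 0.0:
        raise UndefinedMetricError("correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def histogram_uniformity(values: np.ndarray) -> tuple[float, float]:
    """Chi-square test of the 256-bin byte histogram against uniformity.

    Returns (statistic, upper-tail p-value) with 255 degrees of freedom.
    Accepts any uint8 array (a gray image, one channel, or pooled channels).
    """
    arr = _as_uint8(values, "values")
    if arr.size < 256:
        raise ValidationError(f"need at least 256 values, got {arr.size}")
    counts = np.bincount(arr.ravel(), minlength=256).astype(np.float64)
    expected = arr.size / 256.0
    stat = float(((counts - expected) ** 2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=255))


# ---------------------------------------------------------------------------
# key space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KeySpaceReport:
    """Brute-force cost of an exhaustive key search (365-day years)."""

    bits: int
    n_keys: int
    n_keys_scientific: str
    rate_per_sec: float
    seconds: float
    years: float


def _sci3(n: int) -> str:
    """Three-significant-figure scientific rendering of a big integer."""
    d = Context(prec=3).create_decimal(n)
    mantissa, _, exponent = f"{d:E}".partition("E")
    return f"{mantissa}e{int(exponent):+d}"


def key_space_report(bits: int, rate_per_sec: float = 1e18) -> KeySpaceReport:
    """Exact 2**bits key count and the time to exhaust it at a given rate."""
    if bits < 1:
        raise ValidationError(f"bits={bits!r} must be >= 1")
    if rate_per_sec <= 0:
        raise ValidationError(f"rate_per_sec={rate_per_sec!r} must be > 0")
    n = 1 << bits
    seconds = float(n) / rate_per_sec
    return KeySpaceReport(
        bits=bits,
        n_keys=n,
        n_keys_scientific=_sci3(n),
        rate_per_sec=rate_per_sec,
        seconds=seconds,
        years=seconds / (86400.0 * 365.0),
    )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _round6(v: Optional[float]) -> Optional[float]:
    if v is None:
        return None
    if v == 0 or not math.isfinite(v):
        return v
    return float(f"{v:.6g}")


@dataclass(frozen=True)
class MetricReport:
    """One record of every security statistic for an (original, encrypted) pair.

    Fields that are mathematically undefined for the pair (structural content
    of identical images, correlation of a constant image) are ``None``.
    """

    entropy: float
    contrast: float
    energy: float
    homogeneity: float
    ssim: float
    mse: float
    structural_content: Optional[float]
    correlation_h: Optional[float]
    correlation_v: Optional[float]
    npcr: float
    uaci: float
    chi_square: float
    chi_square_p: float
    metadata: dict

    def to_json(self) -> str:
        d = asdict(self)
        meta = d.pop("metadata")
        d = {k: _round6(v) for k, v in d.items()}
        d["metadata"] = meta
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MetricReport":
        d = json.loads(text)
        return cls(**d)


def evaluate(orig: np.ndarray, enc: np.ndarray, metadata: dict | None = None) -> MetricReport:
    """Compute the full metric battery for an (original, encrypted) pair.

    Texture/entropy/correlation statistics are computed on the luma of the
    encrypted image; SSIM/MSE/SC compare the two lumas; NPCR/UACI and the
    chi-square uniformity test pool all channels.
    """
    o = _as_uint8(orig, "original")
    e = _as_uint8(enc, "encrypted")
    if o.shape != e.shape:
        raise ValidationError(f"shape mismatch: {o.shape} vs {e.shape}")
    go, ge = to_gray(o), to_gray(e)
    occ = cooccurrence(ge)

    try:
        sc = structural_content(go, ge)
    except UndefinedMetricError:
        sc = None
    corr = {}
    for key, direction in (("h", "horizontal"), ("v", "vertical")):
        try:
            corr[key] = adjacent_correlation(ge, direction)
        except UndefinedMetricError:
            corr[key] = None
    chi2_stat, chi2_p = histogram_uniformity(e)

    return MetricReport(
        entropy=shannon_entropy(ge),
        contrast=glcm_contrast(occ),
        energy=glcm_energy(occ),
        homogeneity=glcm_homogeneity(occ),
        ssim=ssim(go, ge),
        mse=mse(go, ge),
        structural_content=sc,
        correlation_h=corr["h"],
        correlation_v=corr["v"],
        npcr=npcr(o, e),
        uaci=uaci(o, e),
        chi_square=chi2_stat,
        chi_square_p=chi2_p,
        metadata=metadata or {},
    )


def plot_histograms(orig: np.ndarray, enc: np.ndarray, path) -> None:
    """Side-by-side 256-bin luma histograms of the pair, written as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=True)
    for ax, img, title in ((axes[0], orig, "original"), (axes[1], enc, "encrypted")):
        ax.hist(to_gray(img).ravel(), bins=256, range=(0, 256), color="tab:green")
        ax.set_title(title)
        ax.set_xlabel("gray level")
    axes[0].set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
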