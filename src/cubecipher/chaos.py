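"""The coupled 3D logistic map and the key material derived from its orbits.

Three logistic maps are coupled through cross-product terms::

    x' = r_x * x * (1 - x) + beta  * y * z
    y' = r_y * y * (1 - y) + gamma * x * z
    z' = r_z * z * (1 - z) + alpha * x * y

with growth rates inside the chaotic window (3.57, 4] and small non-negative
coupling coefficients.  The coupling can push a state slightly outside (0, 1),
so every raw update is wrapped by its fractional part and clamped into
[1e-6, 1 - 1e-6]; within (0, 1) the wrap is the identity, so the uncoupled map
is reproduced exactly.

One orbit supplies, from disjoint segments, everything the cipher needs:

* ``A`` — a width-sized permutation, the stable argsort of the first W values
  of X (column permutation);
* ``B`` — a height-sized permutation from the first H values of Y (rows);
* ``C`` — per-layer quarter-turn counts, floor(4 z) clamped to 3, from the
  first D values of Z;
* ``K`` — the H x W x D byte key cube, floor(256 x) clamped to 255, filled
  row-major from the X values after the A segment.

Using disjoint segments keeps the permutation indices statistically
independent of the key bytes.  Chaoticity is checked with a Lyapunov-exponent
estimate along X: the mean of ln|r_x (1 - 2 x_i)|, the log-derivative of the
uncoupled update (the coupling term is constant in x).  For the uncoupled
map at r = 4 this converges to ln 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .keying import SeedTriple

DEFAULT_BURN_IN = 1000
_LO = 1e-6
_HI = 1.0 - 1e-6


@dataclass(frozen=True)
class ChaoticParams:
    """Growth rates, coupling coefficients and transient length of the map.

    Growth rates default to 3.99/3.98/3.97, well inside the chaotic window
    (3.57, 4]; the cipher should only be used with rates in that window, but
    any rate in (0, 4] is accepted so periodic regimes (e.g. r = 3.2) can be
    studied with the Lyapunov estimator.  Couplings default to 0.01, small
    enough that the bounded map stays chaotic.
    """

    r_x: float = 3.99
    r_y: float = 3.98
    r_z: float = 3.97
    alpha: float = 0.01
    beta: float = 0.01
    gamma: float = 0.01
    burn_in: int = DEFAULT_BURN_IN

    def __post_init__(self) -> None:
        for name, r in (("r_x", self.r_x), ("r_y", self.r_y), ("r_z", self.r_z)):
            if not (0.0 < r <= 4.0):
                raise ValidationError(f"{name}={r!r} outside (0, 4.0]")
        for name, c in (("alpha", self.alpha), ("beta", self.beta), ("gamma", self.gamma)):
            if c < 0:
                raise ValidationError(f"{name}={c!r} must be non-negative")
        if self.burn_in < 0:
            raise ValidationError(f"burn_in={self.burn_in!r} must be >= 0")


@dataclass(frozen=True)
class Orbit:
    """Post-transient chaotic sequences X, Y, Z, all the same length, in (0,1)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class IndexArrays:
    """Permutations A (columns), B (rows) and rotation counts C (layers)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray


def _bound(v: float) -> float:
    v = v % 1.0
    if v < _LO:
        return _LO
    if v > _HI:
        return _HI
    return v


def step(
    params: ChaoticParams, x: float, y: float, z: float
) -> tuple[float, float, float]:
    """One update of the coupled map; inputs must lie in (0, 1)."""
    xn = params.r_x * x * (1.0 - x) + params.beta * y * z
    yn = params.r_y * y * (1.0 - y) + params.gamma * x * z
    zn = params.r_z * z * (1.0 - z) + params.alpha * x * y
    return _bound(xn), _bound(yn), _bound(zn)


def _iterate_py(x, y, z, rx, ry, rz, alpha, beta, gamma, burn, n):
    out_x = np.empty(n)
    out_y = np.empty(n)
    out_z = np.empty(n)
    lo, hi = _LO, _HI
    for i in range(burn + n):
        xn = rx * x * (1.0 - x) + beta * y * z
        yn = ry * y * (1.0 - y) + gamma * x * z
        zn = rz * z * (1.0 - z) + alpha * x * y
        xn = xn % 1.0
        yn = yn % 1.0
        zn = zn % 1.0
        x = lo if xn < lo else (hi if xn > hi else xn)
        y = lo if yn < lo else (hi if yn > hi else yn)
        z = lo if zn < lo else (hi if zn > hi else zn)
        j = i - burn
        if j >= 0:
            out_x[j] = x
            out_y[j] = y
            out_z[j] = z
    return out_x, out_y, out_z


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _iterate = njit(cache=True)(_iterate_py)
except ImportError:  # pragma: no cover
    _iterate = _iterate_py


def generate_orbit(params: ChaoticParams, seeds: SeedTriple, n: int) -> Orbit:
    """Iterate ``burn_in + n`` steps, discard the transient, return ``n`` triples."""
    if n < 1:
        raise ValidationError(f"orbit length n={n!r} must be >= 1")
    x, y, z = _iterate(
        seeds.x0,
        seeds.y0,
        seeds.z0,
        params.r_x,
        params.r_y,
        params.r_z,
        params.alpha,
        params.beta,
        params.gamma,
        params.burn_in,
        n,
    )
    return Orbit(x, y, z)


def required_orbit_length(height: int, width: int, depth: int) -> int:
    """Orbit length needed for the index arrays plus a disjoint key-cube segment."""
    return max(width + height * width * depth, height, depth)


def make_index_arrays(orbit: Orbit, height: int, width: int, depth: int) -> IndexArrays:
    """Permutations and rotation counts from the leading orbit segments."""
    if len(orbit.x) < width or len(orbit.y) < height or len(orbit.z) < depth:
        raise ValidationError(
            f"orbit of length {len(orbit)} too short for index arrays "
            f"(need width={width}, height={height}, depth={depth}); "
            f"generate at least {required_orbit_length(height, width, depth)} values"
        )
    a = np.argsort(orbit.x[:width], kind="stable").astype(np.uint32)
    b = np.argsort(orbit.y[:height], kind="stable").astype(np.uint32)
    c = np.minimum(np.floor(orbit.z[:depth] * 4.0), 3.0).astype(np.uint8)
    return IndexArrays(a, b, c)


def _key_values(orbit: Orbit, height: int, width: int, depth: int) -> np.ndarray:
    need = width + height * width * depth
    if len(orbit.x) < need:
        raise ValidationError(
            f"orbit of length {len(orbit)} too short for a "
            f"{height}x{width}x{depth} key cube; generate at least {need} values"
        )
    return orbit.x[width : width + height * width * depth]


def make_key_cube(orbit: Orbit, height: int, width: int, depth: int) -> np.ndarray:
    """The H x W x D byte key cube K = min(floor(256 x), 255), filled row-major.

    The X segment used starts after the ``width`` values reserved for the
    column permutation, so key bytes and permutation indices never share
    orbit values.
    """
    vals = _key_values(orbit, height, width, depth)
    k = np.minimum(np.floor(vals * 256.0), 255.0).astype(np.uint8)
    return k.reshape(height, width, depth)


def key_plane(orbit: Orbit, height: int, width: int, depth: int) -> np.ndarray:
    """Layer 0 of the key cube without materializing the cube.

    Under row-major (i, j, k) fill the layer-0 bytes are the X values at
    stride ``depth``; this is what the 2D-equivalent fast path consumes.
    """
    vals = _key_values(orbit, height, width, depth)[::depth]
    k = np.minimum(np.floor(vals * 256.0), 255.0).astype(np.uint8)
    return k.reshape(height, width)


def estimate_lyapunov(params: ChaoticParams, seeds: SeedTriple, n: int) -> float:
    """Estimate the largest Lyapunov exponent along the X component.

    Averages ln|r_x (1 - 2 x_i)| over a length-``n`` post-transient orbit.
    Terms where x_i is exactly 0.5 (zero derivative, log undefined) are
    skipped; a positive estimate indicates exponential divergence of nearby
    trajectories.
    """
    if n < 1000:
        raise ValidationError(f"n={n!r} too small for a stable estimate (need >= 1000)")
    orbit = generate_orbit(params, seeds, n)
    deriv = np.abs(params.r_x * (1.0 - 2.0 * orbit.x))
    mask = deriv > 0.0
    if not mask.any():
        raise ValidationError("all derivative terms vanished; estimate undefined")
    return float(np.mean(np.log(deriv[mask])))
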