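"""Substrate surfaces: flat, periodic Gaussian nanostructure arrays, gridded height maps.

A surface is a single-valued height field ``z = f(x, y)`` over a periodic
lateral cell.  Everything downstream (area-weighted sampling, sphere
deposition, coverage normalisation) needs three local quantities:

* the height ``f``,
* the lateral gradient ``(f_x, f_y)``,
* the area-element weight ``w = sqrt(1 + f_x^2 + f_y^2)`` — the Jacobian
  relating projected area ``dx dy`` to true surface area ``dA = w dx dy``.

The outward unit normal is ``n = (-f_x, -f_y, 1) / w``.

All lengths are in nanometres; the coordinate origin sits at the cell
corner and the cell spans ``[0, Lx) x [0, Ly)`` with periodic wrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "GaussianArraySpec",
    "HeightField",
    "Surface",
    "SurfaceArea",
    "InvalidSurfaceError",
    "CalibrationError",
    "make_flat_surface",
    "make_gaussian_surface",
    "make_heightfield_surface",
    "surface_area",
    "calibrate_dp",
    "sample_surface_point",
]

_LN2 = math.log(2.0)

# surface kind codes shared with the compiled deposition kernels
KIND_FLAT = 0
KIND_GAUSSIAN = 1
KIND_GRID = 2


class InvalidSurfaceError(ValueError):
    """Raised for ill-formed surface specifications or height data."""


class CalibrationError(RuntimeError):
    """Raised when no peak spacing can reach the requested area ratio."""


@dataclass(frozen=True)
class GaussianArraySpec:
    """Periodic array of axisymmetric truncated-Gaussian features.

    Parameters
    ----------
    H : float
        Signed feature height in nm.  Positive values give pillars/spikes,
        negative values give holes.
    W : float
        Width at half height in nm (must be positive).
    d_p : float
        Peak-to-peak spacing in nm.  Each feature is truncated to zero
        outside the lateral radius ``d_p / 2``, so neighbouring features
        never overlap.  The truncation is part of the profile definition
        and produces a height step on the truncation circle whenever the
        Gaussian has not decayed there.
    """

    H: float
    W: float
    d_p: float

    def __post_init__(self) -> None:
        if not (self.W > 0):
            raise InvalidSurfaceError(f"width at half height must be positive, got W={self.W}")
        if not (self.d_p > 0):
            raise InvalidSurfaceError(f"peak spacing must be positive, got d_p={self.d_p}")

    @property
    def variance(self) -> float:
        """Gaussian variance ``v = (W/2)^2 / (2 ln 2)`` in nm^2 (derived, never stored)."""
        return (self.W / 2.0) ** 2 / (2.0 * _LN2)


@dataclass(frozen=True)
class HeightField:
    """Gridded height map, e.g. from an AFM scan or the synthetic generator.

    ``z`` has shape ``(ny, nx)``; node ``(i, j)`` sits at ``(i*dx, j*dy)``
    so rows index y.  The field is treated as one periodic tile.
    """

    dx: float
    dy: float
    z: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "z", z)
        if z.ndim != 2 or z.shape[0] < 4 or z.shape[1] < 4:
            raise InvalidSurfaceError(f"height grid must be at least 4x4, got shape {z.shape}")
        if not (self.dx > 0 and self.dy > 0):
            raise InvalidSurfaceError(f"grid spacing must be positive, got dx={self.dx}, dy={self.dy}")
        if not np.all(np.isfinite(z)):
            raise InvalidSurfaceError("height grid contains non-finite entries")

    @property
    def nx(self) -> int:
        return self.z.shape[1]

    @property
    def ny(self) -> int:
        return self.z.shape[0]


class SurfaceArea(NamedTuple):
    """Curved area ``A_s``, projected area ``A_f`` and their ratio."""

    A_s: float
    A_f: float
    ratio: float


@dataclass
class Surface:
    """A periodic substrate cell with height, gradient and area-weight queries.

    Instances are built by the ``make_*`` factories.  ``kind``/``params``/
    ``grids`` encode the surface for the compiled deposition kernels; the
    callables provide the vectorised Python-level API.
    """

    Lx: float
    Ly: float
    kind: int
    params: np.ndarray
    zgrid: np.ndarray
    fxgrid: np.ndarray
    fygrid: np.ndarray
    w_max: float
    zmin: float
    zmax: float
    periodic: bool = True
    _area_cache: dict = field(default_factory=dict, repr=False)

    # -- local queries -------------------------------------------------
    def height(self, x, y):
        z, _, _ = self._eval(np.asarray(x, float), np.asarray(y, float))
        return z

    def gradient(self, x, y):
        _, fx, fy = self._eval(np.asarray(x, float), np.asarray(y, float))
        return fx, fy

    def area_weight(self, x, y):
        """Area-element weight ``w = sqrt(1 + |grad f|^2) >= 1``."""
        fx, fy = self.gradient(x, y)
        return np.sqrt(1.0 + fx * fx + fy * fy)

    def normal(self, x, y):
        """Outward unit normal ``(-f_x, -f_y, 1)/w`` as an ``(..., 3)`` array."""
        _, fx, fy = self._eval(np.asarray(x, float), np.asarray(y, float))
        w = np.sqrt(1.0 + fx * fx + fy * fy)
        return np.stack([-fx / w, -fy / w, 1.0 / w], axis=-1)

    def _eval(self, x, y):
        if self.kind == KIND_FLAT:
            zero = np.zeros(np.broadcast(x, y).shape)
            return zero, zero.copy(), zero.copy()
        if self.kind == KIND_GAUSSIAN:
            H, v, d_p, rt2 = self.params[2], self.params[3], self.params[4], self.params[5]
            ox = np.mod(x, d_p) - 0.5 * d_p
            oy = np.mod(y, d_p) - 0.5 * d_p
            r2 = ox * ox + oy * oy
            inside = r2 <= rt2
            z = np.where(inside, H * np.exp(-0.5 * r2 / v), 0.0)
            fx = np.where(inside, -z * ox / v, 0.0)
            fy = np.where(inside, -z * oy / v, 0.0)
            return z, fx, fy
        return _bilinear_eval(self, x, y)

    def area(self, resolution: float | None = None) -> SurfaceArea:
        """Cached :func:`surface_area` at the given (or default) resolution."""
        key = resolution
        if key not in self._area_cache:
            self._area_cache[key] = surface_area(self, resolution)
        return self._area_cache[key]


def _bilinear_eval(surface: Surface, x, y):
    zg, fxg, fyg = surface.zgrid, surface.fxgrid, surface.fygrid
    gdx, gdy = surface.params[6], surface.params[7]
    ny, nx = zg.shape
    fx_ = np.asarray(x, float) / gdx
    fy_ = np.asarray(y, float) / gdy
    i0 = np.floor(fx_).astype(np.int64)
    j0 = np.floor(fy_).astype(np.int64)
    tx = fx_ - i0
    ty = fy_ - j0
    i0 = np.mod(i0, nx)
    j0 = np.mod(j0, ny)
    i1 = (i0 + 1) % nx
    j1 = (j0 + 1) % ny
    w00 = (1 - tx) * (1 - ty)
    w10 = tx * (1 - ty)
    w01 = (1 - tx) * ty
    w11 = tx * ty

    def interp(g):
        return w00 * g[j0, i0] + w10 * g[j0, i1] + w01 * g[j1, i0] + w11 * g[j1, i1]

    return interp(zg), interp(fxg), interp(fyg)


# ---------------------------------------------------------------------------
# factories
# ---------------------------------------------------------------------------

_DUMMY = np.zeros((1, 1))


def make_flat_surface(Lx: float, Ly: float | None = None) -> Surface:
    """A flat periodic cell of the given lateral extent (nm)."""
    if Ly is None:
        Ly = Lx
    if not (Lx > 0 and Ly > 0):
        raise InvalidSurfaceError("cell extents must be positive")
    params = np.array([Lx, Ly, 0, 0, 0, 0, 0, 0], float)
    return Surface(Lx, Ly, KIND_FLAT, params, _DUMMY, _DUMMY, _DUMMY,
                   w_max=1.0, zmin=0.0, zmax=0.0)


def make_gaussian_surface(spec: GaussianArraySpec, cells: tuple[int, int] = (1, 1)) -> Surface:
    """Tile ``cells`` copies of the truncated-Gaussian feature into a periodic cell.

    Peaks sit at cell centres ``((i + 1/2) d_p, (j + 1/2) d_p)``.  The profile
    is exactly zero outside the truncation circle of radius ``d_p / 2`` around
    each peak, where the gradient is likewise zero.
    """
    mx, my = int(cells[0]), int(cells[1])
    if mx < 1 or my < 1:
        raise InvalidSurfaceError("need at least a 1x1 tiling")
    v = spec.variance
    d_p = spec.d_p
    rt = 0.5 * d_p
    params = np.array([mx * d_p, my * d_p, spec.H, v, d_p, rt * rt, 0, 0], float)
    # max slope of the radial profile g(r) = |H| r/v exp(-r^2/2v) on [0, rt]
    r_star = min(math.sqrt(v), rt)
    gmax = abs(spec.H) * r_star / v * math.exp(-0.5 * r_star * r_star / v)
    w_max = math.sqrt(1.0 + gmax * gmax)
    return Surface(mx * d_p, my * d_p, KIND_GAUSSIAN, params, _DUMMY, _DUMMY, _DUMMY,
                   w_max=w_max, zmin=min(0.0, spec.H), zmax=max(0.0, spec.H))


def make_heightfield_surface(hf: HeightField) -> Surface:
    """Wrap a gridded height map as a periodic surface.

    Height is interpolated bilinearly; the gradient is computed by periodic
    central differences at the nodes and itself interpolated bilinearly, so
    both fields are continuous across the tile seam.
    """
    z = hf.z
    fxg = (np.roll(z, -1, axis=1) - np.roll(z, 1, axis=1)) / (2.0 * hf.dx)
    fyg = (np.roll(z, -1, axis=0) - np.roll(z, 1, axis=0)) / (2.0 * hf.dy)
    Lx = hf.nx * hf.dx
    Ly = hf.ny * hf.dy
    params = np.array([Lx, Ly, 0, 0, 0, 0, hf.dx, hf.dy], float)
    # bilinear interpolation is a convex combination, so node-wise maxima
    # of |fx| and |fy| bound the interpolated gradient components
    w_max = float(np.sqrt(1.0 + np.max(np.abs(fxg)) ** 2 + np.max(np.abs(fyg)) ** 2))
    return Surface(Lx, Ly, KIND_GRID, params,
                   np.ascontiguousarray(z), np.ascontiguousarray(fxg), np.ascontiguousarray(fyg),
                   w_max=w_max, zmin=float(z.min()), zmax=float(z.max()))


# ---------------------------------------------------------------------------
# area integration and spacing calibration
# ---------------------------------------------------------------------------

#: default integration resolution: one tenth of the 7 nm protein diameter
DEFAULT_RESOLUTION = 0.7


def surface_area(surface: Surface, resolution: float | None = None) -> SurfaceArea:
    """Midpoint-rule estimate of the curved area over one periodic cell.

    ``A_s = sum w(x_m, y_m) dx dy`` over midpoints at spacing <= ``resolution``
    (default 0.7 nm).  Rows are processed in chunks so multi-micron height
    maps do not allocate the full sample grid at once.
    """
    if resolution is None:
        resolution = DEFAULT_RESOLUTION
    if not (resolution > 0):
        raise InvalidSurfaceError("resolution must be positive")
    if surface.kind == KIND_FLAT:
        af = surface.Lx * surface.Ly
        return SurfaceArea(af, af, 1.0)
    nx = max(8, int(math.ceil(surface.Lx / resolution)))
    ny = max(8, int(math.ceil(surface.Ly / resolution)))
    hx = surface.Lx / nx
    hy = surface.Ly / ny
    xm = (np.arange(nx) + 0.5) * hx
    total = 0.0
    chunk = max(1, int(2_000_000 // nx))
    for j0 in range(0, ny, chunk):
        ym = (np.arange(j0, min(j0 + chunk, ny)) + 0.5) * hy
        w = surface.area_weight(xm[None, :], ym[:, None])
        total += float(w.sum())
    A_s = total * hx * hy
    A_f = surface.Lx * surface.Ly
    return SurfaceArea(A_s, A_f, A_s / A_f)


def calibrate_dp(H: float, W: float, target_ratio: float,
                 resolution: float | None = None, rtol: float = 1e-3) -> float:
    """Find the peak spacing ``d_p`` whose cell has area ratio ``A_s/A_f = target_ratio``.

    The ratio decreases strictly with ``d_p`` (wider spacing dilutes the
    curved feature over more flat area), so bisection over ``[W, 50 W]``
    against the same midpoint integrator used by :func:`surface_area`
    converges and makes the round trip self-consistent.
    """
    from scipy.optimize import brentq

    if H == 0.0:
        raise CalibrationError("a flat profile (H=0) always has area ratio 1")
    if not (target_ratio > 1.0):
        raise CalibrationError(f"target ratio must exceed 1, got {target_ratio}")

    def ratio_minus_target(d_p: float) -> float:
        surf = make_gaussian_surface(GaussianArraySpec(H, W, d_p))
        return surface_area(surf, resolution).ratio - target_ratio

    lo, hi = W, 50.0 * W
    f_lo, f_hi = ratio_minus_target(lo), ratio_minus_target(hi)
    if f_lo < 0.0 or f_hi > 0.0:
        raise CalibrationError(
            f"area ratio {target_ratio} unreachable for H={H}, W={W} within d_p in [{lo}, {hi}]")
    d_p = brentq(ratio_minus_target, lo, hi, rtol=rtol * 1e-2, xtol=1e-6 * W)
    return float(d_p)


# ---------------------------------------------------------------------------
# area-weighted sampling
# ---------------------------------------------------------------------------


def sample_surface_point(surface: Surface, rng: np.random.Generator, size: int = 1):
    """Draw anchor points uniformly *with respect to curved area*.

    Lateral candidates are uniform over the cell and accepted with
    probability ``w(x, y) / w_max`` (rejection sampling), which makes the
    accepted density proportional to the true area element ``dA = w dx dy``.

    Returns ``(points, normals)``, two ``(size, 3)`` arrays.
    """
    if not np.isfinite(surface.w_max):
        raise InvalidSurfaceError("surface has no finite area-weight bound")
    pts = np.empty((size, 3))
    nrm = np.empty((size, 3))
    got = 0
    while got < size:
        m = max(64, int((size - got) * surface.w_max * 1.2))
        x = rng.random(m) * surface.Lx
        y = rng.random(m) * surface.Ly
        z, fx, fy = surface._eval(x, y)
        w = np.sqrt(1.0 + fx * fx + fy * fy)
        keep = rng.random(m) * surface.w_max <= w
        k = min(int(keep.sum()), size - got)
        idx = np.nonzero(keep)[0][:k]
        sl = slice(got, got + k)
        pts[sl, 0] = x[idx]
        pts[sl, 1] = y[idx]
        pts[sl, 2] = z[idx]
        wi = w[idx]
        nrm[sl, 0] = -fx[idx] / wi
        nrm[sl, 1] = -fy[idx] / wi
        nrm[sl, 2] = 1.0 / wi
        got += k
    return pts, nrm
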