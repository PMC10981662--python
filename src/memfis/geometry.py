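"""Grids, differential operators and quadrature for membrane SCFT.

All lengths are in units of the natural lipid end-to-end distance
``R0 = b * sqrt(N)``.  Four geometries are supported:

``planar1d``
    One Cartesian coordinate normal to a flat membrane.
``radial1d``
    Cylindrical radius only; observables are per unit axial length.
``axisym2d``
    Cylindrical ``(r, z)`` with rotational symmetry about the z axis.
``cart3d``
    Plain periodic Cartesian box (coarse capability).

Grids are cell-centered: the radial axis point ``r = 0`` is never stored and
regularity at the axis is enforced by even parity (zero flux through the
axis), which avoids 1/r singularities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import fft as sfft
PLANAR1D = "planar1d"
RADIAL1D = "radial1d"
AXISYM2D = "axisym2d"
CART3D = "cart3d"

_KINDS = (PLANAR1D, RADIAL1D, AXISYM2D, CART3D)

#: boundary tags
PERIODIC = "periodic"
NOFLUX = "no-flux"
RESERVOIR = "bulk-reservoir"  # no-flux for propagators, fields pinned to bulk


@dataclass(frozen=True)
class Grid:
    """A discretized computational domain in R0 units.

    Parameters
    ----------
    kind
        One of ``planar1d``, ``radial1d``, ``axisym2d``, ``cart3d``.
    shape
        Points per dimension.  ``axisym2d`` is ``(nr, nz)``.
    spacings
        Cell size per dimension in R0.
    boundary
        Boundary tag per dimension.  The radial axis at ``r = 0`` is always
        reflecting and is not tagged; the tag of a radial dimension refers to
        the outer boundary.
    """

    kind: str
    shape: tuple[int, ...]
    spacings: tuple[float, ...]
    boundary: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown grid kind {self.kind!r}")
        ndim = {PLANAR1D: 1, RADIAL1D: 1, AXISYM2D: 2, CART3D: 3}[self.kind]
        if len(self.shape) != ndim or len(self.spacings) != ndim:
            raise ValueError(f"{self.kind} needs {ndim} dimension(s)")
        if any(n < 2 for n in self.shape):
            raise ValueError("need at least 2 points per dimension")
        if any(h <= 0 for h in self.spacings):
            raise ValueError("spacings must be positive")
        if not self.boundary:
            defaults = {
                PLANAR1D: (PERIODIC,),
                RADIAL1D: (NOFLUX,),
                AXISYM2D: (NOFLUX, NOFLUX),
                CART3D: (PERIODIC,) * 3,
            }
            object.__setattr__(self, "boundary", defaults[self.kind])
        if len(self.boundary) != ndim:
            raise ValueError("one boundary tag per dimension")
        if self.kind == CART3D and any(b != PERIODIC for b in self.boundary):
            raise ValueError("cart3d supports periodic boundaries only")
        if self.kind in (RADIAL1D, AXISYM2D) and self.boundary[0] == PERIODIC:
            raise ValueError("radial dimension cannot be periodic")

    # -- basic descriptors -------------------------------------------------

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def extents(self) -> tuple[float, ...]:
        return tuple(n * h for n, h in zip(self.shape, self.spacings))

    def coords(self, axis: int = 0) -> np.ndarray:
        """Cell-center coordinates along ``axis`` (radius for radial dims)."""
        n, h = self.shape[axis], self.spacings[axis]
        return (np.arange(n) + 0.5) * h

    def weights(self) -> np.ndarray:
        """Quadrature weights, shaped like a field on this grid.

        Radial measures carry the ``2*pi*r`` factor (per unit axial length
        for ``radial1d``), so ``weights().sum()`` equals the analytic domain
        volume.
        """
        if self.kind == PLANAR1D:
            return np.full(self.shape, self.spacings[0])
        if self.kind == RADIAL1D:
            r = self.coords(0)
            return 2.0 * np.pi * r * self.spacings[0]
        if self.kind == AXISYM2D:
            r = self.coords(0)
            dr, dz = self.spacings
            return np.broadcast_to(
                (2.0 * np.pi * r * dr)[:, None] * dz, self.shape
            ).copy()
        dv = float(np.prod(self.spacings))
        return np.full(self.shape, dv)

    @property
    def volume(self) -> float:
        return float(self.weights().sum())


# ---------------------------------------------------------------------------
# Laplacians
# ---------------------------------------------------------------------------


def _lap_periodic(f: np.ndarray, dx: float, axis: int) -> np.ndarray:
    """Spectral Laplacian along a periodic axis."""
    n = f.shape[axis]
    k = 2.0 * np.pi * sfft.rfftfreq(n, d=dx)
    fh = sfft.rfft(f, axis=axis)
    shape = [1] * f.ndim
    shape[axis] = k.size
    fh *= -(k**2).reshape(shape)
    return sfft.irfft(fh, n=n, axis=axis)


def _lap_noflux(f: np.ndarray, dx: float, axis: int) -> np.ndarray:
    """Second-order cell-centered Laplacian with reflecting boundaries."""
    fm = np.moveaxis(f, axis, 0)
    out = np.empty_like(fm)
    out[1:-1] = fm[2:] - 2.0 * fm[1:-1] + fm[:-2]
    out[0] = fm[1] - fm[0]
    out[-1] = fm[-2] - fm[-1]
    out /= dx * dx
    return np.moveaxis(out, 0, axis)


def _radial_edge_factors(n: int, dr: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cell-centered radial FD factors (rm, rp, rc) with zero-flux edges."""
    r = (np.arange(n) + 0.5) * dr
    rm = r - 0.5 * dr
    rp = r + 0.5 * dr
    rm[0] = 0.0  # axis: no flux through r = 0
    rp[-1] = 0.0  # outer edge: no flux
    return rm, rp, r


def _lap_radial(f: np.ndarray, dr: float) -> np.ndarray:
    """(1/r) d/dr (r d/dr) with the radial index first."""
    n = f.shape[0]
    rm, rp, r = _radial_edge_factors(n, dr)
    shape = (n,) + (1,) * (f.ndim - 1)
    rm, rp, r = rm.reshape(shape), rp.reshape(shape), r.reshape(shape)
    up = np.empty_like(f)
    dn = np.empty_like(f)
    up[:-1] = f[1:] - f[:-1]
    up[-1] = 0.0
    dn[1:] = f[1:] - f[:-1]
    dn[0] = 0.0
    return (rp * up - rm * dn) / (r * dr * dr)


def laplacian(f: np.ndarray, grid: Grid) -> np.ndarray:
    """Geometry-appropriate Laplacian of a scalar field.

    Spectral along periodic dimensions, second-order finite differences
    along bounded ones; regular at the axis by even parity.
    """
    if f.shape != grid.shape:
        raise ValueError(f"field shape {f.shape} != grid shape {grid.shape}")
    f = np.asarray(f, dtype=float)
    if grid.kind == PLANAR1D:
        if grid.boundary[0] == PERIODIC:
            return _lap_periodic(f, grid.spacings[0], 0)
        return _lap_noflux(f, grid.spacings[0], 0)
    if grid.kind == RADIAL1D:
        return _lap_radial(f, grid.spacings[0])
    if grid.kind == AXISYM2D:
        out = _lap_radial(f, grid.spacings[0])
        if grid.boundary[1] == PERIODIC:
            out += _lap_periodic(f, grid.spacings[1], 1)
        else:
            out += _lap_noflux(f, grid.spacings[1], 1)
        return out
    out = np.zeros_like(f)
    for ax in range(3):
        out += _lap_periodic(f, grid.spacings[ax], ax)
    return out


def integrate(f: np.ndarray, grid: Grid) -> float:
    """Volume integral of a field with the geometry's measure."""
    if np.shape(f) != grid.shape:
        raise ValueError(f"field shape {np.shape(f)} != grid shape {grid.shape}")
    return float(np.sum(grid.weights() * f))


# ---------------------------------------------------------------------------
# Diffusion steppers for the modified diffusion equation
# ---------------------------------------------------------------------------


class _SpectralAxis:
    """Exact exponential of the diffusion operator along one spectral axis.

    Periodic axes use the continuous spectrum; bounded (no-flux) axes use
    the exact spectrum of the cell-centered finite-difference Laplacian
    (DCT-II eigenbasis), so that planar and radial geometries share one
    discrete chain statistics and free energies are comparable across
    geometries.
    """

    def __init__(self, n: int, dx: float, axis: int, coef_dt: float, periodic: bool):
        self.axis = axis
        self.periodic = periodic
        self.n = n
        if periodic:
            k = 2.0 * np.pi * sfft.rfftfreq(n, d=dx)
            lam = -(k**2)
        else:
            # eigenvalues of the no-flux FD Laplacian in the DCT-II basis
            m = np.arange(n)
            lam = -(4.0 / dx**2) * np.sin(np.pi * m / (2 * n)) ** 2
        self.mult = np.exp(coef_dt * lam)

    def __call__(self, f: np.ndarray) -> np.ndarray:
        shape = [1] * f.ndim
        shape[self.axis] = self.mult.size
        m = self.mult.reshape(shape)
        if self.periodic:
            return sfft.irfft(sfft.rfft(f, axis=self.axis) * m, n=self.n, axis=self.axis)
        fh = sfft.dct(f, type=2, axis=self.axis)
        return sfft.idct(fh * m, type=2, axis=self.axis)


class _RadialExp:
    """Exact exponential of the radial FD diffusion operator (axis 0).

    The cylindrical Laplacian is self-adjoint under the quadrature weights
    ``r_j``, so it is symmetrized by a sqrt(r) similarity transform and
    diagonalized once; each contour step is then a dense matrix product.
    This matches the exact-exponential treatment of the planar/periodic
    axes (no time-stepping truncation error), which keeps chemical
    potentials consistent between planar and cylindrical geometries.
    """

    def __init__(self, n: int, dr: float, coef_dt: float):
        rm, rp, r = _radial_edge_factors(n, dr)
        inv = 1.0 / (r * dr * dr)
        lower = rm[1:] * inv[1:]
        upper = rp[:-1] * inv[:-1]
        diag = -(rm + rp) * inv
        off = np.sqrt(upper * lower)  # symmetrized off-diagonal
        lam, u = np.linalg.eigh(
            np.diag(diag) + np.diag(off, 1) + np.diag(off, -1))
        s = np.sqrt(r)
        core = (u * np.exp(coef_dt * lam)) @ u.T
        self._P = (core / s[:, None]) * s[None, :]

    def __call__(self, f: np.ndarray) -> np.ndarray:
        shape = f.shape
        return (self._P @ f.reshape(shape[0], -1)).reshape(shape)


class DiffusionStepper:
    """Applies ``exp(dt * coef * Laplacian)`` on a grid (symmetric splitting).

    Spectral (exact exponential) along periodic and bounded Cartesian
    dimensions and an exact dense exponential along the radial one.  For ``axisym2d``
    the operators are composed Strang-style (z half, r full, z half), so the
    overall stepper is second order in ``dt``.
    """

    def __init__(self, grid: Grid, dt: float, coef: float = 1.0 / 6.0):
        self.grid = grid
        self._ops: list = []
        cdt = coef * dt
        if grid.kind == PLANAR1D:
            self._ops = [
                _SpectralAxis(grid.shape[0], grid.spacings[0], 0, cdt,
                              grid.boundary[0] == PERIODIC)
            ]
        elif grid.kind == RADIAL1D:
            self._ops = [_RadialExp(grid.shape[0], grid.spacings[0], cdt)]
        elif grid.kind == AXISYM2D:
            zhalf = _SpectralAxis(grid.shape[1], grid.spacings[1], 1, 0.5 * cdt,
                                  grid.boundary[1] == PERIODIC)
            rfull = _RadialExp(grid.shape[0], grid.spacings[0], cdt)
            self._ops = [zhalf, rfull, zhalf]
        else:  # cart3d: single 3D spectral exponential
            self._ops = [
                _SpectralAxis(grid.shape[ax], grid.spacings[ax], ax, cdt, True)
                for ax in range(3)
            ]

    def __call__(self, f: np.ndarray) -> np.ndarray:
        for op in self._ops:
            f = op(f)
        return f


@lru_cache(maxsize=32)
def make_stepper(grid: Grid, dt: float, coef: float = 1.0 / 6.0) -> DiffusionStepper:
    """Cached diffusion stepper factory (grids are hashable and immutable)."""
    return DiffusionStepper(grid, dt, coef)
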