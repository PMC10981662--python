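"""Seed configurations for membrane topologies.

Builders return initial conjugate fields derived from a tanh-interface
tail-density ansatz: given an ansatz tail fraction ``phi_t``, the seed is
``w_A = chiN (1 - phi_t)``, ``w_B = chiN phi_t``, ``xi = 0`` — the exact
self-consistent fields of an incompressible configuration with that tail
distribution.  SCFT convergence then relaxes shape, interface width, and
lipid uptake at the given chemical potential.

Supported kinds: ``planar_bilayer``, ``sm_tube``, ``dm_tube``, ``stalk``,
``pore``, ``wlm_bridge``, ``capped_tube``.
"""

from __future__ import annotations

import numpy as np

from .geometry import AXISYM2D, Grid, PLANAR1D, RADIAL1D
from .params import ModelParams
from .scft import FieldState

__all__ = ["seed_topology", "DEFAULT_CORE_HALF_WIDTH", "DEFAULT_INTERFACE_WIDTH"]

#: half-width of the seeded hydrophobic core, R0
DEFAULT_CORE_HALF_WIDTH = 0.7
#: tanh interface width of the seed, R0
DEFAULT_INTERFACE_WIDTH = 0.25


def _smooth(d: np.ndarray, delta: float) -> np.ndarray:
    """0/1 indicator smoothed over delta: ~1 where d > 0."""
    return 0.5 * (1.0 + np.tanh(d / delta))


def _slab(u: np.ndarray, center: float, half: float, delta: float) -> np.ndarray:
    """Tail core of half-width ``half`` centered at ``center`` along u."""
    return _smooth(half - np.abs(u - center), delta)


def _rz(grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    r = grid.coords(0)[:, None]
    z = grid.coords(1)[None, :]
    return r, z


def _fields_from_tail(phi_t: np.ndarray, params: ModelParams) -> FieldState:
    phi_t = np.clip(phi_t, 0.0, 1.0)
    # pressure ansatz: inside the lipid-filled core the local lipid weight
    # exp(mu - f*w_A - (1-f)*w_B - xi) should be O(1), giving
    # xi ~ mu - (1-f)*chiN; outside, the dilute reservoir has xi ~ 0
    xi_core = params.mu - (1.0 - params.f) * params.chiN
    return FieldState(params.chiN * (1.0 - phi_t), params.chiN * phi_t,
                      xi_core * phi_t)


def _capped_segment_distance(r, z, z_lo: float, z_hi: float) -> np.ndarray:
    """Distance from (r, z) to the axis segment z in [z_lo, z_hi]."""
    dz = np.maximum(np.maximum(z_lo - z, z - z_hi), 0.0)
    return np.sqrt(r**2 + dz**2)


def seed_topology(kind: str, grid: Grid, params: ModelParams | None = None,
                  **geom) -> FieldState:
    """Build seed fields for a membrane topology on ``grid``.

    Geometry keywords (all lengths in R0):

    - ``planar_bilayer``: ``center`` (default mid-domain; the membrane
      normal is the grid coordinate for ``planar1d``, z for ``axisym2d``).
    - ``sm_tube``: ``r`` midplane radius.
    - ``dm_tube``: ``r_in`` inner midplane radius, ``gap`` head-to-head
      solvent gap; the outer midplane sits at
      ``r_in + thickness + gap`` with ``thickness = 2*half_width``.
    - ``stalk``: ``separation`` between the two bilayer midplanes,
      ``neck_radius`` of the tail bridge on the axis.
    - ``pore``: ``radius`` of the hole in a planar bilayer (axisym2d).
    - ``wlm_bridge``: ``length`` of the worm-like micellar bridge between
      two capped tubes of radius ``r``.
    - ``capped_tube``: ``r`` midplane radius, ``cap_z`` position of the cap
      along the axis (tube fills z > cap_z).

    Common keywords: ``half_width`` (tail core half-width, default 0.7),
    ``delta`` (interface width, default 0.25).
    """
    params = params or ModelParams()
    half = float(geom.pop("half_width", DEFAULT_CORE_HALF_WIDTH))
    delta = float(geom.pop("delta", DEFAULT_INTERFACE_WIDTH))
    if half <= 0 or delta <= 0:
        raise ValueError("half_width and delta must be positive")

    if kind == "planar_bilayer":
        if grid.kind == PLANAR1D:
            u = grid.coords(0)
            center = float(geom.pop("center", 0.5 * grid.extents[0]))
            phi_t = _slab(u, center, half, delta)
        elif grid.kind == AXISYM2D:
            _, z = _rz(grid)
            center = float(geom.pop("center", 0.5 * grid.extents[1]))
            phi_t = np.broadcast_to(_slab(z, center, half, delta),
                                    grid.shape).copy()
        else:
            raise ValueError("planar_bilayer needs planar1d or axisym2d")

    elif kind == "sm_tube":
        radius = float(geom.pop("r"))
        if radius <= half:
            raise ValueError("tube radius must exceed the core half-width")
        if grid.kind == RADIAL1D:
            u = grid.coords(0)
            phi_t = _slab(u, radius, half, delta)
        elif grid.kind == AXISYM2D:
            r, _ = _rz(grid)
            phi_t = np.broadcast_to(_slab(r, radius, half, delta),
                                    grid.shape).copy()
        else:
            raise ValueError("sm_tube needs radial1d or axisym2d")

    elif kind == "dm_tube":
        r_in = float(geom.pop("r_in"))
        gap = float(geom.pop("gap"))
        if gap < 0:
            raise ValueError("gap must be non-negative")
        r_out = r_in + 2.0 * half + gap
        if r_in <= half:
            raise ValueError("inner radius must exceed the core half-width")
        if grid.kind != RADIAL1D:
            raise ValueError("dm_tube needs radial1d")
        u = grid.coords(0)
        if r_out + half > grid.extents[0]:
            raise ValueError("outer tube does not fit in the domain")
        phi_t = np.maximum(_slab(u, r_in, half, delta),
                           _slab(u, r_out, half, delta))

    elif kind == "stalk":
        if grid.kind != AXISYM2D:
            raise ValueError("stalk needs axisym2d")
        sep = float(geom.pop("separation"))
        neck = float(geom.pop("neck_radius", 1.0))
        if sep <= 2.0 * half:
            raise ValueError("separation must exceed the bilayer core width")
        if neck <= 0:
            raise ValueError("neck_radius must be positive")
        r, z = _rz(grid)
        zc = float(geom.pop("center", 0.5 * grid.extents[1]))
        z1, z2 = zc - 0.5 * sep, zc + 0.5 * sep
        bilayers = np.maximum(_slab(z, z1, half, delta),
                              _slab(z, z2, half, delta))
        between = _smooth(z - z1, delta) * _smooth(z2 - z, delta)
        neck_core = _smooth(neck - r, delta) * between
        phi_t = np.maximum(np.broadcast_to(bilayers, grid.shape), neck_core)

    elif kind == "pore":
        if grid.kind != AXISYM2D:
            raise ValueError("pore needs axisym2d")
        radius = float(geom.pop("radius"))
        if radius <= 0:
            raise ValueError("pore radius must be positive")
        r, z = _rz(grid)
        zc = float(geom.pop("center", 0.5 * grid.extents[1]))
        phi_t = np.broadcast_to(_slab(z, zc, half, delta), grid.shape) \
            * _smooth(r - radius, delta)

    elif kind == "wlm_bridge":
        if grid.kind != AXISYM2D:
            raise ValueError("wlm_bridge needs axisym2d")
        length = float(geom.pop("length"))
        radius = float(geom.pop("r", 3.0))
        r_wlm = float(geom.pop("r_wlm", half))
        if length < 0:
            raise ValueError("length must be non-negative")
        r, z = _rz(grid)
        zc = float(geom.pop("center", 0.5 * grid.extents[1]))
        z1, z2 = zc - 0.5 * length, zc + 0.5 * length
        # capped tubes filling z < z1 and z > z2
        d_lo = _capped_segment_distance(r, z, -np.inf, z1)
        d_hi = _capped_segment_distance(r, z, z2, np.inf)
        shells = np.maximum(_smooth(half - np.abs(d_lo - radius), delta),
                            _smooth(half - np.abs(d_hi - radius), delta))
        # micellar cylinder bridging the caps along the axis
        between = _smooth(z - z1 + half, delta) * _smooth(z2 - z + half, delta)
        wlm = _smooth(r_wlm - r, delta) * between
        phi_t = np.maximum(shells, wlm)

    elif kind == "capped_tube":
        if grid.kind != AXISYM2D:
            raise ValueError("capped_tube needs axisym2d")
        radius = float(geom.pop("r"))
        if radius <= half:
            raise ValueError("tube radius must exceed the core half-width")
        r, z = _rz(grid)
        cap_z = float(geom.pop("cap_z", 0.5 * grid.extents[1]))
        d = _capped_segment_distance(r, z, cap_z, np.inf)
        phi_t = _smooth(half - np.abs(d - radius), delta)

    else:
        raise ValueError(f"unknown topology kind {kind!r}")

    if geom:
        raise TypeError(f"unknown geometry parameters {sorted(geom)}")
    return _fields_from_tail(phi_t, params)
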