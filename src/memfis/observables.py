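"""Membrane-level observables from converged SCFT states.

Extracts bilayer thickness and midplane position, membrane tension from the
excess grand free energy, tube radii in cylindrical geometry, the bending
rigidity from the tension-radius relation ``r = sqrt(kappa / (2 sigma))``,
and the calibration of model units (R0, k_BT) to nm and Dyn/cm.

Conventions
-----------
* Thickness is head peak-to-peak (the distance between the two head-density
  maxima flanking the hydrophobic core), matching how bilayer thickness is
  read off cryoEM density profiles; the hydrophobic-core full width at half
  maximum is exposed as a secondary diagnostic.
* Tube radii are bilayer-midplane radii (distance from the tube center to
  the middle of the bilayer), the same convention used by the fluorometry
  formulas.
* Physical tension: 1 k_BT/nm^2 = 4.11 mN/m = 4.11 Dyn/cm at 298 K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Grid, PLANAR1D, RADIAL1D
from .homogeneous import bulk_state
from .params import ModelParams
from .scft import DensityState, FieldState, grand_free_energy

__all__ = [
    "MembraneProfile",
    "UnitMap",
    "TensionPoint",
    "BilayerGeometry",
    "bilayer_geometry",
    "tension",
    "tube_radius",
    "fit_kappa",
    "calibrate_units",
    "radial_profile",
]

#: k_B T in joules at 298 K
KBT_JOULES = 4.11e-21


@dataclass
class MembraneProfile:
    """Volume-fraction profiles along the membrane normal (or radius)."""

    coord: np.ndarray
    phi_tail: np.ndarray
    phi_head: np.ndarray
    phi_solvent: np.ndarray

    def __post_init__(self):
        n = len(self.coord)
        if not all(len(a) == n for a in
                   (self.phi_tail, self.phi_head, self.phi_solvent)):
            raise ValueError("profile arrays must share one length")


@dataclass(frozen=True)
class UnitMap:
    """Calibration from model units (R0, k_BT) to nm and Dyn/cm.

    ``C = rho * R0^3 / N`` is the invariant chain concentration: the number
    of lipid chains per R0^3 volume.  The SCFT functional is computed per
    chain volume, so every extensive energy the solver reports (free
    energies, tensions, bending rigidities) carries one factor of C when
    expressed in k_BT.  Lengths are pure rescalings by ``nm_per_R0``.
    """

    nm_per_R0: float
    kBT_J: float = KBT_JOULES
    C: float = 1.0

    def __post_init__(self):
        if self.nm_per_R0 <= 0:
            raise ValueError("nm_per_R0 must be positive")
        if self.kBT_J <= 0:
            raise ValueError("kBT_J must be positive")
        if self.C <= 0:
            raise ValueError("chain concentration C must be positive")

    @property
    def dyn_cm_per_kBT_nm2(self) -> float:
        """1 k_BT/nm^2 in Dyn/cm (= mN/m): kBT_J * 1e21."""
        return self.kBT_J * 1e21

    def length_to_nm(self, length_R0: float) -> float:
        return length_R0 * self.nm_per_R0

    def length_to_R0(self, length_nm: float) -> float:
        return length_nm / self.nm_per_R0

    def energy_to_kBT(self, energy_model: float) -> float:
        """SCFT energy unit (k_BT per chain volume) -> k_BT."""
        return energy_model * self.C

    def tension_to_kBT_R02(self, sigma_model: float) -> float:
        return sigma_model * self.C

    def tension_to_phys(self, sigma_model: float) -> float:
        """SCFT tension unit -> Dyn/cm."""
        return (sigma_model * self.C * self.dyn_cm_per_kBT_nm2
                / self.nm_per_R0**2)

    def tension_to_model(self, sigma_dyn_cm: float) -> float:
        """Dyn/cm -> SCFT tension unit."""
        return (sigma_dyn_cm * self.nm_per_R0**2
                / (self.C * self.dyn_cm_per_kBT_nm2))


@dataclass
class TensionPoint:
    """Tension of one converged state: mu (k_BT), sigma (k_BT/R0^2)."""

    mu: float
    sigma: float
    sigma_phys: float | None = None


@dataclass
class BilayerGeometry:
    """Thickness and midplane of one bilayer, in R0."""

    thickness: float
    midplane: float
    core_fwhm: float


def _quadratic_peak(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-grid apex by a parabola through (i-1, i, i+1)."""
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(y[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0:  # not a maximum; fall back to the grid point
        return float(x[i]), float(y[i])
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    dx = x[1] - x[0]
    xpk = float(x[i] + shift * dx)
    ypk = float(y[i] - 0.25 * (y[i - 1] - y[i + 1]) * shift)
    return xpk, ypk


def _core_windows(phi_tail: np.ndarray, level: float = 0.5) -> list[tuple[int, int]]:
    """Index ranges of contiguous hydrophobic cores (tail above level*max)."""
    thr = level * float(phi_tail.max())
    above = phi_tail > thr
    windows = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            windows.append((i, j))
            i = j + 1
        else:
            i += 1
    return windows


def _fwhm(x: np.ndarray, y: np.ndarray, lo: int, hi: int) -> float:
    """Full width at half maximum of the peak spanning [lo, hi]."""
    half = 0.5 * float(y[lo:hi + 1].max())
    left = lo
    while left > 0 and y[left - 1] > half:
        left -= 1
    right = hi
    while right < len(y) - 1 and y[right + 1] > half:
        right += 1

    def cross(i0, i1):
        if y[i1] == y[i0]:
            return float(x[i0])
        t = (half - y[i0]) / (y[i1] - y[i0])
        return float(x[i0] + t * (x[i1] - x[i0]))

    xl = cross(left, left - 1) if left > 0 else float(x[0])
    xr = cross(right, right + 1) if right < len(y) - 1 else float(x[-1])
    return xr - xl


def bilayer_geometry(profile: MembraneProfile) -> BilayerGeometry:
    """Thickness (head peak-to-peak) and midplane of a single bilayer.

    The midplane is the center of mass of the hydrophobic (tail) core; the
    thickness is the distance between the two head-density maxima flanking
    it, located to sub-grid accuracy by quadratic interpolation.

    Raises
    ------
    ValueError
        If no tail core is present, or more than one (window the profile
        around one membrane first).
    """
    x = np.asarray(profile.coord, dtype=float)
    pt = np.asarray(profile.phi_tail, dtype=float)
    ph = np.asarray(profile.phi_head, dtype=float)
    if pt.max() < 0.2:
        raise ValueError("no hydrophobic core found in profile")
    windows = _core_windows(pt)
    if len(windows) != 1:
        raise ValueError(f"{len(windows)} tail cores found; expected one "
                         "(window the profile around a single bilayer)")
    lo, hi = windows[0]
    w = pt[lo:hi + 1]
    midplane = float(np.sum(x[lo:hi + 1] * w) / np.sum(w))

    # head peaks on each side of the midplane
    imid = int(np.searchsorted(x, midplane))
    peaks = []
    for side in (slice(0, imid), slice(imid, len(x))):
        seg = ph[side]
        if seg.size < 3:
            raise ValueError("profile does not flank the core on both sides")
        i_loc = int(np.argmax(seg)) + (side.start or 0)
        xpk, _ = _quadratic_peak(x, ph, i_loc)
        peaks.append(xpk)
    thickness = peaks[1] - peaks[0]
    if thickness <= 0:
        raise ValueError("degenerate head peaks; not a bilayer profile")
    return BilayerGeometry(thickness=thickness, midplane=midplane,
                           core_fwhm=_fwhm(x, pt, lo, hi))


def radial_profile(dens: DensityState, grid: Grid) -> MembraneProfile:
    """Density profile along the single coordinate of a 1D grid."""
    if grid.kind not in (PLANAR1D, RADIAL1D):
        raise ValueError("radial_profile needs a 1D grid")
    return MembraneProfile(grid.coords(0), dens.phi_tail, dens.phi_head,
                           dens.phi_solvent)


def tension(fields: FieldState, dens: DensityState, params: ModelParams,
            grid: Grid, unit_map: UnitMap | None = None) -> TensionPoint:
    """Membrane tension of a converged planar bilayer.

    sigma = excess grand free energy per unit membrane area relative to
    homogeneous bulk solvent at the same exchange chemical potential.  On a
    ``planar1d`` grid the state is per unit area, so sigma is the excess
    free energy itself.
    """
    if grid.kind != PLANAR1D:
        raise ValueError("tension is defined on a planar1d bilayer state")
    _, omega_b = bulk_state(params.mu, params)
    sigma = grand_free_energy(fields, dens, params, grid) - omega_b * grid.volume
    phys = unit_map.tension_to_phys(sigma) if unit_map is not None else None
    return TensionPoint(mu=params.mu, sigma=sigma, sigma_phys=phys)


def tube_radius(dens: DensityState, grid: Grid,
                expect: int | None = None) -> list[float]:
    """Midplane radii of the bilayer(s) of a cylindrical tube state.

    Applies :func:`bilayer_geometry` to each tail core found along the
    radius and returns the midplane radii sorted inside-out (one entry for
    a single-membrane tube, two for a double-membrane tube).
    """
    if grid.kind != RADIAL1D:
        raise ValueError("tube_radius needs a radial1d state")
    prof = radial_profile(dens, grid)
    windows = _core_windows(prof.phi_tail)
    if expect is not None and len(windows) != expect:
        raise ValueError(f"found {len(windows)} bilayer(s), expected {expect}")
    if not windows:
        raise ValueError("no bilayer found")
    radii = []
    x = prof.coord
    for lo, hi in windows:
        # widen the window into the flanking head regions
        pad = max(3, (hi - lo))
        a, b = max(0, lo - pad), min(len(x), hi + 1 + pad)
        sub = MembraneProfile(x[a:b], prof.phi_tail[a:b], prof.phi_head[a:b],
                              prof.phi_solvent[a:b])
        radii.append(bilayer_geometry(sub).midplane)
    return sorted(radii)


def fit_kappa(points: list[tuple[float, float]]) -> tuple[float, float]:
    """Bending rigidity from (radius, sigma) pairs via r = sqrt(kappa/2sigma).

    Least-squares fit of ``r^2 = kappa / (2 sigma)`` (linear in ``1/sigma``,
    through the origin).  Returns ``(kappa, exponent)`` where ``exponent``
    is the fitted log-log slope of r versus sigma, a diagnostic that should
    be close to -1/2 where the thin-tube limit holds.

    Requires at least 3 points spanning a factor >= 2 in sigma.
    """
    pts = [(float(r), float(s)) for r, s in points]
    if len(pts) < 3:
        raise ValueError("need at least 3 (radius, sigma) points")
    r = np.array([p[0] for p in pts])
    s = np.array([p[1] for p in pts])
    if np.any(r <= 0) or np.any(s <= 0):
        raise ValueError("radii and tensions must be positive")
    if s.max() / s.min() < 2.0:
        raise ValueError("tension values must span at least a factor of 2")
    xv = 1.0 / (2.0 * s)
    kappa = float(np.sum(xv * r**2) / np.sum(xv**2))
    exponent = float(np.polyfit(np.log(s), np.log(r), 1)[0])
    return kappa, exponent


def calibrate_units(profile: MembraneProfile,
                    target_thickness_nm: float = 5.0,
                    lipid_volume_nm3: float = 1.3) -> UnitMap:
    """Anchor model units to physical ones from a tensionless bilayer.

    The length scale comes from the bilayer thickness:
    ``nm_per_R0 = target_thickness_nm / thickness_R0`` (5 nm is the
    standard cryoEM value).  The energy scale comes from the lipid
    molecular volume: one chain occupies ``lipid_volume_nm3`` (default
    1.3 nm^3, a typical phospholipid), so the invariant chain
    concentration is ``C = nm_per_R0^3 / lipid_volume_nm3`` chains per
    R0^3, the factor converting SCFT energies to k_BT.
    """
    if target_thickness_nm <= 0:
        raise ValueError("target thickness must be positive")
    if lipid_volume_nm3 <= 0:
        raise ValueError("lipid volume must be positive")
    geom = bilayer_geometry(profile)
    nm_per_r0 = target_thickness_nm / geom.thickness
    return UnitMap(nm_per_R0=nm_per_r0,
                   C=nm_per_r0**3 / lipid_volume_nm3)
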