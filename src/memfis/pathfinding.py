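"""Minimum free-energy paths between membrane topologies: the string method.

A transformation (fission, stalk formation, pore opening) is represented as
an ordered string of configurations ("nodes") between two metastable
states.  The simplified string method alternates

1. partial free-energy descent on every interior node, and
2. redistribution of the nodes to equal arc length along the path,

until the string is stationary: the minimum free-energy path (MFEP).  The
reaction coordinate alpha is the normalized cumulative root-mean-squared
change in local density along the string, and the free-energy profile
F(alpha) exposes metastable intermediates (interior minima) and barriers
(interior maxima).

Two landscape backends share the machinery: :class:`SCFTLandscape`, whose
nodes are SCFT field configurations relaxed by damped self-consistency
iterations, and :class:`AnalyticLandscape`, an arbitrary differentiable
energy over a few scalar degrees of freedom (used to validate the string
machinery against brute-force saddle searches).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Callable, Protocol

import numpy as np

from .geometry import Grid, integrate
from .params import ModelParams
from .scft import DensityState, FieldState, densities, grand_free_energy, propagate
from .topology import seed_topology  # re-exported: seeds build string endpoints

__all__ = [
    "density_distance",
    "StringPath",
    "EnergyProfile",
    "PathLandscape",
    "AnalyticLandscape",
    "SCFTLandscape",
    "make_string",
    "reparametrize",
    "relax_string",
    "extract_barriers",
    "seed_topology",
]


def density_distance(a: DensityState, b: DensityState, grid: Grid) -> float:
    """Root-mean-squared change in local density between two states.

    ``sqrt( sum_species int (phi_a - phi_b)^2 dV / V )``; a metric on
    density configurations (symmetric, zero iff equal, triangle
    inequality from the underlying L2 norm).
    """
    if a.phi_tail.shape != grid.shape or b.phi_tail.shape != grid.shape:
        raise ValueError("density states must live on the given grid")
    acc = 0.0
    for pa, pb in ((a.phi_tail, b.phi_tail), (a.phi_head, b.phi_head),
                   (a.phi_solvent, b.phi_solvent)):
        acc += integrate((pa - pb) ** 2, grid)
    return float(np.sqrt(acc / grid.volume))


class PathLandscape(Protocol):
    """The operations the string method needs from an energy landscape."""

    def energy(self, node) -> float: ...

    def relax(self, node, steps: int): ...

    def distance(self, a, b) -> float: ...

    def interpolate(self, a, b, t: float): ...


@dataclass
class StringPath:
    """An ordered string of configurations with reaction coordinates.

    ``alphas`` are normalized cumulative arc lengths (0 at the initial
    state, 1 at the final state); endpoints are fixed during relaxation.
    """

    nodes: list
    alphas: np.ndarray = dataclass_field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        if len(self.nodes) < 2:
            raise ValueError("a string needs at least 2 nodes")
        if self.alphas.size == 0:
            self.alphas = np.linspace(0.0, 1.0, len(self.nodes))

    def __len__(self):
        return len(self.nodes)


@dataclass
class EnergyProfile:
    """Free energy along a string: F(alpha), optionally in units of kappa."""

    alpha: np.ndarray
    F: np.ndarray
    F_over_kappa: np.ndarray | None = None

    def barriers(self):
        return extract_barriers(self)


@dataclass
class AnalyticLandscape:
    """A differentiable test energy over a few scalar degrees of freedom.

    ``grad`` may be omitted, in which case central differences with step
    ``fd_eps`` are used.  ``relax`` performs plain gradient descent with
    step size ``step``.
    """

    energy_fn: Callable[[np.ndarray], float]
    grad_fn: Callable[[np.ndarray], np.ndarray] | None = None
    step: float = 0.01
    fd_eps: float = 1e-6

    def energy(self, node: np.ndarray) -> float:
        return float(self.energy_fn(np.asarray(node, dtype=float)))

    def _grad(self, x: np.ndarray) -> np.ndarray:
        if self.grad_fn is not None:
            return np.asarray(self.grad_fn(x), dtype=float)
        g = np.empty_like(x)
        for i in range(x.size):
            e = np.zeros_like(x)
            e[i] = self.fd_eps
            g[i] = (self.energy_fn(x + e) - self.energy_fn(x - e)) / (2 * self.fd_eps)
        return g

    def relax(self, node: np.ndarray, steps: int) -> np.ndarray:
        x = np.asarray(node, dtype=float).copy()
        for _ in range(steps):
            x -= self.step * self._grad(x)
        return x

    def distance(self, a, b) -> float:
        return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))

    def interpolate(self, a, b, t: float) -> np.ndarray:
        return (1.0 - t) * np.asarray(a, dtype=float) + t * np.asarray(b, dtype=float)


class SCFTLandscape:
    """SCFT free-energy landscape over field configurations at fixed mu.

    Nodes are :class:`FieldState` objects.  ``relax`` applies damped
    self-consistency (Picard) iterations — an approximate free-energy
    descent that preserves the saddle structure of the functional — and
    the metric is the RMS density distance between the nodes' density
    configurations.  Densities and energies are cached per node.
    """

    def __init__(self, params: ModelParams, grid: Grid, mixing: float = 0.05,
                 pressure_gain: float = 5.0):
        self.params = params
        self.grid = grid
        self.mixing = mixing
        self.pressure_gain = pressure_gain
        self._cache: dict[int, tuple[DensityState, float]] = {}

    def _eval(self, node: FieldState) -> tuple[DensityState, float]:
        key = id(node)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        props = propagate(node, self.grid, self.params)
        dens = densities(props, node, self.params, self.grid)
        fe = grand_free_energy(node, dens, self.params, self.grid)
        if len(self._cache) > 256:
            self._cache.clear()
        self._cache[key] = (dens, fe)
        return dens, fe

    def densities_of(self, node: FieldState) -> DensityState:
        return self._eval(node)[0]

    def energy(self, node: FieldState) -> float:
        return self._eval(node)[1]

    def relax(self, node: FieldState, steps: int) -> FieldState:
        chiN = self.params.chiN
        fs = node.copy()
        for _ in range(steps):
            props = propagate(fs, self.grid, self.params)
            dens = densities(props, fs, self.params, self.grid)
            fs = FieldState(
                fs.w_A + self.mixing * (chiN * dens.phi_B_total - fs.w_A),
                fs.w_B + self.mixing * (chiN * dens.phi_tail - fs.w_B),
                fs.xi + self.mixing * self.pressure_gain
                * np.log(np.clip(dens.total, 0.05, 20.0)),
            )
        return fs

    def distance(self, a: FieldState, b: FieldState) -> float:
        return density_distance(self.densities_of(a), self.densities_of(b),
                                self.grid)

    def interpolate(self, a: FieldState, b: FieldState, t: float) -> FieldState:
        return FieldState((1 - t) * a.w_A + t * b.w_A,
                          (1 - t) * a.w_B + t * b.w_B,
                          (1 - t) * a.xi + t * b.xi)


def make_string(start, end, n_nodes: int, model: PathLandscape) -> StringPath:
    """Linearly interpolated initial string between two endpoint states."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    ts = np.linspace(0.0, 1.0, n_nodes)
    nodes = [start] + [model.interpolate(start, end, float(t))
                       for t in ts[1:-1]] + [end]
    return StringPath(nodes=nodes)


def _arc_lengths(path: StringPath, model: PathLandscape) -> np.ndarray:
    d = [model.distance(path.nodes[i], path.nodes[i + 1])
         for i in range(len(path) - 1)]
    return np.concatenate([[0.0], np.cumsum(d)])


def _redistribute_once(path: StringPath, model: PathLandscape) -> StringPath:
    s = _arc_lengths(path, model)
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate (zero-length) path")
    targets = np.linspace(0.0, total, len(path))
    new_nodes = [path.nodes[0]]
    j = 0
    for m in range(1, len(path) - 1):
        t = targets[m]
        while j < len(s) - 2 and s[j + 1] < t:
            j += 1
        seg = s[j + 1] - s[j]
        frac = 0.0 if seg <= 0 else (t - s[j]) / seg
        new_nodes.append(model.interpolate(path.nodes[j], path.nodes[j + 1],
                                           float(frac)))
    new_nodes.append(path.nodes[-1])
    return StringPath(nodes=new_nodes,
                      alphas=np.linspace(0.0, 1.0, len(path)))


def reparametrize(path: StringPath, model: PathLandscape,
                  cv_tol: float = 1e-3, max_passes: int = 8) -> StringPath:
    """Redistribute nodes to equal arc length by piecewise-linear interpolation.

    Endpoints are untouched; interior nodes are placed at uniform fractions
    of the cumulative arc length measured with the landscape metric.  On a
    curved path one linear redistribution leaves a residual spacing spread,
    so passes repeat until the coefficient of variation of adjacent
    distances drops below ``cv_tol``.
    """
    if len(path) < 3:
        return path
    for _ in range(max_passes):
        path = _redistribute_once(path, model)
        d = np.diff(_arc_lengths(path, model))
        if np.std(d) <= cv_tol * np.mean(d):
            break
    return path


def relax_string(
    path: StringPath,
    model: PathLandscape,
    n_outer: int = 100,
    inner_steps: int = 10,
    tol: float = 1e-6,
    kappa: float | None = None,
) -> tuple[StringPath, EnergyProfile]:
    """Evolve a string to the minimum free-energy path (simplified string).

    Each outer sweep applies ``inner_steps`` of landscape descent to every
    interior node and then reparametrizes to equal arc length; endpoints
    stay fixed.  Terminates after ``n_outer`` sweeps or when the maximum
    node displacement per sweep (in the landscape metric) drops below
    ``tol``.  The profile's alpha is the normalized cumulative RMS density
    change; with ``kappa`` given, ``F_over_kappa`` holds the profile
    relative to its initial value in units of kappa.
    """
    path = reparametrize(path, model)
    for sweep in range(n_outer):
        moved = 0.0
        new_nodes = [path.nodes[0]]
        for m in range(1, len(path) - 1):
            node = model.relax(path.nodes[m], inner_steps)
            moved = max(moved, model.distance(path.nodes[m], node))
            new_nodes.append(node)
        new_nodes.append(path.nodes[-1])
        path = reparametrize(StringPath(nodes=new_nodes, alphas=path.alphas),
                             model)
        if not np.isfinite(moved):
            raise FloatingPointError(f"node blow-up in sweep {sweep}")
        if moved < tol:
            break
    s = _arc_lengths(path, model)
    alpha = s / s[-1] if s[-1] > 0 else np.linspace(0, 1, len(path))
    F = np.array([model.energy(n) for n in path.nodes])
    over_kappa = (F - F[0]) / kappa if kappa else None
    return path, EnergyProfile(alpha=alpha, F=F, F_over_kappa=over_kappa)


def extract_barriers(profile: EnergyProfile) -> list[tuple[float, float]]:
    """Barriers of a free-energy profile: (alpha_peak, dF_forward) pairs.

    Each interior local maximum is paired with the lowest point since the
    preceding interior minimum (or the start); ``dF`` is the climb from
    that minimum to the peak, always >= 0.  A monotone profile has no
    barriers.  The list is ordered along alpha; the rate-limiting barrier
    is the one with the largest dF.
    """
    F = np.asarray(profile.F, dtype=float)
    a = np.asarray(profile.alpha, dtype=float)
    if F.size < 3:
        return []
    out = []
    base = F[0]
    for i in range(1, F.size - 1):
        if F[i] > F[i - 1] and F[i] >= F[i + 1]:  # interior maximum
            out.append((float(a[i]), float(F[i] - base)))
        elif F[i] < F[i - 1] and F[i] <= F[i + 1]:  # interior minimum
            base = F[i]
    return out
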