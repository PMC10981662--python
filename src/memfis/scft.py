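"""Self-consistent field theory of the lipid/solvent Gaussian-chain mixture.

The lipid is an AB diblock (tail fraction ``f``), the solvent a short B
homopolymer; both diffuse in conjugate fields via the modified diffusion
equation

    dq/ds = (1/6) Lap q - W(r) q ,      q(r, 0) = 1,

with lengths in R0 and the block-appropriate total field
``W = w + xi`` (``w_A + xi`` on the tail contour, ``w_B + xi`` on head and
solvent).  Densities follow from contour integrals of ``q * qdag`` weighted
by the species activities (solvent activity 1, lipid ``exp(mu)``), and the
fields are iterated to self-consistency

    w_A = chiN * (phi_head + phi_solvent),   w_B = chiN * phi_tail,
    phi_tail + phi_head + phi_solvent = 1     (pressure field xi),

by Picard iteration with Anderson acceleration.  Incompressibility is
enforced exactly through ``xi`` inside the same fixed-point loop, not by a
penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import simpson

from .geometry import Grid, RESERVOIR, integrate, make_stepper
from .homogeneous import bulk_field_values, bulk_state
from .params import ModelParams

__all__ = [
    "FieldState",
    "DensityState",
    "Propagators",
    "MaxIterationsExceeded",
    "DivergenceError",
    "propagate",
    "densities",
    "grand_free_energy",
    "excess_free_energy",
    "scft_converge",
    "uniform_fields",
]


@dataclass
class FieldState:
    """Conjugate potential fields (k_BT per chain contour) on a grid.

    ``w_A``/``w_B`` are the interaction parts conjugate to tail and
    head+solvent densities; ``xi`` is the pressure-like field enforcing
    incompressibility.  Propagation uses the totals ``w + xi``, so the
    state is gauge-invariant under ``w_A += c, w_B += c, xi -= c``.
    """

    w_A: np.ndarray
    w_B: np.ndarray
    xi: np.ndarray

    def __post_init__(self):
        self.w_A = np.asarray(self.w_A, dtype=float)
        self.w_B = np.asarray(self.w_B, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        if not (self.w_A.shape == self.w_B.shape == self.xi.shape):
            raise ValueError("field components must share one shape")

    @property
    def total_tail(self) -> np.ndarray:
        return self.w_A + self.xi

    @property
    def total_head(self) -> np.ndarray:
        return self.w_B + self.xi

    def is_finite(self) -> bool:
        return bool(np.isfinite(self.w_A).all() and np.isfinite(self.w_B).all()
                    and np.isfinite(self.xi).all())

    def copy(self) -> "FieldState":
        return FieldState(self.w_A.copy(), self.w_B.copy(), self.xi.copy())


@dataclass
class DensityState:
    """Local volume fractions of tail, head and solvent segments."""

    phi_tail: np.ndarray
    phi_head: np.ndarray
    phi_solvent: np.ndarray

    @property
    def phi_lipid(self) -> np.ndarray:
        return self.phi_tail + self.phi_head

    @property
    def phi_B_total(self) -> np.ndarray:
        return self.phi_head + self.phi_solvent

    @property
    def total(self) -> np.ndarray:
        return self.phi_tail + self.phi_head + self.phi_solvent

    def copy(self) -> "DensityState":
        return DensityState(self.phi_tail.copy(), self.phi_head.copy(),
                            self.phi_solvent.copy())


@dataclass
class Propagators:
    """Chain partition-function propagators over the contour variable s.

    ``q[i]`` and ``qdag[i]`` sample the forward/backward lipid propagator at
    ``s = i*ds`` (backward measured from the head end), ``q_s[i]`` the
    solvent propagator at ``s = i*ds_solvent``.
    """

    q: np.ndarray        # (ns_lipid+1, *grid.shape)
    qdag: np.ndarray     # (ns_lipid+1, *grid.shape)
    q_s: np.ndarray      # (ns_solvent+1, *grid.shape)
    params: ModelParams


class MaxIterationsExceeded(RuntimeError):
    """Raised when the residual stays above tol; carries the last state."""

    def __init__(self, residual: float, history: list[float],
                 fields=None, dens=None, mu=None, pin_force=None):
        super().__init__(f"SCFT did not converge; last residual {residual:.3e}")
        self.residual = residual
        self.history = history
        self.fields = fields
        self.densities = dens
        self.mu = mu
        self.pin_force = pin_force


class DivergenceError(RuntimeError):
    def __init__(self, residual: float, history: list[float]):
        super().__init__(f"SCFT iteration diverging; residual {residual:.3e}")
        self.residual = residual
        self.history = history


# ---------------------------------------------------------------------------
# propagation and densities
# ---------------------------------------------------------------------------


def _march(q0: np.ndarray, steppers_fields: list[tuple[Callable, np.ndarray, int]],
           ds_list: list[float]) -> np.ndarray:
    """Second-order contour march: half-field, diffusion, half-field."""
    out = [q0]
    q = q0
    for (step, w, nsteps), ds in zip(steppers_fields, ds_list):
        e = np.exp(-0.5 * ds * w)
        for _ in range(nsteps):
            q = e * step(e * q)
            out.append(q)
    return np.stack(out)


def propagate(fields: FieldState, grid: Grid, params: ModelParams) -> Propagators:
    """Solve the modified diffusion equation for lipid and solvent.

    Symmetric operator splitting per contour step (second order in ds);
    the initial condition is q = 1 on the whole grid.
    """
    if fields.w_A.shape != grid.shape:
        raise ValueError(f"fields shaped {fields.w_A.shape}, grid {grid.shape}")
    if not fields.is_finite():
        raise ValueError("non-finite input fields")
    w_t, w_h = fields.total_tail, fields.total_head
    step = make_stepper(grid, params.ds)
    one = np.ones(grid.shape)

    q = _march(one, [(step, w_t, params.ns_tail), (step, w_h, params.ns_head)],
               [params.ds, params.ds])
    qdag = _march(one, [(step, w_h, params.ns_head), (step, w_t, params.ns_tail)],
                  [params.ds, params.ds])
    ds_s = params.ds_solvent
    step_s = step if abs(ds_s - params.ds) < 1e-14 else make_stepper(grid, ds_s)
    q_s = _march(one, [(step_s, w_h, params.ns_solvent)], [ds_s])

    for arr, name in ((q, "q"), (qdag, "qdag"), (q_s, "q_s")):
        if not np.isfinite(arr).all():
            raise FloatingPointError(
                f"non-finite values in propagator {name}: contour step blow-up")
    return Propagators(q=q, qdag=qdag, q_s=q_s, params=params)


def densities(props: Propagators, fields: FieldState, params: ModelParams,
              grid: Grid, lipid_activity: float | None = None) -> DensityState:
    """Assemble species volume fractions from the propagators.

    phi_tail = z_l * int_0^f q qdag ds, phi_head = z_l * int_f^1,
    phi_solvent = (1/beta) * int_0^beta q_s(s) q_s(beta - s) ds with solvent
    activity 1 (the fixed normalization convention of this package).  The
    lipid activity is ``exp(mu)`` unless overridden (canonical-lipid mode).
    """
    nt, nl = params.ns_tail, params.ns_lipid
    s = np.arange(nl + 1) * params.ds
    integrand = props.q * props.qdag[::-1]
    z_l = np.exp(params.mu) if lipid_activity is None else lipid_activity
    phi_tail = z_l * simpson(integrand[: nt + 1], x=s[: nt + 1], axis=0)
    phi_head = z_l * simpson(integrand[nt:], x=s[nt:], axis=0)

    ns_s = params.ns_solvent
    s_s = np.arange(ns_s + 1) * params.ds_solvent
    integrand_s = props.q_s * props.q_s[::-1]
    phi_solvent = simpson(integrand_s, x=s_s, axis=0) / params.solvent_ratio

    # tolerate tiny spectral undershoots on sharp seed profiles; anything
    # larger indicates genuine propagator corruption
    for arr, name in ((phi_tail, "tail"), (phi_head, "head"),
                      (phi_solvent, "solvent")):
        if arr.min() < -0.1:
            raise ValueError(f"negative {name} density ({arr.min():.3e}): "
                             "corrupted propagators")
    return DensityState(phi_tail, phi_head, phi_solvent)


# ---------------------------------------------------------------------------
# free energy
# ---------------------------------------------------------------------------


def grand_free_energy(fields: FieldState, dens: DensityState,
                      params: ModelParams, grid: Grid) -> float:
    """Semi-grand canonical free energy in k_BT (extensive over the grid).

    Evaluated in a manifestly gauge-invariant form: only the total fields
    ``W = w + xi`` enter, with the pressure field reconstructed as
    ``xi_eff = (W_A - chiN*phi_B + W_B - chiN*phi_A)/2`` (equal to the
    stored xi at self-consistency).  The single-chain partition terms are
    expressed through the densities, ``z_l V Q_l = int phi_lipid`` and
    ``(1/beta) V Q_s = int phi_solvent / beta``.
    """
    chiN = params.chiN
    phi_a = dens.phi_tail
    phi_b = dens.phi_B_total
    w_a_tot, w_b_tot = fields.total_tail, fields.total_head
    xi_eff = 0.5 * ((w_a_tot - chiN * phi_b) + (w_b_tot - chiN * phi_a))
    integrand = (
        chiN * phi_a * phi_b
        - w_a_tot * phi_a
        - w_b_tot * phi_b
        + xi_eff * (phi_a + phi_b - 1.0)
        - dens.phi_lipid
        - dens.phi_solvent / params.solvent_ratio
    )
    val = integrate(integrand, grid)
    if not np.isfinite(val):
        raise FloatingPointError("non-finite free energy")
    return val


def excess_free_energy(fields: FieldState, dens: DensityState,
                       params: ModelParams, grid: Grid) -> float:
    """Free energy relative to homogeneous bulk solvent at the same mu."""
    _, omega_bulk = bulk_state(params.mu, params)
    return grand_free_energy(fields, dens, params, grid) - omega_bulk * grid.volume


# ---------------------------------------------------------------------------
# self-consistent iteration
# ---------------------------------------------------------------------------


def uniform_fields(grid: Grid, params: ModelParams) -> FieldState:
    """Self-consistent fields of the homogeneous reservoir on a grid."""
    w_a, w_b, xi = bulk_field_values(params.mu, params)
    shape = grid.shape
    return FieldState(np.full(shape, w_a), np.full(shape, w_b),
                      np.full(shape, xi))


@dataclass
class SCFTResult:
    """Converged SCFT state; iterable as (fields, densities, free_energy,
    residual_history) for tuple unpacking.

    ``mu`` is the exchange chemical potential of the state: the input mu
    for reservoir-coupled (semi-grand canonical) runs, or the measured
    ``ln(lipid activity)`` for canonical-lipid runs.
    """

    fields: FieldState
    densities: DensityState
    free_energy: float
    history: list[float]
    mu: float
    pin_force: float | np.ndarray = 0.0

    def __iter__(self):
        return iter((self.fields, self.densities, self.free_energy,
                     self.history))


class _Anderson:
    """Type-II Anderson acceleration of a fixed-point map x -> g(x)."""

    def __init__(self, depth: int = 10, damping: float = 1.0):
        self.depth = depth
        self.damping = damping
        self._xs: list[np.ndarray] = []
        self._fs: list[np.ndarray] = []

    def reset(self):
        self._xs.clear()
        self._fs.clear()

    def step(self, x: np.ndarray, gx: np.ndarray) -> np.ndarray:
        f = gx - x
        self._xs.append(x)
        self._fs.append(f)
        if len(self._xs) > self.depth + 1:
            self._xs.pop(0)
            self._fs.pop(0)
        m = len(self._xs) - 1
        if m == 0:
            return x + self.damping * f
        df = np.stack([self._fs[i + 1] - self._fs[i] for i in range(m)], axis=1)
        dx = np.stack([self._xs[i + 1] - self._xs[i] for i in range(m)], axis=1)
        gamma, *_ = np.linalg.lstsq(df, f, rcond=1e-10)
        x_new = x + self.damping * f - (dx + self.damping * df) @ gamma
        if not np.isfinite(x_new).all():
            self.reset()
            return x + self.damping * f
        return x_new


def _reservoir_mask(grid: Grid, margin: float) -> np.ndarray | None:
    """Mask of cells within ``margin`` of a bulk-reservoir boundary."""
    if RESERVOIR not in grid.boundary:
        return None
    mask = np.zeros(grid.shape, dtype=bool)
    for ax, tag in enumerate(grid.boundary):
        if tag != RESERVOIR:
            continue
        x = grid.coords(ax)
        outer = x > (grid.extents[ax] - margin)
        sl: list = [None] * len(grid.shape)
        shape = [1] * len(grid.shape)
        shape[ax] = x.size
        mask |= outer.reshape(shape)
    return mask


def scft_converge(
    init: FieldState,
    params: ModelParams,
    grid: Grid,
    tol: float = 1e-6,
    max_iter: int = 5000,
    mixing: float = 0.05,
    warmup: int = 50,
    anderson_depth: int = 10,
    anderson_damping: float = 1.0,
    pressure_gain: float = 5.0,
    reservoir_margin: float = 1.0,
    lipid_mass: float | None = None,
    radius_pin: float | None = None,
    pin_weight: np.ndarray | None = None,
    pin_target: float | None = None,
    pins: list[tuple[np.ndarray, float]] | None = None,
    pin_gain: float = 1.0,
    pin_eta0: np.ndarray | float | None = None,
    callback: Callable[[int, float, float], None] | None = None,
) -> SCFTResult:
    """Iterate the SCFT equations to a (meta)stable configuration.

    Simple mixing (``mixing``) for ``warmup`` iterations, then Anderson
    acceleration with history ``anderson_depth``.  The max-norm residual
    combines the two field equations and the incompressibility violation
    (scaled by ``pressure_gain``); iteration stops when it drops below
    ``tol``.  Grid boundaries tagged ``bulk-reservoir`` have their fields
    pinned to the homogeneous-reservoir values within ``reservoir_margin``
    R0 of the boundary after every update.

    With ``lipid_mass`` set, the run is canonical in the lipid: the lipid
    activity is renormalized every iteration so the integrated lipid
    fraction equals ``lipid_mass`` (in R0^3, or per unit area / axial
    length on lower-dimensional grids), and the effective exchange
    chemical potential ``ln z`` is reported on the result.  This removes
    the membrane-mass runaway mode of the reservoir-coupled iteration,
    which loses stability for strongly stretched membranes; the converged
    fields are identical to a reservoir-coupled solution at ``mu = ln z``.

    With ``radius_pin`` set (radial grids), a scalar Lagrange multiplier
    ``eta`` couples a linear radial potential to the tail density so the
    tail center of mass is held at the given radius.  This freezes the
    slowly spiraling radius mode of cylindrical membranes; the multiplier
    is reported as ``result.pin_force``, and the unconstrained equilibrium
    radius is where it crosses zero.

    Returns an :class:`SCFTResult`, unpackable as
    ``(fields, densities, free_energy, residual_history)``.

    Raises
    ------
    MaxIterationsExceeded
        If the residual is still above ``tol`` after ``max_iter`` sweeps.
    DivergenceError
        If the residual grows by more than 1e3 over its running best for a
        sustained window.
    """
    if not init.is_finite():
        raise ValueError("non-finite initial fields")
    chiN = params.chiN
    shape = grid.shape
    npts = int(np.prod(shape))
    mask = _reservoir_mask(grid, reservoir_margin)
    if mask is not None:
        wab, wbb, xib = bulk_field_values(params.mu, params)

    weights = grid.weights()
    mu_eff = params.mu
    if radius_pin is not None:
        if grid.kind != "radial1d":
            raise ValueError("radius_pin requires a radial1d grid")
        pin_weight = np.broadcast_to(grid.coords(0), grid.shape)
        pin_target = float(radius_pin)
    if pin_weight is not None:
        if pin_target is None:
            raise ValueError("pin_target required with pin_weight")
        pins = (pins or []) + [(pin_weight, pin_target)]
    pins = pins or []
    n_pin = len(pins)
    pin_us = np.stack([np.asarray(w, dtype=float) - t for w, t in pins]) \
        if n_pin else None

    def pack(fs: FieldState, eta: np.ndarray | None = None) -> np.ndarray:
        tail = np.zeros(n_pin) if eta is None else np.asarray(eta, dtype=float)
        return np.concatenate([fs.w_A.ravel(), fs.w_B.ravel(), fs.xi.ravel(),
                               tail])

    def unpack(x: np.ndarray) -> tuple[FieldState, np.ndarray]:
        fs = FieldState(x[:npts].reshape(shape),
                        x[npts:2 * npts].reshape(shape),
                        x[2 * npts:3 * npts].reshape(shape))
        return fs, x[3 * npts:]

    def pin(fs: FieldState) -> FieldState:
        if mask is not None:
            fs.w_A[mask] = wab
            fs.w_B[mask] = wbb
            fs.xi[mask] = xib
        return fs

    def evaluate(fs: FieldState, eta: np.ndarray):
        nonlocal mu_eff
        if n_pin == 0:
            eff = fs
        else:
            eff = FieldState(
                fs.w_A + np.tensordot(eta, pin_us, axes=1), fs.w_B, fs.xi)
        props = propagate(eff, grid, params)
        if lipid_mass is None:
            dens = densities(props, eff, params, grid)
        else:
            raw = densities(props, eff, params, grid, lipid_activity=1.0)
            got = float(np.sum(weights * raw.phi_lipid))
            if got <= 0:
                raise FloatingPointError("vanishing lipid weight")
            z = lipid_mass / got
            dens = DensityState(z * raw.phi_tail, z * raw.phi_head,
                                raw.phi_solvent)
            mu_eff = float(np.log(z))
        # logarithmic pressure update: densities respond exponentially to
        # xi, so ln(phi_total) is the linearly responding error signal
        target = FieldState(
            chiN * dens.phi_B_total,
            chiN * dens.phi_tail,
            fs.xi + pressure_gain * np.log(np.clip(dens.total, 0.05, 20.0)),
        )
        eta_target = eta
        if n_pin:
            mass = float(np.sum(weights * dens.phi_tail))
            com = np.tensordot(pin_us, weights * dens.phi_tail,
                               axes=pin_us.ndim - 1) / mass
            eta_target = eta + pin_gain * com
        return dens, target, eta_target

    fields = pin(init.copy())
    eta_init = None
    if pin_eta0 is not None and n_pin:
        eta_init = np.atleast_1d(np.asarray(pin_eta0, dtype=float))
        if eta_init.size != n_pin:
            raise ValueError("pin_eta0 size must match the number of pins")
    x = pack(fields, eta_init)
    aa = _Anderson(anderson_depth, anderson_damping)
    history: list[float] = []
    best = np.inf
    best_x = best_gx = None
    bad_streak = 0
    good_streak = 0

    for it in range(max_iter + 1):
        fields, eta = unpack(x)
        dens, target, eta_t = evaluate(fields, eta)
        gx = pack(target, eta_t)
        res = float(np.max(np.abs(gx - x)))
        history.append(res)
        if callback is not None:
            fe = grand_free_energy(fields, dens, params, grid)
            callback(it, res, fe)
        if res < best:
            best, best_x, best_gx = res, x, gx
            bad_streak = 0
            good_streak += 1
            # recover acceleration strength while progress is steady
            if good_streak >= 30 and aa.damping < anderson_damping:
                aa.damping = min(anderson_damping, 1.3 * aa.damping)
                good_streak = 0
        else:
            bad_streak += 1
            good_streak = 0
        if res < tol:
            fe = grand_free_energy(fields, dens, params, grid)
            force = (float(eta[0]) if eta.size == 1
                     else (eta.copy() if eta.size else 0.0))
            return SCFTResult(fields, dens, fe, history, mu_eff, force)
        if not np.isfinite(res) or (res > 1e4 * max(best, tol) and bad_streak > 100):
            raise DivergenceError(res, history)
        if it == max_iter:
            break
        if it < warmup:
            x = x + mixing * (gx - x)
        elif res > 10.0 * best and bad_streak > 2:
            # acceleration overshot: restart from the best state seen and
            # damp subsequent accelerated steps (self-stabilizing on stiff
            # 2D problems where full Anderson steps thrash)
            aa.reset()
            aa.damping = max(0.15, 0.7 * aa.damping)
            bad_streak = 0
            x = best_x + mixing * (best_gx - best_x)
        else:
            x = aa.step(x, gx)
            if not np.isfinite(x).all():
                aa.reset()
                x = x + mixing * (gx - x)
        fs2, eta2 = unpack(x)
        x = pack(pin(fs2), eta2)

    raise MaxIterationsExceeded(history[-1], history, fields=fields,
                                dens=dens, mu=mu_eff,
                                pin_force=eta if n_pin else None)
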