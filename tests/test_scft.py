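"""SCFT engine: propagators, densities, free energy, convergence."""

import numpy as np
import pytest

from memfis.geometry import Grid
from memfis.homogeneous import (
    fh_free_energy_density,
    grand_potential_density,
    solvent_branch_phi,
)
from memfis.params import ModelParams
from memfis.scft import (
    FieldState,
    densities,
    grand_free_energy,
    propagate,
    scft_converge,
    uniform_fields,
)
from memfis.topology import seed_topology


def _uniform(grid, w_a, w_b, xi=0.0):
    return FieldState(np.full(grid.shape, w_a), np.full(grid.shape, w_b),
                      np.full(grid.shape, xi))


# ---------------------------------------------------------------------------
# propagator oracles
# ---------------------------------------------------------------------------


def test_zero_field_propagator_identity(params):
    grid = Grid("planar1d", (64,), (0.1,), ("periodic",))
    props = propagate(_uniform(grid, 0.0, 0.0), grid, params)
    for q in (props.q, props.qdag, props.q_s):
        assert np.abs(q - 1.0).max() < 1e-10


def test_constant_field_exponential(params):
    grid = Grid("planar1d", (64,), (0.1,), ("periodic",))
    c = 0.7
    props = propagate(_uniform(grid, c, c), grid, params)
    s = np.arange(params.ns_lipid + 1) * params.ds
    expect = np.exp(-c * s)[:, None]
    assert np.abs(props.q - expect).max() < 1e-10
    s_s = np.arange(params.ns_solvent + 1) * params.ds_solvent
    assert np.abs(props.q_s - np.exp(-c * s_s)[:, None]).max() < 1e-10


def test_contour_stepping_second_order():
    """Richardson refinement: halving ds reduces the error ~4x."""
    grid = Grid("planar1d", (64,), (0.1,), ("periodic",))
    x = grid.coords(0)
    w = 0.8 * np.cos(2 * np.pi * x / grid.extents[0])
    sols = {}
    for ds in (0.02, 0.01, 0.005):
        p = ModelParams(ds=ds)
        fields = FieldState(w, w, np.zeros_like(w))
        sols[ds] = propagate(fields, grid, p).q[-1]
    e1 = np.abs(sols[0.02] - sols[0.01]).max()
    e2 = np.abs(sols[0.01] - sols[0.005]).max()
    order = np.log2(e1 / e2)
    assert 1.7 < order < 2.3


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------


def _phi_oracle_bisect(mu, params):
    """Independent scalar oracle: bisection on the uniform-mixture equation.

    d/dphi of the mixture free energy equals mu; written out directly here
    so the oracle shares no code with the implementation.
    """
    beta, f, chiN = params.solvent_ratio, params.f, params.chiN

    def g(phi):
        return (np.log(phi) - np.log(1 - phi) / beta
                + chiN * f * (1 - 2 * f * phi) - mu)

    lo, hi = 1e-12, 0.02
    assert g(lo) < 0 < g(hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def test_uniform_densities_match_scalar_oracle(params):
    mu = 15.0
    p = params.with_mu(mu)
    grid = Grid("planar1d", (64,), (0.1,), ("periodic",))
    fields = uniform_fields(grid, p)
    dens = densities(propagate(fields, grid, p), fields, p, grid)
    phi_star = _phi_oracle_bisect(mu, params)
    assert dens.phi_lipid.mean() == pytest.approx(phi_star, rel=1e-8)
    assert np.abs(dens.total - 1.0).max() < 1e-10
    assert dens.phi_tail.mean() == pytest.approx(params.f * phi_star, rel=1e-8)


def test_low_mu_limit_pure_solvent(params):
    p = params.with_mu(-40.0)
    grid = Grid("planar1d", (32,), (0.1,), ("periodic",))
    fields = uniform_fields(grid, p)
    dens = densities(propagate(fields, grid, p), fields, p, grid)
    assert dens.phi_solvent.mean() == pytest.approx(1.0, abs=1e-10)
    assert dens.phi_lipid.max() < 1e-12


def test_mirror_symmetric_fields_give_mirror_symmetric_densities(params, rng):
    grid = Grid("planar1d", (64,), (0.1,), ("no-flux",))
    half = rng.standard_normal(32)
    w = np.concatenate([half, half[::-1]])
    fields = FieldState(w, 0.5 * w[::-1] + 0.5 * w, np.zeros(64))
    p = params.with_mu(5.0)
    dens = densities(propagate(fields, grid, p), fields, p, grid)
    for phi in (dens.phi_tail, dens.phi_head, dens.phi_solvent):
        assert np.abs(phi - phi[::-1]).max() < 1e-10


# ---------------------------------------------------------------------------
# free energy
# ---------------------------------------------------------------------------


def test_homogeneous_free_energy_matches_flory_huggins(params):
    mu = 15.0
    p = params.with_mu(mu)
    grid = Grid("planar1d", (64,), (0.1,), ("periodic",))
    fields = uniform_fields(grid, p)
    dens = densities(propagate(fields, grid, p), fields, p, grid)
    omega = grand_free_energy(fields, dens, p, grid) / grid.volume
    phi = solvent_branch_phi(mu, params)
    expect = grand_potential_density(phi, params, mu)
    assert omega == pytest.approx(expect, rel=1e-8)
    # and the Helmholtz part separately
    f_fh = fh_free_energy_density(phi, params)
    assert omega + mu * phi == pytest.approx(f_fh, rel=1e-8)


def test_free_energy_gauge_invariance(converged_bilayer, params,
                                      planar_grid_coarse):
    res = converged_bilayer
    p = params.with_mu(res.mu)
    base = grand_free_energy(res.fields, res.densities, p, planar_grid_coarse)
    c = 1.7
    shifted = FieldState(res.fields.w_A + c, res.fields.w_B + c,
                         res.fields.xi - c)
    moved = grand_free_energy(shifted, res.densities, p, planar_grid_coarse)
    assert moved == pytest.approx(base, rel=1e-10)


# ---------------------------------------------------------------------------
# convergence
# ---------------------------------------------------------------------------


def test_converged_state_is_fixed_point(converged_bilayer, params,
                                        planar_grid_coarse):
    res = converged_bilayer
    again = scft_converge(res.fields, params, planar_grid_coarse,
                          lipid_mass=1.35, tol=1e-7, max_iter=50)
    assert len(again.history) <= 3
    assert np.abs(again.fields.w_A - res.fields.w_A).max() < 1e-5


def test_planar_bilayer_structure(converged_bilayer, planar_grid_coarse):
    dens = converged_bilayer.densities
    assert dens.phi_tail.max() > 0.9  # tail-rich hydrophobic core
    assert np.abs(dens.total - 1.0).max() < 1e-5  # incompressibility
    # head-rich layers flank the core
    core = int(np.argmax(dens.phi_tail))
    assert dens.phi_head[:core].max() > 2 * dens.phi_head[core]


def test_homogeneous_initialization_stays_homogeneous(params):
    p = params.with_mu(8.0)  # far below the self-assembly regime
    grid = Grid("planar1d", (64,), (0.1,), ("no-flux",))
    res = scft_converge(uniform_fields(grid, p), p, grid, tol=1e-8,
                        max_iter=200)
    phi_star = _phi_oracle_bisect(8.0, params)
    assert res.densities.phi_lipid.mean() == pytest.approx(phi_star, rel=1e-6)
    assert np.ptp(res.densities.phi_lipid) < 1e-9


def test_invalid_inputs_raise(params):
    grid = Grid("planar1d", (32,), (0.1,), ("periodic",))
    bad = _uniform(grid, np.nan, 0.0)
    with pytest.raises(ValueError):
        propagate(bad, grid, params)
    with pytest.raises(ValueError):
        ModelParams(f=1.2)
    with pytest.raises(ValueError):
        ModelParams(ds=0.013)  # junction misses the contour grid
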