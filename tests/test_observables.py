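"""Membrane observables: thickness, tension, tube radii, rigidity, units."""

import numpy as np
import pytest

from memfis.geometry import Grid
from memfis.observables import (
    MembraneProfile,
    UnitMap,
    bilayer_geometry,
    calibrate_units,
    fit_kappa,
    radial_profile,
    tension,
    tube_radius,
)
from memfis.scft import DensityState, scft_converge
from memfis.topology import seed_topology


def _synthetic_bilayer(x, center=0.0, head_at=1.0, width=0.25):
    """Tail core flanked by head peaks at center +/- head_at."""
    tail = np.exp(-((x - center) / (0.6 * head_at)) ** 4)
    head = (np.exp(-((x - center - head_at) / width) ** 2)
            + np.exp(-((x - center + head_at) / width) ** 2))
    solv = np.clip(1.0 - tail - 0.4 * head, 0.0, 1.0)
    return MembraneProfile(x, tail, 0.4 * head, solv)


def test_bilayer_geometry_on_constructed_profile():
    x = np.linspace(-4, 4, 801)
    prof = _synthetic_bilayer(x)
    geom = bilayer_geometry(prof)
    assert geom.thickness == pytest.approx(2.0, abs=1e-3)
    assert geom.midplane == pytest.approx(0.0, abs=1e-3)
    assert geom.core_fwhm > 0


def test_bilayer_geometry_translation_equivariance():
    x = np.linspace(-4, 6, 1001)
    g0 = bilayer_geometry(_synthetic_bilayer(x, center=0.0))
    g1 = bilayer_geometry(_synthetic_bilayer(x, center=1.3))
    assert g1.midplane - g0.midplane == pytest.approx(1.3, abs=1e-3)
    assert g1.thickness == pytest.approx(g0.thickness, abs=1e-6)


def test_bilayer_geometry_rejects_flat_and_double_profiles():
    x = np.linspace(-4, 4, 401)
    flat = MembraneProfile(x, np.zeros_like(x), np.zeros_like(x),
                           np.ones_like(x))
    with pytest.raises(ValueError):
        bilayer_geometry(flat)
    double = _synthetic_bilayer(x, center=-2.0)
    d2 = _synthetic_bilayer(x, center=2.0)
    both = MembraneProfile(x, double.phi_tail + d2.phi_tail,
                           double.phi_head + d2.phi_head,
                           np.ones_like(x))
    with pytest.raises(ValueError):
        bilayer_geometry(both)


def test_tube_radius_orders_nested_bilayers():
    grid = Grid("radial1d", (240,), (0.05,))
    r = grid.coords(0)
    def shell(c):
        tail = np.exp(-((r - c) / 0.5) ** 4)
        head = (np.exp(-((r - c - 0.8) / 0.25) ** 2)
                + np.exp(-((r - c + 0.8) / 0.25) ** 2))
        return tail, 0.4 * head
    t1, h1 = shell(3.0)
    t2, h2 = shell(6.5)
    dens = DensityState(t1 + t2, h1 + h2,
                        np.clip(1 - t1 - t2 - h1 - h2, 0, 1))
    radii = tube_radius(dens, grid, expect=2)
    assert radii[0] == pytest.approx(3.0, abs=0.05)
    assert radii[1] == pytest.approx(6.5, abs=0.05)
    assert radii[1] > radii[0] + 1.6  # outer > inner + thickness


# ---------------------------------------------------------------------------
# rigidity fit
# ---------------------------------------------------------------------------


def test_fit_kappa_exact_recovery():
    kappa = 20.0
    sigmas = np.array([0.5, 1.0, 2.0, 4.0])
    pts = [(np.sqrt(kappa / (2 * s)), s) for s in sigmas]
    k, expo = fit_kappa(pts)
    assert k == pytest.approx(kappa, rel=1e-8)
    assert expo == pytest.approx(-0.5, abs=1e-8)


def test_fit_kappa_scaling():
    sigmas = np.array([0.5, 1.0, 2.0])
    p1 = [(np.sqrt(5.0 / (2 * s)), s) for s in sigmas]
    p4 = [(np.sqrt(20.0 / (2 * s)), s) for s in sigmas]
    for (r1, _), (r4, _) in zip(p1, p4):
        assert r4 == pytest.approx(2 * r1, rel=1e-12)
    assert fit_kappa(p4)[0] == pytest.approx(4 * fit_kappa(p1)[0], rel=1e-10)


def test_fit_kappa_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        fit_kappa([(1.0, 1.0), (1.1, 1.2)])
    with pytest.raises(ValueError):
        fit_kappa([(1.0, 1.0), (1.05, 1.1), (1.1, 1.3)])  # <2x sigma span


# ---------------------------------------------------------------------------
# unit calibration
# ---------------------------------------------------------------------------


def test_unit_map_round_trip_and_arithmetic():
    umap = UnitMap(nm_per_R0=2.5, C=12.0)
    assert umap.tension_to_phys(umap.tension_to_model(1.0)) == pytest.approx(
        1.0, rel=1e-12)
    assert umap.length_to_R0(umap.length_to_nm(3.3)) == pytest.approx(
        3.3, rel=1e-12)
    # 1 kBT/nm^2 = 4.11 Dyn/cm
    assert umap.dyn_cm_per_kBT_nm2 == pytest.approx(4.11, rel=1e-12)
    # 1 Dyn/cm in model units: 0.243 kBT/nm^2 * nm_per_R0^2 / C
    expect = (1.0 / 4.11) * 2.5**2 / 12.0
    assert umap.tension_to_model(1.0) == pytest.approx(expect, rel=1e-9)


def test_calibrate_units_from_synthetic_profile():
    x = np.linspace(-4, 4, 801)
    prof = _synthetic_bilayer(x)  # thickness 2 R0
    umap = calibrate_units(prof, target_thickness_nm=5.0,
                           lipid_volume_nm3=1.3)
    assert umap.nm_per_R0 == pytest.approx(2.5, abs=0.01)
    assert umap.C == pytest.approx(2.5**3 / 1.3, rel=0.02)
    # different anchor rescales lengths proportionally
    umap2 = calibrate_units(prof, target_thickness_nm=4.0)
    assert umap2.nm_per_R0 / umap.nm_per_R0 == pytest.approx(0.8, rel=1e-6)


def test_unit_map_validation():
    with pytest.raises(ValueError):
        UnitMap(nm_per_R0=-1.0)
    with pytest.raises(ValueError):
        UnitMap(nm_per_R0=2.0, C=0.0)


# ---------------------------------------------------------------------------
# tension from converged states
# ---------------------------------------------------------------------------


def test_tension_requires_planar_grid(converged_bilayer, params):
    grid = Grid("radial1d", (32,), (0.1,))
    with pytest.raises(ValueError):
        tension(converged_bilayer.fields, converged_bilayer.densities,
                params, grid)


def test_sigma_decreases_with_mu_and_changes_sign(params, planar_grid_coarse):
    """Gibbs adsorption: more lipid-favorable reservoirs relax the membrane.

    sigma(mu) is strictly decreasing (the membrane adsorbs lipid) and
    crosses zero at the tensionless point.
    """
    sigmas, mus = [], []
    for mass in (1.25, 1.35, 1.45):
        seed = seed_topology("planar_bilayer", planar_grid_coarse,
                             params.with_mu(11.6))
        res = scft_converge(seed, params, planar_grid_coarse,
                            lipid_mass=mass, tol=1e-7, max_iter=6000,
                            mixing=0.02, warmup=100)
        tp = tension(res.fields, res.densities, params.with_mu(res.mu),
                     planar_grid_coarse)
        sigmas.append(tp.sigma)
        mus.append(res.mu)
    assert mus[0] < mus[1] < mus[2]
    assert sigmas[0] > sigmas[1] > sigmas[2]
    assert sigmas[0] > 0 > sigmas[2]  # tensionless point inside the bracket
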