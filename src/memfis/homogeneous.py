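"""Closed-form thermodynamics of the homogeneous lipid/solvent mixture.

For spatially uniform states the SCFT reduces to Flory-Huggins theory of an
incompressible diblock/homopolymer mixture.  With lipid volume fraction
``phi`` (tail ``f*phi``, head ``(1-f)*phi``), solvent ``1 - phi``, and
solvent length ratio ``beta = N_s/N``, the Helmholtz free-energy density per
site (k_BT, chain-number entropy with Stirling ``-1`` terms) is

    fFH(phi) = phi (ln phi - 1) + ((1-phi)/beta) (ln(1-phi) - 1)
               + chiN * phiA * phiB,

with ``phiA = f*phi`` and ``phiB = 1 - f*phi``.  Its stationarity condition
``dfFH/dphi = mu`` is exactly the homogeneous limit of the SCFT equations
under the activity convention used throughout (solvent activity 1, lipid
weight ``exp(mu)``), which makes these formulas the bulk reference for
excess free energies and membrane tension.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .params import ModelParams

__all__ = [
    "fh_free_energy_density",
    "mu_of_phi",
    "grand_potential_density",
    "solvent_branch_phi",
    "bulk_state",
    "bulk_field_values",
]


def _xlogxm1(x: np.ndarray | float) -> np.ndarray | float:
    """x*(ln x - 1) with the x -> 0 limit 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0, x * (np.log(np.where(x > 0, x, 1.0)) - 1.0), 0.0)
    return out if out.ndim else float(out)


def fh_free_energy_density(phi: float, params: ModelParams) -> float:
    """Flory-Huggins Helmholtz free energy per unit volume (k_BT)."""
    beta = params.solvent_ratio
    phi_s = 1.0 - phi
    phi_a = params.f * phi
    phi_b = 1.0 - phi_a
    return float(
        _xlogxm1(phi)
        + _xlogxm1(phi_s) / beta
        + params.chiN * phi_a * phi_b
    )


def mu_of_phi(phi: float, params: ModelParams) -> float:
    """Exchange chemical potential of the uniform mixture, d fFH / d phi."""
    beta = params.solvent_ratio
    f = params.f
    return float(
        np.log(phi)
        - np.log1p(-phi) / beta
        + params.chiN * f * (1.0 - 2.0 * f * phi)
    )


def grand_potential_density(phi: float, params: ModelParams, mu: float) -> float:
    """Grand potential per unit volume, fFH(phi) - mu*phi (k_BT)."""
    return fh_free_energy_density(phi, params) - mu * phi


def _spinodal_upper(params: ModelParams) -> float:
    """Upper end of the solvent-rich branch: first maximum of mu(phi).

    ``mu'(phi) = 1/phi + 1/(beta(1-phi)) - 2 chiN f^2`` is convex with at
    most two roots in (0, 1); the smaller one bounds the solvent branch.
    Returns 1 (minus epsilon) if mu is monotone.
    """
    beta = params.solvent_ratio
    c = 2.0 * params.chiN * params.f**2
    # 1/phi + 1/(beta(1-phi)) = c  =>  c*beta*phi^2 + (1 - beta - c*beta)*phi + beta = 0
    a2 = c * beta
    a1 = 1.0 - beta - c * beta
    a0 = beta
    disc = a1 * a1 - 4.0 * a2 * a0
    if a2 <= 0 or disc <= 0:
        return 1.0 - 1e-12
    r1 = (-a1 - np.sqrt(disc)) / (2.0 * a2)
    r2 = (-a1 + np.sqrt(disc)) / (2.0 * a2)
    roots = sorted(r for r in (r1, r2) if 0.0 < r < 1.0)
    return roots[0] if roots else 1.0 - 1e-12


def solvent_branch_phi(mu: float, params: ModelParams) -> float:
    """Lipid fraction of the solvent-rich homogeneous state at given mu.

    Solves ``mu_of_phi(phi) = mu`` on the stable solvent branch by
    bracketed root finding.  Raises if mu exceeds the branch end (the
    reservoir would be supersaturated with lipid).
    """
    hi = _spinodal_upper(params)
    mu_hi = mu_of_phi(hi, params)
    if mu >= mu_hi:
        raise ValueError(
            f"mu = {mu} is above the solvent-branch limit ({mu_hi:.4f}); "
            "no solvent-rich homogeneous state exists"
        )
    lo = 1e-300
    return float(brentq(lambda p: mu_of_phi(p, params) - mu, lo, hi,
                        xtol=1e-15, rtol=8.9e-16, maxiter=200))


def bulk_state(mu: float, params: ModelParams) -> tuple[float, float]:
    """(phi_lipid, grand potential density) of the bulk solvent reservoir."""
    phi = solvent_branch_phi(mu, params)
    return phi, grand_potential_density(phi, params, mu)


def bulk_field_values(mu: float, params: ModelParams) -> tuple[float, float, float]:
    """Self-consistent (w_A, w_B, xi) of the homogeneous reservoir.

    ``w_A = chiN*phi_B``, ``w_B = chiN*phi_A`` and the pressure field from
    the solvent weight, ``xi = -ln(phi_s)/beta - chiN*phi_A``.
    """
    beta = params.solvent_ratio
    phi = solvent_branch_phi(mu, params)
    phi_a = params.f * phi
    phi_b = 1.0 - phi_a
    w_a = params.chiN * phi_b
    w_b = params.chiN * phi_a
    xi = -np.log(1.0 - phi) / beta - params.chiN * phi_a
    return float(w_a), float(w_b), float(xi)
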