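"""Model constants for the Gaussian-chain lipid/solvent mixture.

The lipid is an AB diblock copolymer: a hydrophobic tail block (A) of
fraction ``f`` and a hydrophilic head block (B) of fraction ``1 - f`` of the
chain's ``N`` segments.  The solvent is a short B homopolymer of
``solvent_ratio * N`` segments.  Lengths are measured in
``R0 = b * sqrt(N)``; fields and energies in k_BT.  The ensemble is
semi-grand canonical: the total segment density is fixed (incompressible)
and lipid and solvent exchange with a reservoir at exchange chemical
potential ``mu = mu_lipid - mu_solvent`` (k_BT per chain).
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class ModelParams:
    """Constants of the amphiphile model.

    Attributes
    ----------
    chiN
        Flory-Huggins A-B repulsion times lipid chain length (dimensionless).
    f
        Tail (A-block) fraction of the lipid chain.
    solvent_ratio
        Solvent chain length over lipid chain length, ``N_s / N``.
    mu
        Exchange chemical potential of lipid relative to solvent, in k_BT.
        The convention fixed throughout: solvent activity is 1 and
        ``exp(mu)`` multiplies the lipid statistical weight.
    ds
        Contour step as a fraction of the lipid chain.  ``f/ds`` and
        ``(1-f)/ds`` must be integers so the tail/head junction falls on a
        contour grid point.
    """

    chiN: float = 30.0
    f: float = 0.8
    solvent_ratio: float = 0.1
    mu: float = 0.0
    ds: float = 0.01

    def __post_init__(self):
        if not 0.0 < self.f < 1.0:
            raise ValueError("f must lie in (0, 1)")
        if self.chiN <= 0:
            raise ValueError("chiN must be positive")
        if self.solvent_ratio <= 0:
            raise ValueError("solvent_ratio must be positive")
        if self.ds <= 0:
            raise ValueError("ds must be positive")
        for name, x in (("f/ds", self.f / self.ds),
                        ("(1-f)/ds", (1.0 - self.f) / self.ds)):
            if abs(x - round(x)) > 1e-9 * max(1.0, x):
                raise ValueError(f"{name} = {x} is not an integer")

    # contour discretization -------------------------------------------------

    @property
    def ns_tail(self) -> int:
        return round(self.f / self.ds)

    @property
    def ns_head(self) -> int:
        return round((1.0 - self.f) / self.ds)

    @property
    def ns_lipid(self) -> int:
        return self.ns_tail + self.ns_head

    @property
    def ns_solvent(self) -> int:
        n = max(1, round(self.solvent_ratio / self.ds))
        return n

    @property
    def ds_solvent(self) -> float:
        """Solvent contour step (the solvent length may not divide ds)."""
        return self.solvent_ratio / self.ns_solvent

    def with_mu(self, mu: float) -> "ModelParams":
        return replace(self, mu=mu)
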