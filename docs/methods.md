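# Methods

## Model

`memfis` implements self-consistent field theory (SCFT) of a coarse-grained
amphiphile/solvent mixture used to study membrane nanotubes and the
topological intermediates of membrane fission.  A lipid is a Gaussian
AB diblock chain of `N` statistical segments: a hydrophobic tail block of
fraction `f = 0.8` (species A) and a hydrophilic head block of fraction
`1 - f` (species B).  The solvent is a short B homopolymer of `N_s = N/10`
segments.  A/B contacts are penalized by the Flory–Huggins parameter,
`chiN = 30`, deep in the strong-segregation regime where the mixture
self-assembles into bilayers with a nearly pure tail core.  Lengths are
measured in the natural chain size `R0 = b sqrt(N)`, and the melt is
incompressible: the local segment fractions satisfy
`phi_tail + phi_head + phi_solvent = 1` everywhere.

The ensemble is semi-grand canonical.  The total segment density is fixed;
lipid and solvent exchange with a reservoir at exchange chemical potential
`mu = mu_lipid - mu_solvent` (k_BT per chain).  The activity convention is
fixed once and used everywhere: the solvent activity is 1 and `exp(mu)`
multiplies the lipid single-chain weight.  Under this convention the
homogeneous limit of the SCFT equations is exactly the stationarity
condition of the closed-form mixture free-energy density

    f_FH(phi) = phi (ln phi - 1) + ((1-phi)/beta)(ln(1-phi) - 1)
                + chiN * phi_A * phi_B,        beta = N_s / N,

which the test suite uses as an analytic oracle (agreement to 1e-8).
Other textbook conventions differ from this one by constant offsets in
`mu` and the free energy; all observables reported here are differences
(tensions, barriers), which are convention-independent.

Chain statistics enter through the modified diffusion equation
`dq/ds = (1/6) Lap q - W q` solved by symmetric operator splitting
(half-potential, diffusion, half-potential), second order in the contour
step `ds = 0.01`.  The diffusion substep applies the exact exponential of
the discrete Laplacian in every geometry: FFT on periodic axes, DCT-II
eigenbasis on bounded Cartesian axes, and a dense symmetric
eigendecomposition of the cylindrical finite-difference operator on radial
axes.  Treating every geometry with the exact exponential of its own
discrete operator (rather than, say, Crank–Nicolson time stepping in the
radial direction) matters: time-stepping truncation error shifts chemical
potentials by O(1e-2) k_BT, which is large on the scale of the tensions
studied here.

Mean-field only: no composition fluctuations or thermal noise, matching
the theory the package implements.

## Numerics of self-consistency

Fields are iterated by Picard mixing with Anderson acceleration (history
10).  Robustness features that proved necessary:

* **Logarithmic pressure update.**  Densities respond exponentially to the
  pressure field `xi`, so the incompressibility error signal used in the
  update is `ln(phi_total)`, not `phi_total - 1`.
* **Canonical-lipid mode.**  The reservoir-coupled iteration loses
  stability for stretched membranes (sigma above roughly half the rupture
  tension): the membrane-mass "breathing" mode becomes a growing spiral of
  the fixed-point map even though the state itself is metastable.  Fixing
  the integrated lipid content and renormalizing the activity every
  iteration removes the runaway mode; the effective `mu = ln z` is
  reported and the converged fields are identical to a reservoir-coupled
  solution at that `mu`.  Equilibria at prescribed `mu` or tension are
  then found by one-dimensional root finding on the lipid content.
* **Moment pins.**  Shape modes with nearly flat free-energy directions
  (tube radius; the inner/outer mass split of a nested double tube; the
  bilayer separation of a stalk) converge arbitrarily slowly or spiral.
  Each such mode is frozen by a scalar Lagrange multiplier coupling a
  moment of the tail density (center of mass, smooth shell indicator,
  axial moment) to a target value; the multiplier is part of the
  accelerated fixed-point vector.  At the end the multiplier is driven to
  zero by a secant/Broyden iteration over the target, so the reported
  states solve the *unconstrained* SCFT equations: the pin force is the
  free-energy gradient along the pinned mode and vanishes at the free
  equilibrium.
* **Trust-region-like safeguards.**  Anderson steps that raise the
  residual 10x above the running best trigger a restart from the best
  state with reduced acceleration damping; the damping recovers while
  progress is steady.

Default tolerances: max-norm field residual 1e-6 (planar workflow runs
1e-8, tube equilibria 1e-9 because the pin force must be resolved), which
keeps the incompressibility violation below 1e-6.  Pinned root searches
warm-start successive solves from the previous iterate's fields and
multiplier, which cuts their cost several-fold.  Two structures relax
their last soft modes extremely slowly and are accepted at a stagnated
residual with a stationary structure: double-membrane tubes (accepted
below 1e-2, which still fixes the radii to about 1%) and the stalk
(accepted below 0.2; the residual is a grid-scale flicker localized at
the strongly curved neck-bilayer junction while the global structure is
unchanged over tens of thousands of iterations).

## Observables and unit calibration

Thickness is head peak-to-peak (the distance between the two head-density
maxima flanking the tail core, located by quadratic interpolation),
matching how bilayer thickness is read from cryoEM micrographs; the
hydrophobic-core FWHM is a secondary diagnostic.  Tube radii are
bilayer-midplane radii.  Membrane tension is the excess grand free energy
per area of a planar bilayer relative to homogeneous bulk solvent at the
same `mu`.  `sigma(mu)` is strictly decreasing (Gibbs adsorption with
positive lipid excess) and crosses zero at the tensionless point
`mu* = 11.655` for the default model; the tensionless bilayer is
`1.334 R0` thick.

Physical units require two anchors:

* **Length**: the tensionless bilayer thickness is set to 5 nm (the
  cryoEM value for these membranes), giving `1 R0 = 3.75 nm`.
* **Energy**: the SCFT functional is computed per chain volume, so every
  extensive energy carries one factor of the invariant chain
  concentration `C = rho R0^3 / N` (chains per R0^3).  `C` is anchored by
  a typical phospholipid molecular volume of 1.3 nm^3:
  `C = nm_per_R0^3 / 1.3 ~ 40`.  With these anchors 1 k_BT/nm^2 =
  4.11 Dyn/cm, the model's rupture tension is ~23 Dyn/cm (realistic for
  lipid bilayers), and the bending rigidity comes out `kappa ~ 8 k_BT` —
  a softer membrane than a typical phosphatidylcholine bilayer
  (~20 k_BT), as expected for a generic amphiphile model with a single
  chain architecture.  All R0-unit results are independent of both
  anchors; changing an anchor rescales only the nm / k_BT values.

### Cylindrical reference calibration

Planar and cylindrical grids discretize the bilayer interface slightly
differently, biasing the free energy per area by O(dx^2) between the two
geometries (equivalent to a `mu` shift of ~0.011 at dx = 0.05, shrinking
~4x when dx is halved).  Left uncorrected, this bias masquerades as an
extra tension offset for every tube and visibly distorts the
radius–tension law.  The package calibrates it once per resolution: a
single very large ring (r = 12 R0, locally flat) is converged to its free
equilibrium, and the difference between its `mu` (after removing the
small `kappa/2r^2` bending contribution) and the planar `mu*` is applied
as a shift whenever a tube's `mu` is converted to a tension through the
planar equation of state.  After this calibration the fitted `kappa` is
radius-independent (0.195 +/- 0.01 in SCFT units) and the log-log slope
of r vs sigma is -0.51 +/- 0.02 over a tenfold tension span.

### Tubes and the radius–tension law

An equilibrium tube at prescribed tension is found by: (i) sampling the
planar equation of state sigma(mu, mass/area); (ii) converging
radius-pinned canonical tubes at fixed lipid mass per length and driving
the pin force to zero (secant); (iii) adjusting the mass until the tube's
tension (from its effective `mu`) matches the target.  Double-membrane
tubes add the shell-split pin and a 2D Broyden iteration over both radii.
The sweep fits `r = sqrt(kappa/(2 sigma))`; the exponent diagnostic uses
radii 1.8–4 R0 where the tension span is wide while curvature corrections
remain moderate.

At 1 Dyn/cm (0.084 SCFT units with the calibration above) the model
sustains a single-membrane tube of radius ~1.3 R0 ~ 4.8 nm.  This is
smaller than the ~8.5 nm cryoEM-scale reference because the model's
`kappa` is ~8 k_BT rather than the ~35 k_BT implied by an 8.5 nm tube at
that tension; the radius at fixed physical tension scales as
`sqrt(kappa)` and is insensitive to the length anchor.

### Stalk (hemifusion) intermediate

The stalk is computed in the axisymmetric half-domain: a reflecting plane
through the stalk center and one bilayer held at half the membrane
separation by a z-moment pin (the physical setup prescribes the
inter-membrane distance; the pin plays the role of the constraint that in
experiment is provided by the apposed-membrane geometry).  The neck is
seeded as a tail-filled bridge on the axis and relaxed.  Metastability is
probed two ways: the converged stalk must retain a connected tail core
through the mirror plane, and after a random field kick
(amplitude 0.5 k_BT) the re-converged state must return to the stalk
rather than to two detached bilayers.

## Minimum free-energy paths

The simplified string method operates on an abstract landscape interface
(energy, partial descent, metric, interpolation), with two backends: the
SCFT functional over field configurations (descent = damped
self-consistency iterations; metric = root-mean-squared local density
change, summed over species) and analytic test energies over a few scalar
degrees of freedom.  Strings are redistributed to equal arc length after
every sweep (iterated piecewise-linear redistribution, spacing CV below
1e-3); the reaction coordinate alpha is normalized cumulative arc length.
Barriers pair each interior maximum of F(alpha) with the lowest preceding
minimum.  The machinery is validated against brute-force saddle location
on a two-well analytic landscape (barrier agreement within 1%, error
decreasing with node count).

## Synthetic data

The fluorometry module's generator emulates the quantification pipeline of
nanotube fluorescence experiments: a tube of midplane radius `r` carries
area `2 pi r` per unit length, doubled for a double-membrane tube, with
the fluorescence-per-area calibration `D` from a supported bilayer.  Line
scans are Gaussian-PSF profiles; measurement noise is additive on the
integrated fluorescence with standard deviation `noise_sd * F_l`, so the
recovered radius `F_l / (2 pi D)` is unbiased with per-tube relative SD
equal to `noise_sd`.  The generator reproduces the bimodal F_l histogram
(DM peak at twice the SM peak) used for lamellarity classification; it
does not emulate image segmentation, kymographs, PSF estimation, or
spatially correlated noise, so passing tests validate the quantification
formulas, not an imaging pipeline.

## Problem sizes

Default production settings: dx = 0.05 R0 (planar/radial 1D; 16 R0
domains), contour step ds = 0.01; stalk calculations use dx = 0.1,
ds = 0.02 on a 3.2 x 3.2 R0 axisymmetric half-domain.  The unit tests run
coarser 1D grids (dx = 0.1).  These sizes resolve the interface
(width ~0.15 R0 at chiN = 30) marginally; halving dx and ds changes the
planar thickness by 0.2% and tensions by well under 1% once the
cylindrical reference calibration is applied at the same resolution.

## Known limitations

* One lipid species, no charge, no explicit hydration repulsion: the
  double-membrane gap is set by solvent-mediated interactions alone.
* Mean-field: no thermally excited shape fluctuations; rigidities are
  bare SCFT values.
* The nm / k_BT calibration depends on the thickness and lipid-volume
  anchors described above; quantities in R0 / SCFT units are the primary
  outputs.
* Cartesian 3D grids are a coarse capability (periodic spectral only) and
  are not used by the validated workflows.
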