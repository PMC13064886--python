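# Methods

## Model

The vocal fold is idealized as a rectangular two-layer prism (the body–cover
model): a stiff inner *body* and a soft superficial *cover*, perfectly bonded
at a planar interface. Each layer is a linear elastic, transversely isotropic
solid whose plane of isotropy is perpendicular to the anterior–posterior (AP)
axis. Small in vacuo vibrations about the rest state satisfy the
Navier–Cauchy eigenproblem

    -rho omega^2 u_i = d_j ( C_ijkl eps_kl ),   eps_kl = (d_k u_l + d_l u_k)/2,

with zero displacement on the mechanically fixed faces (lateral, anterior,
posterior), zero traction on the free faces (medial, superior, inferior), and
displacement/traction continuity across the body–cover interface. The
eigenvalue is lambda = omega^2 (rad^2/s^2); reported frequencies are
f = sqrt(lambda)/2pi in Hz.

Coordinates (used by every module): x runs medial→lateral over the depth
Dc + Db with the cover occupying x <= Dc, y inferior→superior over the
medial-surface thickness T, z anterior→posterior over the length L; the
origin is the medial–inferior–anterior corner.

## Constitutive parameterization

The free material parameters of a configuration are the transverse Young's
modulus Et (shared by both layers) and the AP shear moduli GAP of body and
cover; the AP Young's modulus is tied to shear by E_AP = 4 GAP. These three
numbers do not close a transversely isotropic law, so the remaining constants
live in `AuxiliaryElasticParams`:

| constant | meaning | default | rationale |
| --- | --- | --- | --- |
| nu_t | in-plane Poisson ratio | 0.499 | near-incompressible transverse plane |
| nu_ap | axial–transverse Poisson ratio | 0 | simplest stable closure; <0.3% effect on the low modes |
| eap_factor | E_AP / G_AP | 4 | the model's stated coupling |

with the in-plane shear modulus G_t = Et / (2 (1 + nu_t)). The stiffness is
built by inverting the compliance matrix and is checked positive definite for
every configuration; Voigt order is (11, 22, 33, 23, 13, 12) with engineering
shear strains, everywhere.

Note that with nu_ap = 0 the axial direction decouples from the in-plane bulk
response, so the three-dimensional bulk modulus stays finite: the material is
*not* volumetrically locking at nu_t = 0.499, and full Gauss integration of
trilinear hexahedra converges cleanly (verified by the mesh-convergence
test). A mean-dilatation or selective-integration element was therefore not
needed.

## Geometry profiles

The body–cover parameterization this package follows lists body depth
60 mm and cover depth 15 mm — an order of magnitude above typical vocal
fold dimensions, while T = 4.5 mm and L = 17 mm are typical. Both readings
ship as profiles:
`PRINTED_PROFILE` (Db = 60 mm, Dc = 15 mm) and `RESCALED_PROFILE`
(Db = 6.0 mm, Dc = 1.5 mm). The rescaled profile is the default and the one
used by the acceptance computations; with it, the computed low
eigenfrequencies land in the expected range (~80–100 Hz), whereas the
printed profile yields ~65–75 Hz.

## Finite-element reference solver

* 8-node trilinear hexahedra on a structured grid; the interface plane x = Dc
  always coincides with a mesh plane, so no element straddles layers.
* Full 2×2×2 Gauss quadrature for stiffness and consistent mass. Because the
  mesh is axis-aligned with one element shape per layer, only two distinct
  element matrix pairs exist per configuration; assembly is a vectorized
  scatter.
* Dirichlet constraints by row/column elimination (exact zeros), then sparse
  shift-invert `eigsh` at sigma = 0 for the smallest eigenvalues.
* Eigenvectors are unit-normalized over all DOFs and sign-fixed so the
  largest-magnitude component is positive.
* Mesh convergence: frequencies decrease monotonically under refinement;
  the mesh-limit estimate is an h² Richardson fit f(h) = f0 + c·h² over a
  resolution ladder (trilinear elements converge at second order). The
  acceptance ladder runs (8,6,8) → (24,16,24), about 28k free DOFs at the
  finest rung.

The reference dataset covers the Cartesian material grid
Et ∈ {1,2,4} kPa × GAP_body ∈ {1,10,20,30,40} kPa × GAP_cover ∈ same
(75 configurations), 10 modes each, split 80/20 by configuration with a
seeded shuffle (60 train / 15 validation). Which configurations are held out
is a seed-dependent draw; split-dependent numbers are therefore
distribution-level, not identity-level.

Eigenvalue ordering can swap between configurations as materials vary, so
mode identities are aligned by the modal assurance criterion
MAC(u, v) = (u·v)² / (|u|²|v|²) against an anchor configuration, greedily in
anchor-mode order with frequency-order tie-breaks; the MAC tables are
returned for audit. Cross-configuration mode-stability statistics
(median/mean pairwise |cos| per mode over the training split) quantify how
strongly a mode's spatial pattern depends on the material parameters; the
low-order modes are markedly more stable than mode 8 and above, which is the
property the acceptance suite asserts.

## Network

A SiLU-activated two-layer dense encoder maps the min–max-normalized
material triple (Et, GAP_body, GAP_cover) to a 64-vector (width
configurable); the encoding is concatenated with the spatial coordinates
affinely mapped to [-1, 1]³ and fed to a SIREN: hidden layers
z ← sin(omega0 (W z + b)) with omega0 = 5, four hidden layers × 128 units in
the reference configuration, and a linear 3-component output head.
Initialization follows the sinusoidal-network uniform scheme: first layer
U(±1/fan_in), deeper layers U(±sqrt(6/fan_in)/omega0). Normalization
constants are stored inside the checkpoint so inference is self-contained.

Displacements are nondimensional: eigenmodes carry no physical amplitude and
every shape metric (Rayleigh quotient, cosine) is scale-invariant, so no
output scale is imposed.

Spatial first and second derivatives are propagated layerwise in closed form
(value/Jacobian/Hessian through each affine and sine layer), which is exactly
the chain rule that nested automatic differentiation would apply; the
derivative chain through the coordinate normalization converts them to
per-metre units. The whole computation is expressed in a small reverse-mode
autodiff engine (`vfpinn.autodiff`), so one backward pass yields parameter
gradients of any loss built on u, grad u, or the Hessian. Derivative
exactness is enforced against central finite differences in the test suite
(first order to 1e-5 relative at step 1e-4, second order to 1e-3).

## Loss stack

For one configuration and one target mode, with lambda_RQ the Rayleigh
quotient of the predicted field over the weighted interior collocation set:

* governing-equation term: mean |d_j sigma_ij + rho·lambda·u_i|² at interior
  points, with lambda = lambda_RQ (gradients flow through it; a detach flag
  exists for ablation);
* Dirichlet term: mean |u|² on fixed-face points;
* Neumann term: mean |sigma·n|² on free-face points;
* interface term: mean |u⁺−u⁻|² + mean |sigma⁺·n − sigma⁻·n|² at x = Dc,
  each side with its own stiffness (for one continuous network the
  displacement jump is identically zero);
* eigenvalue term: ((lambda_RQ − lambda_true)/lambda_true)²;
* cosine term: 1 − cos(u_pred, u_true), evaluated on free-surface points
  (a volumetric option exists), with u_true interpolated from the reference
  mesh (trilinear by default; the interpolation order is configurable).

The total is the plain sum (all weights 1 by default, configurable).

Nondimensionalization: the displacement terms are O(1) by construction, but
raw residual and traction magnitudes carry units. The residual is divided by
rho·lambda_true (the inertial force-density scale of the target mode) and
tractions by Et_cover / L_char with L_char half the largest box extent (the
coordinate-normalization length), making every term dimensionless and
comparable at weight 1. lambda_true enters the eigenvalue term in rad²/s²;
the term is invariant to the Hz²-vs-rad²/s² choice as long as one convention
is used for both eigenvalues.

### Quadrature

Interior collocation is stratified by layer: counts proportional to layer
volumes (remainder to the body), each stratum uniform, per-point weight =
stratum volume / stratum count. Sums over the set therefore partition the
prism volume exactly and the body-to-cover volume ratio is honoured by
construction — this is what makes the Rayleigh quotient's strain and kinetic
integrals consistent between layers. With 2×10⁴ points the Rayleigh quotient
of the interpolated reference mode agrees with the mesh-limit eigenvalue to
well under 2%.

### Reference-mode interpolation

Reference modes are interpolated per layer (separate tensor-product
B-splines for cover and body), because the true mode has a strain kink at
the interface: traction, not strain, is continuous there. Order 1 reproduces
the FEM trilinear field; order 3 gives the twice-differentiable
representation needed when the mode is pushed through the residual term
(loss-stack consistency checks). Two-sided evaluation at the interface gives
exact displacement continuity and one-sided tractions.

## Training and evaluation

One network is trained per mode (independent training avoids mode mixing);
the objective is the composite loss summed over training configurations,
optimized with Adam (default learning rate 1e-4, cosine decay to a 10%
floor — the optimizer is this package's choice, standard for SIREN-based
physics-informed models). Collocation is a fixed seeded draw by default;
per-epoch resampling is available and recommended: with a fixed sparse draw
the network can minimize the eigenvalue term against the *sampled* Rayleigh
quotient rather than the integral (quadrature overfitting), which resampling
removes. Every randomized component (init, sampling, split) carries an
explicit seed recorded in the run manifest; non-finite losses abort with the
epoch reached.

Evaluation per configuration: f_pred = sqrt(lambda_RQ)/2pi from a fresh,
seeded, dense stratified draw (2×10⁴ points by default); relative error
100·|f_pred − f_true|/f_true; and |cos| between predicted and reference
displacements on the free-surface mesh nodes, *excluding* nodes that also
lie on a fixed face — there the reference is identically zero, so including
them only inflates the predicted norm and biases the metric. The evaluation
cosine uses the absolute value and the MAC-matched reference mode, making it
invariant to eigenvector sign and cross-configuration mode swaps.

## Scaled-down study conditions

The full-scale protocol (75 configurations, 4×128 network, 3000 epochs per
mode) is exercised structurally but not at full compute in the test suite.
The end-to-end recovery check runs the package's scaled-down conditions: a
1×3×3 material subgrid (Et = 2 kPa; GAP body/cover ∈ {10, 20, 30} kPa) on a
6×4×6 mesh, mode 1, a 3×48 SIREN with a 2×24 encoder, 256 interior + 48
per-face + 32 interface points resampled each epoch, 1500 epochs at learning
rate 2e-3, fixed seeds. Under these conditions the trained network reaches a
few percent mean eigenfrequency error and |cos| ≈ 0.98 on held-out
configurations; the acceptance thresholds are <10% and >0.9.

## What the generated data does and does not emulate

The FEM module generates exactly the quantities the method consumes —
per-configuration ascending eigenfrequency lists and unit-norm nodal
eigenmodes on a shared mesh — under the same idealizations as the model
itself (linear elasticity, rectangular geometry, perfect bonding, in vacuo).
It does not emulate measurement noise, geometric variability between
subjects, viscoelastic damping, or air loading; passing tests therefore
demonstrate correctness of the method under the model's assumptions, not
robustness to real tissue data.

## Known limitations and numerical notes

* The solver behind the tabulated reference eigenfrequencies leaves its
  mesh, element order, and full constitutive constants unstated; with every stated condition honoured
  (rescaled profile, nu_t = 0.499, E_AP = 4 GAP, rho = 1030 kg/m³) the
  mesh-limit frequencies for the Et = 2 kPa / GAP 20/10 kPa configuration
  come out at 83.0 and 100.0 Hz against the tabulated 90.60 and 96.17 Hz
  (−8.4% / +4.0%) — recomputed by `scripts/acceptance.py`. The mode spacing
  differs as well, so no global stiffness rescaling can close both gaps;
  the residual discrepancy is attributed to those unstated solver details.
* The eigenvalue loss plateaus if the field collapses toward a constant
  (lambda_RQ → 0 satisfies the physics terms trivially); the data terms pull
  the optimizer out of this regime, but short runs at high learning rates
  can linger there.
* Degenerate inputs: zero fields raise a degenerate-field error in the
  Rayleigh quotient and cosine loss; non-positive reference eigenvalues are
  rejected; points outside the prism raise a domain error; meshes that
  cannot separate the two layers are rejected.
* Ties in MAC matching are broken by ascending frequency; matched datasets
  may have locally non-ascending frequency lists, which is expected and
  recorded via the `matched_to` field.
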