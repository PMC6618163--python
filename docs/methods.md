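# Methods

This note records the model, the numerical choices, and the reasoning
behind the design decisions in `cardiouq`. It is the reference for what
the package computes and what its tests do and do not establish.

## Forward model

### Geometry

The ventricle is idealized as a truncated shell between two coaxial
prolate spheroids sharing a center on the long axis, cut by a flat basal
plane. Coordinates are in cm, apex at the origin, long axis +z. The
default dimensions are not free parameters: they are calibrated once, by
a nested scalar root-find (`calibrate_reference_geometry`), so that the
four undeformed reference quantities match the reference configuration
used throughout the study:

| quantity | target | analytic value of defaults |
|---|---|---|
| cavity volume Q_c | 170 cm^3 | 170.000 |
| apical wall thickness Q_l | 1.11 cm | 1.110 |
| basal wall thickness Q_t | 0.699 cm | 0.699 |
| wall volume Q_v | 126 cm^3 | 126.000 |

One degree of freedom remains after the four constraints (the shape of
the cut): the basal plane is fixed 2 cm above the equator, a
physiological choice made a priori for an LV-like silhouette; the
resulting inner apex-base length is 10.1 cm. Discrete (mesh) volumes are
1-2% below the analytic values at the default resolution because the
polyhedral surface is inscribed; this bias converges at second order in
the edge length.

The mesh is a structured (transmural x meridional x circumferential)
grid blended linearly between the two surfaces, tetrahedralized by the
translation-invariant Kuhn subdivision in index space (conforming by
construction, verified by a face-count check); the hexahedra collapsed
at the apex pole become prisms whose degenerate tetrahedra are dropped.
Default resolution (`target_edge_length = 0.88` cm): 21 x 13 x 2 cells,
3150 tetrahedra, 822 vertices. That size was chosen so a nonlinear
inflation solve takes on the order of a second, making the
hundreds-of-solves experiments below practical, while keeping discrete
volumes within 2% of the analytic shell volume.

### Fiber architecture

A harmonic transmural coordinate t (Dirichlet 0/1 on the endo/epi
surfaces, natural condition on the base) is computed with piecewise
linear finite elements. Local wall axes: transmural = normalized
gradient of t (volume-weighted vertex average of cell gradients);
longitudinal = +z projected orthogonal to it; circumferential completes
the right-handed triad. Within a small cylinder around the long axis the
projection degenerates (the circumferential direction has a topological
singularity at the apex), so those vertices copy the longitudinal axis
of their nearest well-defined neighbor and re-orthogonalize; the
substitution count is logged.

The helix angle interpolates linearly in t between alpha_endo = 50 deg
and alpha_epi = -50 deg; the fiber direction f rotates the
circumferential axis by alpha(t) in the circumferential-longitudinal
plane. The sheet axis starts from the transmural direction projected off
f and rotates about f by the transverse angle beta(t), interpolated the
same way between beta_endo = -65 deg and beta_epi = 25 deg (whether the
transverse angle should interpolate linearly is not established; the
same rule as for alpha is the simplest consistent choice and is flagged
here). Angles are validated against (-180, 180]: the (-90, 90] range is
the natural fundamental domain of an unsigned fiber direction, but
random draws of the angle inputs can step slightly past +-90 and the
frame rotation (and the energy, which is even in the fiber sign) remains
well defined there.

With two transmural cell layers the helix angle jumps ~50 deg between
neighboring vertex layers (the 100 deg endo-epi span across three vertex
layers); this is a property of the deliberately coarse default
resolution, not of the assignment rule, and the smoothness test
therefore checks continuity along layers, away from the apex.

### Material and mechanics

Transversely isotropic exponential (Guccione-type) strain energy with a
volumetric penalty:

    Psi(E) = C/2 (exp(W) - 1) + K (J ln J - J + 1)
    W = b_ff E_ff^2 + b_xx (E_ss^2 + E_nn^2 + E_sn^2 + E_ns^2)
        + b_fx (E_fn^2 + E_nf^2 + E_fs^2 + E_sf^2)

with E the Green-Lagrange strain in the local (f, s, n) axes, J = det F.
Defaults (study means): C = 1.1 kPa, b_ff = 6.6, b_xx = 4.0, b_fx = 2.6,
K = 10 kPa. The second Piola-Kirchhoff stress S = dPsi/dE and the
material tangent dP/dF (P = F S) are derived analytically in batched
closed form; both are verified against central finite differences to
1e-6 relative in the tests.

Boundary conditions: follower pressure (normal to the *deformed*
endocardium, the physically standard reading of a normal-stress
condition) rising to 2 kPa, the end-diastolic load; traction-free
epicardium; zero longitudinal displacement on the base; and lumped
in-plane springs of 1 kPa/cm on the basal ring (the quoted "1 kPa"
spring constant is dimensionally incomplete for a surface traction; per
unit displacement and area is the standard completion).

Discretization: continuous piecewise-linear displacement on tetrahedra
with one-point quadrature (F constant per element; fiber triads averaged
from the vertices and re-orthonormalized per element). Loading in 10
equal pressure increments; each step solved by Newton's method with an
analytic consistent tangent, a sparse LU direct solver, backtracking
line search guarding against element inversion, and a secant predictor
across load steps. By default the factorized tangent is reused while the
residual contracts by at least a factor 5 per iteration (chord
iterations) and rebuilt otherwise; `reuse_tangent=False` restores
textbook Newton (the two agree to ~1e-9 in displacement at the 1e-8
relative residual tolerance). Assembly order is deterministic, so
repeated runs are bit-identical.

With K = 10 kPa the penalty is weak: at 2 kPa the element Jacobians span
roughly [0.93, 1.18] and the wall volume grows a few percent. A
thick-walled shell under internal pressure has positive mean stress
(hoop tension of order p r/t against radial stress between -p and 0), so
a net J > 1 is the expected sign at this penalty; the tissue here is
"almost incompressible" only loosely. The property test asserts the
honest band J in (0.8, 1.3) rather than a tight incompressibility band.

### Quantities of interest

Four global scalars characterize the deformed state; all are invariant
under rigid motions appended to the displacement:

- **Q_c, cavity volume** (cm^3): divergence theorem over the deformed
  endocardial surface closed by a triangle fan about the deformed basal
  endocardial centroid (the fan makes the surface watertight).
- **Q_l, apex lengthening** (cm): deformed epicardial minus endocardial
  apex-to-base axial length; the apexes are tracked materially (the
  reference-extremal vertices), avoiding discontinuities under small
  deformations.
- **Q_t, wall thickness at base** (cm): mean deformed epicardial minus
  endocardial radius over the basal rings, measured about the deformed
  basal centroid. (The averaging rule is a choice; the mean over the
  ring vertices is reported.)
- **Q_v, wall volume** (cm^3): integral of J over the reference domain.

Reports use the conventional scales 10^2 cm^3 (Q_c), cm (Q_l), 10^-1 cm
(Q_t), 10 cm^3 (Q_v).

## Uncertainty machinery

### Input model

Nine independent scalar inputs (model A): the five material parameters
(stiffness exponents normal; the positive factors C and K lognormal,
moment-matched so the stated mean and standard deviation are those of
the lognormal itself) and the four fiber angles (normal, coefficient of
variation 0.15). All surrogate construction happens in standardized
normal coordinates xi: normals map affinely, lognormals through their
underlying normal, so the joint density of xi is exactly standard
Gaussian.

### Polynomial chaos by point collocation

Tensorized probabilists' Hermite polynomials He_n/sqrt(n!), restricted
to total degree <= N, enumerated in graded lexicographic order; the
basis is exactly orthonormal under the standardized Gaussian, verified
in tests by Gauss-Hermite quadrature for d <= 3. With d inputs and order
N there are M = (N+d)!/(N! d!) terms. Coefficients are fitted by least
squares at N_s = 2M unscrambled Halton points (bases the first d primes,
sequence starting at index 1, i.e. the first 1-D point is 1/2) mapped
through the inverse normal CDF; the collocation matrix condition number
is recorded and a warning issued above 1e8. N = 2 and N_s = 2M are the
defaults; `calibration_sweep` reproduces the supporting held-out-RMSE
grid over N in {1,..} and N_s in {2M, 3M, 4M}.

Surrogate statistics: mean = leading coefficient and variance = sum of
squared remaining coefficients (exact for the surrogate); the 95%
prediction interval (equal-tail 2.5/97.5 empirical percentiles),
skewness, and excess kurtosis come from seeded Monte Carlo on the
surrogate (default 1e5 samples). The +-1.96 band on skewness and excess
kurtosis is reported as a normality screen. Main and total Sobol indices
are the exact coefficient sums over multi-index subsets (supported only
on input i, and involving input i, respectively); a double-loop Monte
Carlo estimator on the surrogate serves as the independent oracle in
tests.

Quasi-Monte Carlo validation evaluates the forward model directly on the
Halton sequence mapped through the input transform and reports plug-in
moments; failed forward solves are logged and skipped.

### Fiber-angle random field (model B)

Zero-mean Gaussian field with squared-exponential covariance
C(x,y) = sigma_KL^2 exp(-|x-y|^2 / 2 l^2), discretized on mesh vertices
by the Galerkin generalized eigenproblem T phi = lambda M phi, T = MQM,
with the P1 mass matrix M and the dense nodal covariance Q (dense
assembly is exact and affordable at desk scale; a configurable node cap,
default 20 000, guards memory). Small problems use a dense symmetric
generalized eigensolve, larger ones shift-free Lanczos with an M-inner
product; modes are M-orthonormalized and their signs fixed by making the
largest-magnitude entry positive (determinism).

Truncation keeps the smallest n_KL such that the *normalized* pointwise
error variance 1 - sum_{k<=n} lambda_k phi_k(x)^2 / sigma_KL^2 is below
0.05 at >= 92% of vertices. Normalizing by the pointwise variance makes
the criterion independent of sigma_KL — with an absolute threshold the
criterion would be vacuous at sigma_KL = 0.1 rad and binding only at
0.5 rad, whereas a single truncation order per correlation length is the
intended behavior. On the default mesh this yields n_KL = 4, 7, 19 for
l = 10, 5, 3 cm (mesh-converged; the count rises for short correlation
lengths because the elongated idealized shell has a larger surface
extent than a patient ventricle of equal wall volume).

A field sample (independent standard normal coordinates, one scalar
angle field in radians) perturbs the fiber frame by rigidly rotating the
(f, s) pair about the sheet normal n by the local angle. A rigid
rotation preserves orthonormality and handedness exactly, which the
literal vector addition of a perturbation to f would not; the transverse
angle is not perturbed. In model B the nine scalar inputs stay at their
means and the PCE is built in the n_KL field coordinates.

## Problem sizes and determinism

The experiments are sized for a single CPU: model A fits 110 collocation
solves (d = 9, N = 2) plus an optional 250-solve QMC reference, about
ten minutes in total at the default resolution; the model-B cases need
2M(n_KL) solves each (30 at l = 10 cm up to ~420 at l = 3 cm). All
randomness flows from named seeds (surrogate Monte Carlo; the Halton
constructions are deterministic), and a full run reproduces its reports
byte for byte.

## What the synthetic geometry does and does not establish

The truncated-spheroid ventricle reproduces the reference cavity and
wall volumes and the basal/apical thicknesses, and under the 2 kPa load
its responses at mean parameters land close to the reference study
state. It does *not* reproduce patient-specific wall-thickness
heterogeneity, trabeculation, or the irregular basal contour, and its
uniform thin wall concentrates fiber strain more than an image-derived
ventricle would. Variance-based sensitivity conclusions are
load-dependent in this model class: the exponents act on the stress
through b E^2 inside the exponential, so their influence relative to the
multiplicative factor C grows with strain; rankings measured on this
geometry at full load need not transfer to geometries with different
strain distributions, and the acceptance checks report what this
geometry actually yields. Passing tests demonstrate internal correctness
(discretization, surrogate, and sensitivity machinery against
independent oracles) and calibrated reference behavior — not clinical
fidelity.

## Known limitations

- Linear elements with one-point quadrature: mild strain smoothing at
  the default coarse resolution; QoIs change < 2% under refinement.
- The basal Robin springs act on lumped vertex areas (consistent surface
  integration would change basal in-plane stiffness marginally).
- The apex fallback rule makes fiber directions near the pole
  mesh-dependent within a two-edge-length cylinder.
- No active tension, viscoelasticity, contact, mixed u-p formulation, or
  unloaded-state estimation; single ventricle only.
- The KLE uses dense covariance storage; meshes beyond the node cap
  require coarsening rather than hierarchical compression.
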