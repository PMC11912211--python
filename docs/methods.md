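# Methods

## Scope and model

The package implements two coupled components:

1. a generator of atomic auxiliary basis sets (ABS) made of primitive Hermite
   Gaussian function sets with shared, even-tempered exponents (GEN-Xn,
   n ∈ {2, 3, 4}), derived from the primitive exponent structure of an
   orbital basis set (OBS); and
2. a variational density-fitting engine that, for a supplied closed-shell
   density, fits the two-electron Coulomb repulsion and Fock exchange
   energies in that ABS under the Coulomb metric and evaluates the signed
   fitting errors.

No SCF is performed anywhere.  The variational bounds — the fitted Coulomb
energy never exceeds the exact one, the fitted exchange energy never falls
below it — hold *pointwise for every valid density*, so seeded synthetic
densities are sufficient to verify them.  Absolute energies of the fixture
systems are not chemically meaningful; only the bound structure, the working
equation identities, and the relative accuracy ordering of GEN-X2/X3/X4 are.

## Generator

Inputs: the per-angular-momentum primitive exponent ranges
[ζ_min^l, ζ_max^l] of one element's OBS (contractions flattened — only
exponents matter, contraction coefficients are parsed but ignored).

- progression factor: β = 6 − n, so GEN-X2/X3/X4 use β = 4/3/2;
- anchor: α₀ = 2·g, g the geometric mean of the highest-l ("polarization")
  primitive exponents.  With a single polarization primitive this is exactly
  the Gaussian self-product exponent 2ζ; the geometric mean extension is
  scale-covariant and reduces to it;
- ladder: α₀·β^k for consecutive integers k, extended upward until the first
  value ≥ 2ζ_max and downward until the first value ≤ 2ζ_min, both inclusive
  ("fuzzy bounds").  If α₀ already meets a bound, no extension happens on
  that side.  Values are computed as explicit powers, never cumulative
  products, so the even-tempered ratio is exact in floating point and
  exactly testable;
- angularity: each ladder exponent α receives
  L_set(α) = max { min(2l, L_max) : α ∈ [2ζ_min^l, 2ζ_max^l] }, default 0,
  with closed intervals (a zero-width polarization interval is hit exactly
  by α₀).  A coverage-repair pass then guarantees, per l, auxiliary
  functions of angularity ≥ min(2l, L_max) at or beyond both interval edges
  by promoting the nearest bracketing ladder exponents; this matters when a
  product interval is narrower than one ladder step.  Promotions only
  increase angularities, so repairs for different l cannot undo each other;
- L_max defaults to 6 (i functions), even and ≤ 6 by construction; elements
  whose OBS contains only s shells still receive an (all-s) ABS.

## Integral engine

- Cartesian orbital Gaussians up to l = 2 (d), components ordered
  x-major lexicographically (xx, xy, xz, yy, yz, zz); primitive Hermite
  auxiliary Gaussians up to L = 6, triples (t, u, v) ordered by total index
  then lexicographically.  The engine works internally in Cartesian
  components; all bound properties verified here are representation
  independent, and the exact Hermite↔Cartesian span equivalence per total
  index is exercised by a dedicated test.
- Normalization: orbital functions to unit self-overlap per component
  (contraction included); auxiliary functions to unit Coulomb self-repulsion,
  which gives the metric G a unit diagonal and a condition number that
  reflects genuine redundancy rather than scale disparity.  All fitted
  energies are invariant under rescaling of any auxiliary function (tested).
- Boys function: double-factorial series at the highest order with downward
  recursion for T ≤ 35; closed form with upward recursion above (where
  e^{-T} ≤ 6·10⁻¹⁶ and T exceeds every order used).  Verified against the
  40-digit incomplete-gamma closed form to ≤ 10⁻¹³ absolute.
- 2-/3-/4-center repulsion integrals through McMurchie–Davidson Hermite
  expansion (E coefficients) and Hermite Coulomb recursion (R tensor);
  the Hermite auxiliary ket is consumed directly as R-tensor indices — no
  Cartesian transformation step.  Shell-pair E tensors are cached and blocks
  are assembled with einsum contractions.
- Quadrature oracle: the Coulomb repulsion of two analytic
  polynomial-times-Gaussian charge distributions, computed by sampling both
  on a cell-centered grid, zero-padding to twice the box, and contracting
  the discrete Fourier transforms with a spherically truncated Coulomb
  kernel (cutoff = half the padded box, which exactly isolates periodic
  images for charges inside the inscribed sphere).  Grid spacing
  0.24/√(Σα) and extent from the 10⁻¹² Gaussian tail give relative errors
  well below 10⁻⁸ for exponents in roughly [0.3, 3]; a points-per-axis
  budget turns unrepresentable inputs into a diagnostic error.  The code
  path shares nothing with the analytic engine except the function
  definitions themselves.

## Fitting

With G_kl = ⟨k̄‖l̄⟩ and J_k = Σ P_μν ⟨μν‖k̄⟩, the coefficients solve
G x = J and the four fitted Coulomb expressions are evaluated as
E_a = x·J − ½xᵀGx, E_b = ½x·J, E_c = ½xᵀGx, and E_d = ½Σ_k x_k J_k with J
recontracted from the three-center tensor.  E_a is a lower bound of E_H for
arbitrary x; the four expressions coincide at the exact solution (pairwise
≤ 10⁻¹⁰ relative in the acceptance suite).  ε₂ᴴ = E_H − E_a is reported as
the MinMax-style signed error; its positivity certifies the fit.

Fock exchange: for occupied orbitals i, j (S-orthonormal, enforced), pair
vectors J_ij are half-transformed from the three-center tensor; each fitted
pair repulsion J_ijᵀG⁺J_ij is a Coulomb-metric projection bounded by the
exact ⟨ψ_iψ_j‖ψ_iψ_j⟩, so Ẽ_F = −Σ_ij J_ijᵀG⁺J_ij ≥ E_F.  The fit is global
over the full ABS; spatially local fits are a truncation of it and the
global fit is their exact limit, with all bounds intact.  Closed-shell only.

Solvers for G x = J:

- `direct`: Cholesky factorization plus one iterative-refinement pass
  (residual pushed to O(eps·‖G‖‖x‖), which the working-equation equivalence
  tests rely on); raises on numerically indefinite G, pointing to TED;
- `ted`: eigendecomposition, eigenpairs with λ < τ·λ_max dropped
  (default τ = 10⁻⁹ — large enough to remove double-precision noise
  directions of a unit-diagonal metric, small enough not to touch physical
  eigenpairs of the desk-scale fixtures), pseudo-inverse application.
  Because G⁺GG⁺ = G⁺, the identities E_b = E_c and ε₂ᴴ ≥ 0 survive
  truncation;
- `minres`: scipy MINRES to relative residual 10⁻¹⁰ (cap 5·dim iterations),
  unpreconditioned, followed by up to two refinement passes to undo the
  condition-number amplification of the solution error; non-convergence is
  a diagnostic error.

Error statistics: MSE = mean signed error, MAE = mean absolute error,
σ = sample (n−1) standard deviation, γ̄ = mean ratio of auxiliary to orbital
basis functions.

## Synthetic data and fixtures

Densities are drawn as seeded standard-normal coefficient matrices
symmetrically orthogonalized in the overlap metric (P = 2ccᵀ, cᵀSc = 1,
bit-reproducible per seed).  They emulate the algebraic structure of
closed-shell SCF densities — idempotency, correct electron count — but not
their energetic ordering; that is exactly what the pointwise bounds do not
require.

Fixture systems (h2, heh+, h2o_toy, dimer_scan, random_obs) are one- to
three-atom closed-shell systems with uncontracted bases.  Exponent spans
follow production basis sets (hydrogen ~0.16–19 with a p polarization
function; the beryllium dimer ~0.08–1265, four decades), because the span of
the orbital-product interval is what differentiates the GEN-Xn ladders: with
narrow spans the β = 4 and β = 3 ladders contain equally many points and the
X2→X3 accuracy ordering washes out.  h2o_toy uses the documentation toy
s/p/d basis on oxygen.  The "random_obs" fixture draws a seeded random
two-to-four-shell basis inside stated exponent bounds.  What passing tests
show is that the bound structure, equation identities and accuracy ordering
hold under these conditions; they say nothing about absolute fitting errors
of production molecules.

Problem sizes: up to 28 orbital and ~120 auxiliary functions per fixture;
the property suites use 210 seeded densities (5 systems × 3 GEN-Xn levels ×
14 seeds) and a 100-case analytic-vs-quadrature integral comparison, with
geometry-dependent tensors cached per (system, n).

## Numerical choices and degenerate inputs

- Bound checks use a slack of 10⁻¹⁰ relative to the energy scale — pure
  floating-point headroom on exact inequalities.
- Interval membership in the generator is inclusive on both edges; the
  ladder pre-condition requires α₀ ∈ [lo, hi] within 10⁻¹² relative.
- A degenerate metric (duplicated auxiliary function) is handled by TED with
  one dropped eigenpair and keeps ε₂ᴴ ≥ 0; the direct solver refuses it.
- Coincident atoms are rejected at the geometry boundary; zero-width
  exponent ranges (single-primitive shells) are ordinary inputs everywhere.

## Known limitations

- Orbital angular momentum is capped at d in the four-center path (capability
  error beyond); auxiliary angularity at i (L = 6).
- Closed-shell densities only; open shells are out of scope.
- The quadrature oracle needs well-scaled exponents (roughly 0.3–3); very
  tight or very diffuse functions exceed its grid budget by design.
- No integral screening or batching: the engine targets desk-scale
  verification, not production system sizes.
- Spherical-harmonic orbital components are not implemented; results that
  depend only on spans and bounds are unaffected.
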