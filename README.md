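# auxgen

Automatic generation of **even-tempered, shared-exponent primitive Hermite
Gaussian auxiliary basis sets** (GEN-Xn, n = 2, 3, 4) for variational density
fitting, together with a self-contained fitting engine that verifies the
variational error bounds of Coulomb and Fock-exchange fitting on desk-scale
systems.

## Who this is for

Developers and users of density-fitting / resolution-of-the-identity (RI)
electronic-structure methods who need auxiliary basis sets (ABS) matched to an
arbitrary orbital basis set (OBS), and a transparent reference implementation
of the variational fitting equations with which ABS quality can be probed
without running a full SCF program.

## The method

**Generator.** For one element, the GEN-Xn algorithm reads the primitive
exponent ranges ζ of the OBS and builds a geometric exponent ladder

    alpha_k = alpha_0 * beta^k,    beta = 6 - n,

anchored at the self-product of the polarization function,
`alpha_0 = 2 * zeta_pol` (geometric mean when several highest-l primitives
exist), and extended up and down until the orbital-product interval
`[2 zeta_min, 2 zeta_max]` is covered (the terminating values may overshoot —
"fuzzy bounds").  Each ladder exponent receives a set angularity
`L = min(2l, L_max)` from the highest orbital angular momentum l whose product
interval `[2 zeta_min^l, 2 zeta_max^l]` contains it, with a repair pass that
promotes the nearest bracketing exponents whenever a product interval is
narrower than one ladder step, so that for every l

    min(alpha^L) <= 2 min(zeta^l)   and   max(alpha^L) >= 2 max(zeta^l),  L >= 2l.

A set of angularity L holds all (L+1)(L+2)(L+3)/6 Hermite functions with index
0..L on one shared exponent (a d set: 1 s + 3 p + 6 d = 10 functions).

**Fitting.** With the auxiliary Coulomb metric `G_kl = <k||l>` and the
density-contracted three-center vector `J_k = sum P_mn <mn||k>`, the fitted
density solves `G x = J` and the fitted Coulomb energy

    E_a = x.J - 1/2 x.G.x  <=  E_H          (eps2_H = E_H - E_a >= 0)

is a lower bound for *any* x, because the residual
`1/2 <rho - rho~||rho - rho~>` is non-negative in the Coulomb metric.  Fock
exchange is fitted pair density by pair density, giving the mirror bound
`E~_F >= E_F` (eps2_F <= 0).  Ill-conditioned metrics are handled by a
truncated eigendecomposition (TED) or by MINRES; both preserve the bounds.
The integral engine (Boys function, McMurchie–Davidson recurrences, 2-/3-/4-
center repulsion integrals over Cartesian orbital and primitive Hermite
auxiliary functions) is built in, and an independent FFT convolution
quadrature oracle cross-checks every analytic integral class.

## Worked example

```sh
python examples/generate_auxiliary_basis.py
```

prints, for the documentation toy basis (s exponents 0.1 and 50, p exponents
0.5 and 5, d exponent 0.8):

```
GEN-X2: beta=4  alpha0=1.6  6 sets / 67 functions
O GEN-X2 beta=4.0 alpha0=1.6 lmax=6
   1   0                    102.4
   2   2                     25.6
   3   2                      6.4
   4   4                      1.6
   5   2                      0.4
   6   0                      0.1
```

The ladder is anchored at 1.6 = 2 × 0.8 (the d self-product), covers
[0.2, 100] with ratio 4, and the exponent 1.6 carries a g set (L = 4 = 2·2)
because it lies in the d product interval; the 67 functions are
1 + 10 + 10 + 35 + 10 + 1.  `python examples/coulomb_fitting.py` then fits a
synthetic H2 density:

```
exact  E_H = 2.1205574209 hartree
fitted E_a = 2.1129041592
fitted E_b = 2.1129041592
fitted E_c = 2.1129041592
fitted E_d = 2.1129041592
eps2_H     = 7.653e-03  (>= 0: the fit is variational)
```

All four fitted expressions coincide at the solution and the signed error is
positive, as the variational bound demands.  The remaining examples
demonstrate exchange fitting, the three solver strategies and the full
bound-check suite (`auxgen validate --seed 1 --out report.json` from the
shell).

## Layout

- `src/auxgen/basis_io.py` — basis/geometry text formats (Gaussian-style, JSON, XYZ)
- `src/auxgen/generator.py` — the GEN-Xn algorithm
- `src/auxgen/integrals/` — Boys function, McMurchie–Davidson engine, quadrature oracle
- `src/auxgen/fitting.py` — variational Coulomb/exchange fitting and solvers
- `src/auxgen/harness.py` — fixtures, synthetic densities, validation pipeline
- `src/auxgen/cli.py` — `auxgen gen | fit | validate`
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, conventions, numerical choices, limitations
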