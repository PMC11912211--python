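"""Closed forms, symmetries and oracle agreement of the Gaussian integral engine."""

import math

import numpy as np
import pytest

from auxgen.basis_io import (
    AtomicAuxBasis,
    AtomicOrbitalBasis,
    HermiteAuxSet,
    Molecule,
)
from auxgen.integrals import (
    CartesianGaussianSpec,
    HermiteGaussianSpec,
    ProductSpec,
    build_indexed_basis,
    eri_2c,
    eri_2c_primitive,
    eri_3c,
    eri_3c_primitive,
    eri_4c,
    eri_4c_primitive,
    eri_quadrature_oracle,
    hermite_components,
    hermite_expansion,
    hermite_to_cartesian_1d,
    overlap_matrix,
)
from auxgen.integrals.quadrature import QuadratureConvergenceError
from conftest import shell


def hermite_1d(t, alpha, x):
    """Pointwise Lambda_t(x) = (d/dA)^t exp(-alpha x^2) at A = 0."""
    from numpy.polynomial.hermite import hermval

    c = np.zeros(t + 1)
    c[t] = 1.0
    u = math.sqrt(alpha) * x
    return alpha ** (t / 2.0) * hermval(u, c) * np.exp(-u * u)


def tiny_basis(aux_L=2, zetas=(1.0,), alphas=(1.1,), two_atoms=False):
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.4, 1.1]])
    symbols = ("He", "H") if two_atoms else ("He",)
    obs = {
        "He": AtomicOrbitalBasis("He", tuple(shell(l, z) for l, z in enumerate(zetas))),
        "H": AtomicOrbitalBasis("H", (shell(0, 0.8),)),
    }
    aux = {
        "He": AtomicAuxBasis("He", tuple(HermiteAuxSet(a, aux_L) for a in alphas)),
        "H": AtomicAuxBasis("H", (HermiteAuxSet(0.9, 2),)),
    }
    mol = Molecule(symbols, coords[: len(symbols)])
    return build_indexed_basis(mol, obs, aux)


# ---------------------------------------------------------------------------
# Hermite expansion coefficients
# ---------------------------------------------------------------------------


def test_ss_expansion_is_gaussian_product_prefactor():
    z1, z2, AB = 0.8, 1.7, 1.3
    E = hermite_expansion(0, 0, z1, z2, AB)
    mu = z1 * z2 / (z1 + z2)
    assert E[0, 0, 0] == pytest.approx(math.exp(-mu * AB * AB), rel=1e-14)


def test_p_times_s_at_zero_separation_is_pure_first_hermite():
    p = 0.9 + 1.4
    E = hermite_expansion(1, 0, 0.9, 1.4, 0.0)
    assert E[1, 0, 0] == 0.0
    assert E[1, 0, 1] == pytest.approx(1.0 / (2.0 * p))


@pytest.mark.parametrize("l1, l2", [(0, 1), (1, 1), (2, 1), (2, 2)])
def test_expansion_reconstructs_product_on_grid(l1, l2):
    z1, z2, A, B = 1.2, 0.6, 0.35, -0.55
    p = z1 + z2
    P = (z1 * A + z2 * B) / p
    E = hermite_expansion(l1, l2, z1, z2, A - B)
    x = np.linspace(-4.0, 4.0, 201)
    product = (x - A) ** l1 * (x - B) ** l2 * np.exp(-z1 * (x - A) ** 2 - z2 * (x - B) ** 2)
    recon = sum(E[l1, l2, t] * hermite_1d(t, p, x - P) for t in range(l1 + l2 + 1))
    assert np.max(np.abs(recon - product)) <= 1e-10


def test_hermite_to_cartesian_on_grid():
    alpha = 0.85
    C = hermite_to_cartesian_1d(2, alpha)
    x = np.linspace(-4.0, 4.0, 101)
    for n in range(3):
        target = x**n * np.exp(-alpha * x * x)
        recon = sum(C[n, t] * hermite_1d(t, alpha, x) for t in range(n + 1))
        assert np.max(np.abs(recon - target)) <= 1e-12


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------


def test_overlap_single_normalized_s():
    S = overlap_matrix(tiny_basis(zetas=(1.0,)))
    assert S == pytest.approx(np.array([[1.0]]), abs=1e-14)


def test_overlap_two_s_at_unit_distance():
    obs = {"H": AtomicOrbitalBasis("H", (shell(0, 1.0),))}
    aux = {"H": AtomicAuxBasis("H", (HermiteAuxSet(1.0, 0),))}
    mol = Molecule(("H", "H"), np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]]))
    S = overlap_matrix(build_indexed_basis(mol, obs, aux))
    assert S[0, 1] == pytest.approx(0.6065307, abs=1e-7)


def test_overlap_positive_definite():
    basis = tiny_basis(zetas=(1.3, 0.5, 0.9), two_atoms=True)
    w = np.linalg.eigvalsh(overlap_matrix(basis))
    assert w.min() > 0.0
    assert np.allclose(np.diag(overlap_matrix(basis)), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# 2-/3-/4-center repulsion
# ---------------------------------------------------------------------------


def test_2c_same_center_unit_exponent_is_4pi():
    raw = eri_2c_primitive(1.0, np.zeros(3), (0, 0, 0), 1.0, np.zeros(3), (0, 0, 0))
    N2 = (2.0 / math.pi) ** 1.5  # two overlap-normalized s factors
    assert raw * N2 == pytest.approx(4.0 * math.pi, rel=1e-13)


def test_2c_symmetry_random_parameters():
    rng = np.random.default_rng(2)
    for _ in range(5):
        a, b = rng.uniform(0.4, 2.0, 2)
        A, B = rng.uniform(-1, 1, (2, 3))
        ta = tuple(rng.integers(0, 2, 3))
        tb = tuple(rng.integers(0, 2, 3))
        v1 = eri_2c_primitive(a, A, ta, b, B, tb)
        v2 = eri_2c_primitive(b, B, tb, a, A, ta)
        assert v1 == pytest.approx(v2, rel=1e-12, abs=1e-14)


def test_2c_long_range_coulomb_tail():
    # normalized s-s repulsion approaches Q1 Q2 / R monotonically from below
    a, b = 1.0, 0.7
    Qa = (math.pi / a) ** 1.5
    Qb = (math.pi / b) ** 1.5
    prev = None
    for R in (3.0, 5.0, 8.0, 14.0):
        v = eri_2c_primitive(a, np.zeros(3), (0, 0, 0), b, np.array([0, 0, R]), (0, 0, 0))
        if prev is not None:
            assert v < prev
        prev = v
        assert v <= Qa * Qb / R + 1e-12
    assert prev == pytest.approx(Qa * Qb / 14.0, rel=1e-10)


def test_G_unit_diagonal_and_psd():
    basis = tiny_basis(aux_L=4, alphas=(2.0, 0.5), two_atoms=True)
    G = eri_2c(basis)
    assert np.allclose(np.diag(G), 1.0, atol=1e-12)
    assert np.allclose(G, G.T, atol=1e-14)
    w = np.linalg.eigvalsh(G)
    assert w.min() >= -1e-10 * w.max()


def test_G_duplicated_function_degenerate():
    obs = {"H": AtomicOrbitalBasis("H", (shell(0, 1.0),))}
    aux = {"H": AtomicAuxBasis("H", (HermiteAuxSet(1.0, 0),))}
    # two coincident atoms are rejected, so emulate degeneracy with a tiny offset
    mol = Molecule(("H", "H"), np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1e-7]]))
    G = eri_2c(build_indexed_basis(mol, obs, aux))
    w = np.linalg.eigvalsh(G)
    assert w[-1] == pytest.approx(2.0, abs=1e-6)
    assert abs(w[0]) <= 1e-6


def test_3c_closed_form_coincident_s():
    basis = tiny_basis(zetas=(1.0,), alphas=(1.0,), aux_L=0)
    T3 = eri_3c(basis)
    N2 = (2.0 / math.pi) ** 1.5
    Na = 1.0 / math.sqrt(2.0 * math.pi**2.5 / math.sqrt(2.0))
    expected = 2.0 * math.pi**2.5 * N2 * Na / (2.0 * math.sqrt(3.0))
    assert T3[0, 0, 0] == pytest.approx(expected, rel=1e-13)


def test_3c_bra_symmetry():
    basis = tiny_basis(zetas=(1.3, 0.5, 0.9), aux_L=4, two_atoms=True)
    T3 = eri_3c(basis)
    assert np.max(np.abs(T3 - T3.transpose(1, 0, 2))) <= 1e-13


def test_4c_closed_form_ssss():
    basis = tiny_basis(zetas=(1.0,))
    T4 = eri_4c(basis)
    assert T4[0, 0, 0, 0] == pytest.approx(2.0 / math.sqrt(math.pi), rel=1e-13)


def test_4c_eightfold_symmetry_and_psd():
    basis = tiny_basis(zetas=(1.3, 0.5, 0.9), two_atoms=True)
    T4 = eri_4c(basis)
    for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1), (3, 2, 1, 0)]:
        assert np.max(np.abs(T4 - T4.transpose(perm))) <= 1e-12
    n = basis.nao
    w = np.linalg.eigvalsh(T4.reshape(n * n, n * n))
    assert w.min() >= -1e-10 * w.max()


def test_4c_capability_ceiling():
    obs = {"H": AtomicOrbitalBasis("H", (shell(3, 1.0),))}
    aux = {"H": AtomicAuxBasis("H", (HermiteAuxSet(1.0, 0),))}
    mol = Molecule(("H",), np.zeros((1, 3)))
    with pytest.raises(NotImplementedError):
        eri_4c(build_indexed_basis(mol, obs, aux))


def test_translational_invariance():
    shift = np.array([1.7, -2.3, 0.9])
    b1 = tiny_basis(zetas=(1.3, 0.5, 0.9), aux_L=2, two_atoms=True)
    coords = b1.molecule.coordinates + shift
    mol2 = Molecule(b1.molecule.symbols, coords)
    obs = {
        "He": AtomicOrbitalBasis("He", tuple(shell(l, z) for l, z in enumerate((1.3, 0.5, 0.9)))),
        "H": AtomicOrbitalBasis("H", (shell(0, 0.8),)),
    }
    aux = {
        "He": AtomicAuxBasis("He", (HermiteAuxSet(1.1, 2),)),
        "H": AtomicAuxBasis("H", (HermiteAuxSet(0.9, 2),)),
    }
    b2 = build_indexed_basis(mol2, obs, aux)
    for f in (overlap_matrix, eri_2c, eri_3c, eri_4c):
        t1, t2 = f(b1), f(b2)
        scale = np.max(np.abs(t1))
        assert np.max(np.abs(t1 - t2)) <= 1e-10 * scale


# ---------------------------------------------------------------------------
# quadrature oracle
# ---------------------------------------------------------------------------


def test_oracle_reproduces_closed_form():
    spec = HermiteGaussianSpec((0.0, 0.0, 0.0), 1.0)
    raw = eri_2c_primitive(1.0, np.zeros(3), (0, 0, 0), 1.0, np.zeros(3), (0, 0, 0))
    assert eri_quadrature_oracle(spec, spec) == pytest.approx(raw, rel=1e-8)


def test_oracle_swap_symmetric_and_bilinear():
    f = HermiteGaussianSpec((0.2, 0.0, -0.3), 1.1, (1, 0, 1))
    g = CartesianGaussianSpec((0.0, 0.5, 0.4), 0.8, (0, 2, 0))
    v = eri_quadrature_oracle(f, g)
    assert eri_quadrature_oracle(g, f) == pytest.approx(v, rel=1e-10)
    f3 = HermiteGaussianSpec((0.2, 0.0, -0.3), 1.1, (1, 0, 1), coefficient=3.0)
    assert eri_quadrature_oracle(f3, g) == pytest.approx(3.0 * v, rel=1e-10)
    g3 = CartesianGaussianSpec((0.0, 0.5, 0.4), 0.8, (0, 2, 0), coefficient=3.0)
    assert eri_quadrature_oracle(f3, g3) == pytest.approx(9.0 * v, rel=1e-10)


def test_oracle_budget_error():
    f = HermiteGaussianSpec((0.0, 0.0, 0.0), 1e4)
    g = HermiteGaussianSpec((0.0, 0.0, 0.0), 1e-3)
    with pytest.raises(QuadratureConvergenceError):
        eri_quadrature_oracle(f, g, max_points=64)


def test_random_spd_cases_match_oracle():
    rng = np.random.default_rng(11)
    for _ in range(4):
        z1, z2, alpha = rng.uniform(0.5, 1.6, 3)
        A, B, C = rng.uniform(-0.8, 0.8, (3, 3))
        p1 = tuple(int(v) for v in rng.integers(0, 2, 3))
        p2 = tuple(int(v) for v in rng.integers(0, 3, 3))
        tuv = tuple(int(v) for v in rng.integers(0, 2, 3))
        ana = eri_3c_primitive(z1, A, p1, z2, B, p2, alpha, C, tuv)
        num = eri_quadrature_oracle(
            ProductSpec(
                CartesianGaussianSpec(tuple(A), z1, p1),
                CartesianGaussianSpec(tuple(B), z2, p2),
            ),
            HermiteGaussianSpec(tuple(C), alpha, tuv),
        )
        assert ana == pytest.approx(num, rel=1e-8, abs=1e-10)
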