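"""Solver behavior and the variational structure of the Coulomb/exchange fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from auxgen.basis_io import (
    AtomicAuxBasis,
    AtomicOrbitalBasis,
    HermiteAuxSet,
    Molecule,
)
from auxgen.fitting import (
    DensityState,
    assemble_J,
    coulomb_energies,
    error_metrics,
    exchange_fit,
    solve_fit,
)
from auxgen.integrals import (
    build_indexed_basis,
    eri_2c,
    eri_3c,
    eri_4c,
    overlap_matrix,
)
from auxgen.harness import random_density
from conftest import shell


def _system(zetas=(1.3, 0.5), aux_sets=((2.0, 2), (0.6, 2)), two_atoms=True):
    obs = {"He": AtomicOrbitalBasis("He", tuple(shell(0, z) for z in zetas))}
    aux = {"He": AtomicAuxBasis("He", tuple(HermiteAuxSet(a, L) for a, L in aux_sets))}
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.8]])
    mol = Molecule(("He", "He") if two_atoms else ("He",), coords[: 2 if two_atoms else 1])
    basis = build_indexed_basis(mol, obs, aux)
    return basis, overlap_matrix(basis), eri_2c(basis), eri_3c(basis), eri_4c(basis)


# ---------------------------------------------------------------------------
# linear solvers
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("method", ["direct", "ted", "minres"])
def test_identity_metric_all_methods(method):
    sol = solve_fit(np.eye(2), np.array([1.0, 2.0]), method=method)
    assert sol.x == pytest.approx([1.0, 2.0], abs=1e-12)


def test_ted_drops_null_direction():
    G = np.diag([4.0, 1e-14])
    sol = solve_fit(G, np.array([2.0, 1.0]), method="ted")
    assert sol.x == pytest.approx([0.5, 0.0], abs=1e-12)
    assert sol.dropped == 1


def test_methods_agree_on_spd():
    rng = np.random.default_rng(7)
    A = rng.standard_normal((30, 30))
    G = A @ A.T + 30 * np.eye(30)
    J = rng.standard_normal(30)
    x_direct = solve_fit(G, J, method="direct").x
    x_ted = solve_fit(G, J, method="ted").x
    x_minres = solve_fit(G, J, method="minres").x
    ref = np.linalg.norm(x_direct)
    assert np.linalg.norm(x_ted - x_direct) <= 1e-8 * ref
    assert np.linalg.norm(x_minres - x_direct) <= 1e-8 * ref


def test_direct_rejects_indefinite_advising_ted():
    G = np.diag([1.0, -1.0])
    with pytest.raises(np.linalg.LinAlgError, match="ted"):
        solve_fit(G, np.array([1.0, 1.0]), method="direct")


def test_solver_shape_validation():
    with pytest.raises(ValueError):
        solve_fit(np.eye(3), np.ones(2))
    with pytest.raises(ValueError):
        solve_fit(np.eye(2), np.ones(2), method="lu")


# ---------------------------------------------------------------------------
# Coulomb fitting
# ---------------------------------------------------------------------------


def test_assemble_J_zero_density_and_linearity():
    basis, S, G, T3, T4 = _system()
    rng = np.random.default_rng(0)
    P1 = rng.standard_normal((basis.nao, basis.nao))
    P1 = P1 + P1.T
    P2 = rng.standard_normal((basis.nao, basis.nao))
    P2 = P2 + P2.T
    assert np.all(assemble_J(np.zeros_like(P1), T3) == 0.0)
    assert assemble_J(P1 + P2, T3) == pytest.approx(
        assemble_J(P1, T3) + assemble_J(P2, T3)
    )
    with pytest.raises(ValueError):
        assemble_J(np.zeros((3, 3)), T3)


def test_assemble_J_h_like_toy():
    # one s AO (zeta=1) and one s aux (alpha=1) on one center, P = [[2]]
    obs = {"H": AtomicOrbitalBasis("H", (shell(0, 1.0),))}
    aux = {"H": AtomicAuxBasis("H", (HermiteAuxSet(1.0, 0),))}
    mol = Molecule(("H",), np.zeros((1, 3)))
    basis = build_indexed_basis(mol, obs, aux)
    T3 = eri_3c(basis)
    J = assemble_J(np.array([[2.0]]), T3)
    N2 = (2.0 / math.pi) ** 1.5
    Na = 1.0 / math.sqrt(2.0 * math.pi**2.5 / math.sqrt(2.0))
    assert J[0] == pytest.approx(2.0 * 2.0 * math.pi**2.5 * N2 * Na / (2 * math.sqrt(3)))


def test_exact_span_limit_coulomb():
    # a single s orbital whose self-product (exponent 2 zeta) is in the aux set
    obs = {"H": AtomicOrbitalBasis("H", (shell(0, 1.0),))}
    aux = {"H": AtomicAuxBasis("H", (HermiteAuxSet(2.0, 0),))}
    mol = Molecule(("H",), np.zeros((1, 3)))
    basis = build_indexed_basis(mol, obs, aux)
    S, G, T3, T4 = overlap_matrix(basis), eri_2c(basis), eri_3c(basis), eri_4c(basis)
    P = np.array([[2.0]])
    J = assemble_J(P, T3)
    sol = solve_fit(G, J, method="direct")
    res = coulomb_energies(P, sol.x, G, J, T4, T3, solution=sol)
    assert abs(res.eps2_H) <= 1e-10 * abs(res.E_H)
    for E in (res.E_a, res.E_b, res.E_c, res.E_d):
        assert E == pytest.approx(res.E_H, rel=1e-10)


def test_lower_bound_holds_for_arbitrary_coefficients():
    # E_a is a lower bound of E_H for ANY coefficient vector, not just solutions
    basis, S, G, T3, T4 = _system()
    rng = np.random.default_rng(5)
    d = random_density(S, 2, 9)
    J = assemble_J(d.P, T3)
    for _ in range(20):
        x = rng.standard_normal(basis.naux)
        res = coulomb_energies(d.P, x, G, J, T4, T3)
        assert res.eps2_H >= -1e-10 * abs(res.E_H)


def test_nested_aux_monotonicity():
    # adding a set to the auxiliary basis can only lower eps2_H
    obs = {"He": AtomicOrbitalBasis("He", (shell(0, 1.3), shell(0, 0.5)))}
    small = {"He": AtomicAuxBasis("He", (HermiteAuxSet(2.0, 2),))}
    big = {
        "He": AtomicAuxBasis(
            "He", (HermiteAuxSet(2.0, 2), HermiteAuxSet(0.67, 2))
        )
    }
    mol = Molecule(("He", "He"), np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.8]]))
    eps = {}
    for tag, aux in (("small", small), ("big", big)):
        basis = build_indexed_basis(mol, obs, aux)
        S, G, T3, T4 = overlap_matrix(basis), eri_2c(basis), eri_3c(basis), eri_4c(basis)
        d = random_density(S, 2, 31)
        J = assemble_J(d.P, T3)
        sol = solve_fit(G, J, method="ted")
        eps[tag] = coulomb_energies(d.P, sol.x, G, J, T4, T3).eps2_H
    assert eps["big"] <= eps["small"] + 1e-12


def test_normalization_invariance():
    # rescaling an auxiliary function leaves all fitted energies unchanged
    basis, S, G, T3, T4 = _system()
    d = random_density(S, 2, 3)
    J = assemble_J(d.P, T3)
    sol = solve_fit(G, J, method="direct")
    ref = coulomb_energies(d.P, sol.x, G, J, T4, T3)
    scale = np.ones(basis.naux)
    scale[4] = 7.5
    G2 = G * np.outer(scale, scale)
    T3_2 = T3 * scale
    J2 = assemble_J(d.P, T3_2)
    sol2 = solve_fit(G2, J2, method="direct")
    res2 = coulomb_energies(d.P, sol2.x, G2, J2, T4, T3_2)
    for a, b in [(ref.E_a, res2.E_a), (ref.E_H, res2.E_H), (ref.eps2_H, res2.eps2_H)]:
        assert b == pytest.approx(a, rel=1e-10, abs=1e-12)
    x2 = exchange_fit(d.c, T3, G, T4, S, method="ted")
    x2b = exchange_fit(d.c, T3_2, G2, T4, S, method="ted")
    assert x2b.E_F_fitted == pytest.approx(x2.E_F_fitted, rel=1e-10)


# ---------------------------------------------------------------------------
# exchange fitting
# ---------------------------------------------------------------------------


def test_exact_span_limit_exchange():
    obs = {"H": AtomicOrbitalBasis("H", (shell(0, 1.0),))}
    aux = {"H": AtomicAuxBasis("H", (HermiteAuxSet(2.0, 0),))}
    mol = Molecule(("H",), np.zeros((1, 3)))
    basis = build_indexed_basis(mol, obs, aux)
    S, G, T3, T4 = overlap_matrix(basis), eri_2c(basis), eri_3c(basis), eri_4c(basis)
    c = np.array([[1.0]])
    res = exchange_fit(c, T3, G, T4, S)
    assert res.pair_fitted[0, 0] == pytest.approx(res.pair_exact[0, 0], rel=1e-12)
    assert abs(res.eps2_F) <= 1e-12


def test_pairwise_bounds_and_sign():
    basis, S, G, T3, T4 = _system(zetas=(1.6, 0.9, 0.4), aux_sets=((2.4, 2), (0.8, 0)))
    for seed in range(6):
        d = random_density(S, 2, seed)
        res = exchange_fit(d.c, T3, G, T4, S, method="ted")
        slack = 1e-10 * max(abs(res.E_F), 1.0)
        assert np.all(res.pair_fitted <= res.pair_exact + slack)
        assert res.E_F_fitted >= res.E_F - slack
        assert res.eps2_F <= slack


def test_exchange_requires_orthonormal_orbitals():
    basis, S, G, T3, T4 = _system()
    c = np.ones((basis.nao, 1))  # not S-orthonormal
    with pytest.raises(ValueError):
        exchange_fit(c, T3, G, T4, S)


def test_density_state_validation():
    basis, S, G, T3, T4 = _system()
    d = random_density(S, 2, 0)
    d.validate(S)
    bad = DensityState(P=d.P * 1.01, c=d.c, n_electrons=d.n_electrons)
    with pytest.raises(ValueError):
        bad.validate(S)


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------


def test_error_metrics_examples():
    m = error_metrics([-1.0, 1.0], [2.0, 4.0])
    assert m.MSE == 0.0 and m.MAE == 1.0 and m.gamma_bar == 3.0
    m2 = error_metrics([0.04, 0.04])
    assert m2.MSE == pytest.approx(0.04) and m2.MAE == pytest.approx(0.04)
    assert m2.sigma == 0.0
    with pytest.raises(ValueError):
        error_metrics([])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=30))
def test_mae_bounds_mse(deltas):
    m = error_metrics(deltas)
    assert m.MAE >= abs(m.MSE) - 1e-12
    assert m.sigma >= 0.0
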