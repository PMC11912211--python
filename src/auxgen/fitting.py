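"""Variational density fitting of Coulomb and Fock-exchange energies.

Given a closed-shell density, the fitted density rho~ = sum_k x_k abar_k is
determined by minimizing the Coulomb-metric residual
    eps2_H = 1/2 <rho - rho~ || rho - rho~> >= 0,
which leads to the linear system G x = J with G the auxiliary Coulomb metric
and J the density-contracted three-center vector.  The positive
semidefiniteness of the metric makes the fitted Coulomb energy a lower bound
(eps2_H >= 0) for *any* coefficient vector, so regularized solves keep the
variational property.  Fock exchange is fitted pair-density by pair-density:
each occupied orbital product rho_ij is expanded in the same auxiliary basis,
its fitted self-repulsion J_ij^T G^+ J_ij never exceeds the exact one, and the
fitted exchange energy is an upper bound (eps2_F = E_F - E~_F <= 0).

Three solver strategies address the possible ill-conditioning of G: a direct
symmetric factorization, a truncated eigendecomposition (TED) discarding
near-null eigenpairs, and the Krylov method MINRES.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.sparse.linalg import minres as _minres

__all__ = [
    "DensityState",
    "FitSolution",
    "CoulombFitResult",
    "ExchangeFitResult",
    "ErrorMetrics",
    "assemble_G",
    "assemble_J",
    "solve_fit",
    "coulomb_energies",
    "exchange_fit",
    "error_metrics",
]

#: default relative eigenvalue threshold of the truncated eigendecomposition
TED_THRESHOLD = 1e-9


@dataclass(frozen=True)
class DensityState:
    """Closed-shell density: P = 2 c c^T with S-orthonormal occupied coefficients."""

    P: np.ndarray
    c: np.ndarray
    n_electrons: int

    @classmethod
    def from_coefficients(cls, c: np.ndarray) -> "DensityState":
        c = np.asarray(c, dtype=float)
        return cls(P=2.0 * c @ c.T, c=c, n_electrons=2 * c.shape[1])

    def validate(self, S: np.ndarray, tol: float = 1e-8) -> None:
        n_occ = self.c.shape[1]
        if self.n_electrons != 2 * n_occ:
            raise ValueError("electron count must equal twice the occupied orbitals")
        if np.max(np.abs(self.c.T @ S @ self.c - np.eye(n_occ))) > tol:
            raise ValueError("occupied coefficients are not S-orthonormal")
        if np.max(np.abs(self.P - 2.0 * self.c @ self.c.T)) > tol:
            raise ValueError("P does not equal 2 c c^T")


@dataclass
class FitSolution:
    """Fitting coefficients with solver diagnostics."""

    x: np.ndarray
    method: str
    dropped: int = 0
    iterations: int = 0
    residual: float = 0.0


@dataclass
class CoulombFitResult:
    """Variational Coulomb fit: coefficients, the four fitted energies and eps2_H.

    ``E_a = x.J - 1/2 x.G.x`` is the variational expression (a lower bound for
    any x); ``E_b = 1/2 x.J``, ``E_c = 1/2 x.G.x`` and ``E_d`` (recontracted
    from fresh three-center integrals) coincide with it at the exact solution.
    ``eps2_H = E_H - E_a >= 0`` is the MinMax-style signed fitting error.
    """

    x: np.ndarray
    G: np.ndarray = field(repr=False)
    J: np.ndarray = field(repr=False)
    E_a: float = 0.0
    E_b: float = 0.0
    E_c: float = 0.0
    E_d: float = 0.0
    E_H: float = 0.0
    eps2_H: float = 0.0
    solution: FitSolution | None = None


@dataclass
class ExchangeFitResult:
    """Variational exchange fit: per-pair repulsions, energies and eps2_F <= 0."""

    pair_fitted: np.ndarray
    pair_exact: np.ndarray
    E_F_fitted: float
    E_F: float
    eps2_F: float
    solution: FitSolution | None = None


@dataclass(frozen=True)
class ErrorMetrics:
    """Suite-level signed-error statistics: MSE, MAE, sigma and mean gamma."""

    MSE: float
    MAE: float
    sigma: float
    gamma_bar: float
    count: int


def assemble_G(basis) -> np.ndarray:
    """Auxiliary Coulomb metric matrix G (unit diagonal, formally PSD)."""
    from .integrals import eri_2c

    return eri_2c(basis)


def assemble_J(P: np.ndarray, eri3c: np.ndarray) -> np.ndarray:
    """Coulomb vector J_k = sum_{mu nu} P_{mu nu} <mu nu || k-bar>."""
    P = np.asarray(P)
    if eri3c.shape[:2] != P.shape:
        raise ValueError(
            f"dimension mismatch: P is {P.shape}, 3c tensor is {eri3c.shape[:2]}"
        )
    return np.einsum("mnk,mn->k", eri3c, P)


def solve_fit(
    G: np.ndarray,
    J: np.ndarray,
    method: str = "direct",
    ted_threshold: float = TED_THRESHOLD,
    minres_rtol: float = 1e-10,
) -> FitSolution:
    """Solve the fitting system G x = J.

    ``direct``  -- Cholesky factorization with one step of iterative
                   refinement; requires numerically positive definite G.
    ``ted``     -- eigendecomposition of G, eigenpairs below
                   ``ted_threshold * lambda_max`` discarded, pseudo-inverse
                   application; guarantees a non-negative MinMax error even on
                   (near-)singular metrics.
    ``minres``  -- Krylov iteration to relative residual ``minres_rtol``
                   within 5 * dim iterations.
    """
    G = np.asarray(G, dtype=float)
    J = np.asarray(J, dtype=float)
    if G.shape[0] != G.shape[1] or G.shape[0] != J.shape[0]:
        raise ValueError("G must be square and conformable with J")
    norm_J = np.linalg.norm(J)
    if method == "direct":
        try:
            cf = sla.cho_factor(G, lower=True)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "Coulomb metric is numerically indefinite; use method='ted'"
            ) from exc
        x = sla.cho_solve(cf, J)
        # one refinement pass pushes the residual to O(eps * |G||x|)
        r = J - G @ x
        x = x + sla.cho_solve(cf, r)
        res = float(np.linalg.norm(J - G @ x))
        return FitSolution(x=x, method="direct", residual=res)
    if method == "ted":
        w, V = np.linalg.eigh(G)
        lam_max = float(w[-1])
        keep = w > ted_threshold * lam_max
        Vk = V[:, keep]
        x = Vk @ ((Vk.T @ J) / w[keep])
        res = float(np.linalg.norm(J - G @ x))
        return FitSolution(
            x=x, method="ted", dropped=int((~keep).sum()), residual=res
        )
    if method == "minres":
        it = 0

        def _count(_):
            nonlocal it
            it += 1

        x, info = _minres(
            G, J, rtol=minres_rtol, maxiter=5 * G.shape[0], callback=_count
        )
        # refinement passes counter ill-conditioning of G
        for _ in range(2):
            r = J - G @ x
            if np.linalg.norm(r) <= 1e-13 * max(norm_J, 1.0):
                break
            d, info = _minres(
                G, r, rtol=minres_rtol, maxiter=5 * G.shape[0], callback=_count
            )
            x = x + d
        res = float(np.linalg.norm(J - G @ x))
        if info != 0 and res > 1e-8 * max(norm_J, 1.0):
            raise RuntimeError(
                f"MINRES did not converge: info={info}, residual={res:.3e}"
            )
        return FitSolution(x=x, method="minres", iterations=it, residual=res)
    raise ValueError(f"unknown solver method {method!r}")


def coulomb_energies(
    P: np.ndarray,
    x: np.ndarray,
    G: np.ndarray,
    J: np.ndarray,
    eri4c: np.ndarray,
    eri3c: np.ndarray,
    solution: FitSolution | None = None,
) -> CoulombFitResult:
    """Exact and fitted two-electron Coulomb repulsion energies.

    E_H = 1/2 sum P P <mu nu || lambda sigma>; the four fitted expressions are
    algebraically equivalent at the solution of G x = J, and E_a is a lower
    bound of E_H for any x.
    """
    E_H = 0.5 * float(np.einsum("mn,ls,mnls->", P, P, eri4c, optimize=True))
    xGx = float(x @ G @ x)
    xJ = float(x @ J)
    E_a = xJ - 0.5 * xGx
    E_b = 0.5 * xJ
    E_c = 0.5 * xGx
    # E_d from a fresh contraction of the three-center tensor
    E_d = 0.5 * float(x @ np.einsum("mnk,mn->k", eri3c, P))
    return CoulombFitResult(
        x=x, G=G, J=J, E_a=E_a, E_b=E_b, E_c=E_c, E_d=E_d,
        E_H=E_H, eps2_H=E_H - E_a, solution=solution,
    )


def exchange_fit(
    c_occ: np.ndarray,
    eri3c: np.ndarray,
    G: np.ndarray,
    eri4c: np.ndarray,
    S: np.ndarray,
    method: str = "ted",
    ted_threshold: float = TED_THRESHOLD,
    minres_rtol: float = 1e-10,
) -> ExchangeFitResult:
    """Variational fit of the closed-shell Fock exchange energy.

    Every occupied orbital pair density rho_ij is expanded in the full
    auxiliary basis (a global fit; spatially restricted local fits are its
    truncation).  E_F = -sum_ij <psi_i psi_j || psi_i psi_j>; each fitted pair
    repulsion J_ij^T G^+ J_ij is bounded by the exact one, so the fitted
    exchange energy lies above E_F and eps2_F = E_F - E~_F <= 0.
    """
    c_occ = np.asarray(c_occ, dtype=float)
    n_occ = c_occ.shape[1]
    if np.max(np.abs(c_occ.T @ S @ c_occ - np.eye(n_occ))) > 1e-8:
        raise ValueError("occupied orbital coefficients are not S-orthonormal")
    # half transforms: T[i, j, k] = <psi_i psi_j || k-bar>
    T = np.einsum("mnk,mi,nj->ijk", eri3c, c_occ, c_occ, optimize=True)
    # exact pair repulsions from the 4c tensor
    mo4 = np.einsum(
        "mnls,mi,nj,li,sj->ij", eri4c, c_occ, c_occ, c_occ, c_occ, optimize=True
    )
    # fitted pair repulsions via one solve per pair (shared factorization)
    Jmat = T.reshape(n_occ * n_occ, -1).T  # (naux, n_pairs)
    if method == "ted":
        w, V = np.linalg.eigh(G)
        keep = w > ted_threshold * float(w[-1])
        proj = (V[:, keep].T @ Jmat) / np.sqrt(w[keep])[:, None]
        fitted = np.sum(proj * proj, axis=0).reshape(n_occ, n_occ)
        sol = FitSolution(x=np.empty(0), method="ted", dropped=int((~keep).sum()))
    else:
        fitted = np.empty((n_occ, n_occ))
        sol = None
        for i in range(n_occ):
            for j in range(n_occ):
                s = solve_fit(
                    G, T[i, j], method=method,
                    ted_threshold=ted_threshold, minres_rtol=minres_rtol,
                )
                fitted[i, j] = float(T[i, j] @ s.x)
                sol = s
    E_F = -float(np.sum(mo4))
    E_F_fitted = -float(np.sum(fitted))
    return ExchangeFitResult(
        pair_fitted=fitted,
        pair_exact=mo4,
        E_F_fitted=E_F_fitted,
        E_F=E_F,
        eps2_F=E_F - E_F_fitted,
        solution=sol,
    )


def error_metrics(deltas, gammas=None) -> ErrorMetrics:
    """MSE, MAE, sample standard deviation and mean auxiliary/basis ratio."""
    deltas = np.asarray(list(deltas), dtype=float)
    if deltas.size == 0:
        raise ValueError("error_metrics needs at least one value")
    gam = np.asarray(list(gammas), dtype=float) if gammas is not None else np.array([])
    sigma = float(np.std(deltas, ddof=1)) if deltas.size > 1 else 0.0
    return ErrorMetrics(
        MSE=float(np.mean(deltas)),
        MAE=float(np.mean(np.abs(deltas))),
        sigma=sigma,
        gamma_bar=float(np.mean(gam)) if gam.size else float("nan"),
        count=int(deltas.size),
    )
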