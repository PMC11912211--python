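"""McMurchie-Davidson recurrences.

``hermite_expansion`` builds the E_t^{ij} coefficients that expand a 1D product
of two Cartesian Gaussians into Hermite Gaussians at the composite center;
``hermite_coulomb`` builds the R_{tuv} auxiliary Hermite Coulomb integrals from
the Boys function.  Both follow the standard recurrences.
"""

from __future__ import annotations

import math

import numpy as np

from .boys import boys_array

__all__ = ["hermite_expansion", "hermite_coulomb"]


def hermite_expansion(l1: int, l2: int, zeta1: float, zeta2: float, AB: float) -> np.ndarray:
    """Hermite expansion coefficients E[i, j, t] for one Cartesian direction.

    x_A^i x_B^j exp(-zeta1 x_A^2) exp(-zeta2 x_B^2)
        = sum_t E[i, j, t] Lambda_t(x_P; p),
    with p = zeta1 + zeta2, P the composite center and Lambda_t the t-th
    Hermite Gaussian (derivative of exp(-p x_P^2) with respect to P).
    ``AB`` is the separation A - B along this direction.
    """
    p = zeta1 + zeta2
    mu = zeta1 * zeta2 / p
    PA = -zeta2 / p * AB
    PB = zeta1 / p * AB
    E = np.zeros((l1 + 1, l2 + 1, l1 + l2 + 2))  # one slot of padding in t
    E[0, 0, 0] = math.exp(-mu * AB * AB)
    for i in range(1, l1 + 1):
        for t in range(i + 1):
            E[i, 0, t] = (
                (E[i - 1, 0, t - 1] / (2 * p) if t > 0 else 0.0)
                + PA * E[i - 1, 0, t]
                + (t + 1) * E[i - 1, 0, t + 1]
            )
    for j in range(1, l2 + 1):
        for i in range(l1 + 1):
            for t in range(i + j + 1):
                E[i, j, t] = (
                    (E[i, j - 1, t - 1] / (2 * p) if t > 0 else 0.0)
                    + PB * E[i, j - 1, t]
                    + (t + 1) * E[i, j - 1, t + 1]
                )
    return E[:, :, : l1 + l2 + 1]


def hermite_coulomb(t_max: int, p: float, PC: np.ndarray) -> np.ndarray:
    """Hermite Coulomb integrals R[t, u, v] up to total order t+u+v <= t_max.

    R_{tuv} = (d/dPx)^t (d/dPy)^u (d/dPz)^v [ (-2p)^0 F_0(p |PC|^2) ] evaluated
    through the auxiliary recursion R^n_{000} = (-2p)^n F_n(p R^2).
    Entries with t+u+v > t_max are left zero and must not be used.
    """
    X, Y, Z = float(PC[0]), float(PC[1]), float(PC[2])
    T = p * (X * X + Y * Y + Z * Z)
    F = boys_array(t_max, T)
    dim = t_max + 1
    # R[n, t, u, v]; order-n auxiliaries needed down to n = 0
    R = np.zeros((dim + 1, dim, dim, dim))
    minus2p = -2.0 * p
    for n in range(t_max + 1):
        R[n, 0, 0, 0] = minus2p**n * F[n]
    for total in range(1, t_max + 1):
        for n in range(t_max - total, -1, -1):
            for t in range(total + 1):
                for u in range(total - t + 1):
                    v = total - t - u
                    if t > 0:
                        val = X * R[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * R[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * R[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * R[n + 1, t, u - 2, v]
                    else:
                        val = Z * R[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * R[n + 1, t, u, v - 2]
                    R[n, t, u, v] = val
    return R[0]
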