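"""Assembly of overlap and 2-/3-/4-center repulsion integrals over an indexed basis.

Orbital functions are contracted Cartesian Gaussians normalized to unit
self-overlap per component; auxiliary functions are primitive Hermite
Gaussians normalized to unit Coulomb self-repulsion, so the Coulomb metric
matrix G has a unit diagonal.  The Hermite ket of three-center integrals is
evaluated directly through the McMurchie-Davidson R tensor, with no Cartesian
transformation step.

Cartesian components of a shell are ordered lexicographically by descending
(i, j, k): for d that is xx, xy, xz, yy, yz, zz.  Hermite components of a set
are ordered by total index t+u+v, then the same lexicographic rule, covering
all triples with t+u+v <= L_set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import hermite as nph

from ..basis_io import AtomicAuxBasis, AtomicOrbitalBasis, Molecule
from .mcd import hermite_coulomb, hermite_expansion

__all__ = [
    "IndexedMolecularBasis",
    "build_indexed_basis",
    "cartesian_components",
    "hermite_components",
    "overlap_matrix",
    "eri_2c",
    "eri_3c",
    "eri_4c",
    "eri_2c_primitive",
    "hermite_to_cartesian_1d",
]

TWO_PI_POW = 2.0 * math.pi ** 2.5

MAX_ORBITAL_L = 2  # d functions; capability ceiling of the 4c path
MAX_AUX_L = 6


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def cartesian_components(l: int) -> list[tuple[int, int, int]]:
    """Cartesian powers (i, j, k) with i+j+k = l, x-major lexicographic order."""
    return [(i, j, l - i - j) for i in range(l, -1, -1) for j in range(l - i, -1, -1)]


def hermite_components(L: int) -> list[tuple[int, int, int]]:
    """Hermite index triples (t, u, v) with t+u+v <= L, by total order then lexicographic."""
    comps = []
    for total in range(L + 1):
        comps.extend(
            (t, u, total - t - u)
            for t in range(total, -1, -1)
            for u in range(total - t, -1, -1)
        )
    return comps


def _primitive_norm(zeta: float, l: int) -> float:
    """Unit-self-overlap norm of the (l, 0, 0) Cartesian primitive."""
    return (
        (2.0 * zeta / math.pi) ** 0.75
        * (4.0 * zeta) ** (l / 2.0)
        / math.sqrt(_double_factorial(2 * l - 1))
    )


def _component_factors(l: int) -> np.ndarray:
    """Per-component rescaling relative to the (l, 0, 0) norm."""
    dfl = _double_factorial(2 * l - 1)
    return np.array(
        [
            math.sqrt(dfl / (_double_factorial(2 * i - 1)
                             * _double_factorial(2 * j - 1)
                             * _double_factorial(2 * k - 1)))
            for i, j, k in cartesian_components(l)
        ]
    )


@dataclass
class _AOShell:
    center: np.ndarray
    l: int
    exponents: np.ndarray      # primitive exponents
    weights: np.ndarray        # contraction coefficient * primitive norm * contraction norm
    comp_factors: np.ndarray   # per-component norm correction
    offset: int                # absolute index of the first component

    @property
    def components(self) -> list[tuple[int, int, int]]:
        return cartesian_components(self.l)

    @property
    def n_comp(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2


@dataclass
class _AuxSet:
    center: np.ndarray
    alpha: float
    L: int
    offset: int
    norms: np.ndarray = field(default=None)  # unit-Coulomb-self-repulsion norms

    @property
    def components(self) -> list[tuple[int, int, int]]:
        return hermite_components(self.L)

    @property
    def n_comp(self) -> int:
        return (self.L + 1) * (self.L + 2) * (self.L + 3) // 6


@dataclass
class IndexedMolecularBasis:
    """Flattened per-atom orbital and auxiliary function lists with absolute indices."""

    molecule: Molecule
    ao_shells: list[_AOShell]
    aux_sets: list[_AuxSet]
    nao: int
    naux: int

    @property
    def ao_descriptors(self) -> list[tuple[int, np.ndarray, int, tuple[int, int, int]]]:
        """(absolute index, center, l, (i, j, k)) for every orbital component."""
        out = []
        for sh in self.ao_shells:
            for c, comp in enumerate(sh.components):
                out.append((sh.offset + c, sh.center, sh.l, comp))
        return out

    @property
    def aux_descriptors(self) -> list[tuple[int, np.ndarray, float, tuple[int, int, int]]]:
        """(absolute index, center, alpha, (t, u, v)) for every auxiliary function."""
        out = []
        for st in self.aux_sets:
            for c, comp in enumerate(st.components):
                out.append((st.offset + c, st.center, st.alpha, comp))
        return out


def eri_2c_primitive(
    alpha: float,
    A: np.ndarray,
    tuv_a: tuple[int, int, int],
    beta: float,
    B: np.ndarray,
    tuv_b: tuple[int, int, int],
) -> float:
    """Raw Coulomb repulsion between two unnormalized primitive Hermite Gaussians."""
    t1, u1, v1 = tuv_a
    t2, u2, v2 = tuv_b
    mu = alpha * beta / (alpha + beta)
    R = hermite_coulomb(t1 + u1 + v1 + t2 + u2 + v2, mu, np.asarray(A) - np.asarray(B))
    pref = TWO_PI_POW / (alpha * beta * math.sqrt(alpha + beta))
    return pref * (-1) ** (t2 + u2 + v2) * R[t1 + t2, u1 + u2, v1 + v2]


def eri_3c_primitive(
    zeta1: float,
    A: np.ndarray,
    powers1: tuple[int, int, int],
    zeta2: float,
    B: np.ndarray,
    powers2: tuple[int, int, int],
    alpha: float,
    C: np.ndarray,
    tuv: tuple[int, int, int],
) -> float:
    """Raw <mu nu || k-bar> over unnormalized primitives (Cartesian bra, Hermite ket)."""
    A, B, C = (np.asarray(v, dtype=float) for v in (A, B, C))
    p = zeta1 + zeta2
    P = (zeta1 * A + zeta2 * B) / p
    l1 = sum(powers1)
    l2 = sum(powers2)
    Lk = sum(tuv)
    Es = [hermite_expansion(l1, l2, zeta1, zeta2, A[d] - B[d]) for d in range(3)]
    mu = p * alpha / (p + alpha)
    R = hermite_coulomb(l1 + l2 + Lk, mu, P - C)
    pref = TWO_PI_POW / (p * alpha * math.sqrt(p + alpha))
    sign = (-1) ** sum(tuv)
    total = 0.0
    for t in range(powers1[0] + powers2[0] + 1):
        for u in range(powers1[1] + powers2[1] + 1):
            for v in range(powers1[2] + powers2[2] + 1):
                total += (
                    Es[0][powers1[0], powers2[0], t]
                    * Es[1][powers1[1], powers2[1], u]
                    * Es[2][powers1[2], powers2[2], v]
                    * R[t + tuv[0], u + tuv[1], v + tuv[2]]
                )
    return pref * sign * total


def eri_4c_primitive(
    zeta1, A, powers1, zeta2, B, powers2, zeta3, C, powers3, zeta4, D, powers4
) -> float:
    """Raw <mu nu || lambda sigma> over four unnormalized Cartesian primitives."""
    A, B, C, D = (np.asarray(v, dtype=float) for v in (A, B, C, D))
    p = zeta1 + zeta2
    q = zeta3 + zeta4
    P = (zeta1 * A + zeta2 * B) / p
    Q = (zeta3 * C + zeta4 * D) / q
    lb = sum(powers1) + sum(powers2)
    lk = sum(powers3) + sum(powers4)
    Eb = [hermite_expansion(sum(powers1), sum(powers2), zeta1, zeta2, A[d] - B[d]) for d in range(3)]
    Ek = [hermite_expansion(sum(powers3), sum(powers4), zeta3, zeta4, C[d] - D[d]) for d in range(3)]
    mu = p * q / (p + q)
    R = hermite_coulomb(lb + lk, mu, P - Q)
    pref = TWO_PI_POW / (p * q * math.sqrt(p + q))
    total = 0.0
    for t in range(powers1[0] + powers2[0] + 1):
        for u in range(powers1[1] + powers2[1] + 1):
            for v in range(powers1[2] + powers2[2] + 1):
                eb = (
                    Eb[0][powers1[0], powers2[0], t]
                    * Eb[1][powers1[1], powers2[1], u]
                    * Eb[2][powers1[2], powers2[2], v]
                )
                if eb == 0.0:
                    continue
                for x in range(powers3[0] + powers4[0] + 1):
                    for y in range(powers3[1] + powers4[1] + 1):
                        for z in range(powers3[2] + powers4[2] + 1):
                            ek = (
                                Ek[0][powers3[0], powers4[0], x]
                                * Ek[1][powers3[1], powers4[1], y]
                                * Ek[2][powers3[2], powers4[2], z]
                            )
                            total += (
                                eb * ek * (-1) ** (x + y + z)
                                * R[t + x, u + y, v + z]
                            )
    return pref * total


def build_indexed_basis(
    mol: Molecule,
    obs_map: dict[str, AtomicOrbitalBasis],
    aux_map: dict[str, AtomicAuxBasis] | None = None,
) -> IndexedMolecularBasis:
    """Index all orbital and auxiliary functions of a molecule for assembly."""
    ao_shells: list[_AOShell] = []
    offset = 0
    for sym, center in zip(mol.symbols, mol.coordinates):
        if sym not in obs_map:
            raise KeyError(f"no orbital basis for element {sym!r}")
        for shell in obs_map[sym].shells:
            exps = shell.exponents
            coefs = shell.coefficients
            norms = np.array([_primitive_norm(z, shell.l) for z in exps])
            w = coefs * norms
            # contracted self-overlap (component independent once primitives
            # are normalized); closed form for same-center Cartesian overlap
            s_self = 0.0
            dfl = _double_factorial(2 * shell.l - 1)
            for pz, pw in zip(exps, w):
                for qz, qw in zip(exps, w):
                    zs = pz + qz
                    s_self += pw * qw * (math.pi / zs) ** 1.5 * dfl / (2.0 * zs) ** shell.l
            w = w / math.sqrt(s_self)
            ao_shells.append(
                _AOShell(
                    center=np.asarray(center, dtype=float),
                    l=shell.l,
                    exponents=exps,
                    weights=w,
                    comp_factors=_component_factors(shell.l),
                    offset=offset,
                )
            )
            offset += ao_shells[-1].n_comp
    nao = offset

    aux_sets: list[_AuxSet] = []
    offset = 0
    if aux_map is not None:
        for sym, center in zip(mol.symbols, mol.coordinates):
            if sym not in aux_map:
                raise KeyError(f"no auxiliary basis for element {sym!r}")
            for aset in aux_map[sym].sets:
                st = _AuxSet(
                    center=np.asarray(center, dtype=float),
                    alpha=aset.alpha,
                    L=aset.L_set,
                    offset=offset,
                )
                st.norms = np.array(
                    [
                        1.0
                        / math.sqrt(
                            eri_2c_primitive(st.alpha, st.center, c, st.alpha, st.center, c)
                        )
                        for c in st.components
                    ]
                )
                aux_sets.append(st)
                offset += st.n_comp
    naux = offset
    return IndexedMolecularBasis(mol, ao_shells, aux_sets, nao, naux)


# ----------------------------------------------------------------------------
# shell-pair Hermite charge expansion
# ----------------------------------------------------------------------------


def _pair_expansions(sh1: _AOShell, sh2: _AOShell):
    """Per primitive pair: (p, P, E3) with

    E3[c1, c2, t, u, v] = weights * E_t^x E_u^y E_v^z * component factors,
    the Hermite expansion of every component-pair charge distribution.
    """
    l1, l2 = sh1.l, sh2.l
    lt = l1 + l2
    comps1 = sh1.components
    comps2 = sh2.components
    i1 = np.array([c[0] for c in comps1])
    j1 = np.array([c[1] for c in comps1])
    k1 = np.array([c[2] for c in comps1])
    i2 = np.array([c[0] for c in comps2])
    j2 = np.array([c[1] for c in comps2])
    k2 = np.array([c[2] for c in comps2])
    AB = sh1.center - sh2.center
    out = []
    for z1, w1 in zip(sh1.exponents, sh1.weights):
        for z2, w2 in zip(sh2.exponents, sh2.weights):
            p = z1 + z2
            P = (z1 * sh1.center + z2 * sh2.center) / p
            Ex = hermite_expansion(l1, l2, z1, z2, AB[0])
            Ey = hermite_expansion(l1, l2, z1, z2, AB[1])
            Ez = hermite_expansion(l1, l2, z1, z2, AB[2])
            E3 = (
                Ex[i1[:, None], i2[None, :], :][:, :, :, None, None]
                * Ey[j1[:, None], j2[None, :], :][:, :, None, :, None]
                * Ez[k1[:, None], k2[None, :], :][:, :, None, None, :]
            )
            scale = w1 * w2 * np.outer(sh1.comp_factors, sh2.comp_factors)
            E3 = E3 * scale[:, :, None, None, None]
            out.append((p, P, E3, lt))
    return out


def overlap_matrix(basis: IndexedMolecularBasis) -> np.ndarray:
    """Orbital overlap matrix; unit diagonal under the normalization convention."""
    S = np.zeros((basis.nao, basis.nao))
    for sh1 in basis.ao_shells:
        for sh2 in basis.ao_shells:
            if sh2.offset < sh1.offset:
                continue
            block = np.zeros((sh1.n_comp, sh2.n_comp))
            for p, P, E3, lt in _pair_expansions(sh1, sh2):
                block += (math.pi / p) ** 1.5 * E3[:, :, 0, 0, 0]
            S[
                sh1.offset : sh1.offset + sh1.n_comp,
                sh2.offset : sh2.offset + sh2.n_comp,
            ] = block
            if sh1.offset != sh2.offset:
                S[
                    sh2.offset : sh2.offset + sh2.n_comp,
                    sh1.offset : sh1.offset + sh1.n_comp,
                ] = block.T
    return S


def _aux_index_arrays(aset: _AuxSet):
    comps = aset.components
    t = np.array([c[0] for c in comps])
    u = np.array([c[1] for c in comps])
    v = np.array([c[2] for c in comps])
    signs = (-1.0) ** (t + u + v)
    return t, u, v, signs


def eri_2c(basis: IndexedMolecularBasis) -> np.ndarray:
    """Auxiliary Coulomb metric matrix G with elements <a-bar || b-bar>."""
    G = np.zeros((basis.naux, basis.naux))
    for sa in basis.aux_sets:
        ta, ua, va, _ = _aux_index_arrays(sa)
        for sb in basis.aux_sets:
            if sb.offset < sa.offset:
                continue
            tb, ub, vb, sgn_b = _aux_index_arrays(sb)
            mu = sa.alpha * sb.alpha / (sa.alpha + sb.alpha)
            R = hermite_coulomb(sa.L + sb.L, mu, sa.center - sb.center)
            pref = TWO_PI_POW / (
                sa.alpha * sb.alpha * math.sqrt(sa.alpha + sb.alpha)
            )
            block = (
                pref
                * R[
                    ta[:, None] + tb[None, :],
                    ua[:, None] + ub[None, :],
                    va[:, None] + vb[None, :],
                ]
                * sgn_b[None, :]
                * np.outer(sa.norms, sb.norms)
            )
            G[sa.offset : sa.offset + sa.n_comp, sb.offset : sb.offset + sb.n_comp] = block
            if sa.offset != sb.offset:
                G[sb.offset : sb.offset + sb.n_comp, sa.offset : sa.offset + sa.n_comp] = (
                    block.T
                )
    return G


def eri_3c(basis: IndexedMolecularBasis) -> np.ndarray:
    """Three-center repulsion tensor <mu nu || k-bar> of shape (nao, nao, naux)."""
    out = np.zeros((basis.nao, basis.nao, basis.naux))
    for sh1 in basis.ao_shells:
        for sh2 in basis.ao_shells:
            if sh2.offset < sh1.offset:
                continue
            pairs = _pair_expansions(sh1, sh2)
            block = np.zeros((sh1.n_comp, sh2.n_comp, basis.naux))
            for aset in basis.aux_sets:
                tk, uk, vk, sgn = _aux_index_arrays(aset)
                wk = sgn * aset.norms
                sub = np.zeros((sh1.n_comp, sh2.n_comp, aset.n_comp))
                for p, P, E3, lt in pairs:
                    gamma = aset.alpha
                    mu = p * gamma / (p + gamma)
                    R = hermite_coulomb(lt + aset.L, mu, P - aset.center)
                    pref = TWO_PI_POW / (p * gamma * math.sqrt(p + gamma))
                    idx = np.arange(lt + 1)
                    Rsel = R[
                        idx[:, None, None, None] + tk[None, None, None, :],
                        idx[None, :, None, None] + uk[None, None, None, :],
                        idx[None, None, :, None] + vk[None, None, None, :],
                    ]
                    sub += pref * np.einsum("abtuv,tuvk->abk", E3, Rsel)
                block[:, :, aset.offset : aset.offset + aset.n_comp] = sub * wk
            out[
                sh1.offset : sh1.offset + sh1.n_comp,
                sh2.offset : sh2.offset + sh2.n_comp,
                :,
            ] = block
            if sh1.offset != sh2.offset:
                out[
                    sh2.offset : sh2.offset + sh2.n_comp,
                    sh1.offset : sh1.offset + sh1.n_comp,
                    :,
                ] = block.transpose(1, 0, 2)
    return out


def eri_4c(basis: IndexedMolecularBasis) -> np.ndarray:
    """Four-center repulsion tensor <mu nu || lambda sigma>, full 8-fold symmetric.

    Supported up to d orbital functions; higher angular momenta raise a
    capability error.
    """
    lmax = max(sh.l for sh in basis.ao_shells)
    if lmax > MAX_ORBITAL_L:
        raise NotImplementedError(
            f"four-center path supports orbital l <= {MAX_ORBITAL_L}, got {lmax}"
        )
    n = basis.nao
    out = np.zeros((n, n, n, n))
    # unordered shell pairs with cached Hermite expansions
    shell_pairs = []
    for a, sh1 in enumerate(basis.ao_shells):
        for sh2 in basis.ao_shells[a:]:
            shell_pairs.append((sh1, sh2, _pair_expansions(sh1, sh2)))
    for ipair, (sh1, sh2, bra) in enumerate(shell_pairs):
        for sh3, sh4, ket in shell_pairs[ipair:]:
            ltb = sh1.l + sh2.l
            ltk = sh3.l + sh4.l
            block = np.zeros((sh1.n_comp, sh2.n_comp, sh3.n_comp, sh4.n_comp))
            idx_b = np.arange(ltb + 1)
            idx_k = np.arange(ltk + 1)
            sgn = (-1.0) ** (
                idx_k[:, None, None] + idx_k[None, :, None] + idx_k[None, None, :]
            )
            for p, P, E3b, _ in bra:
                for q, Q, E3k, _ in ket:
                    mu = p * q / (p + q)
                    R = hermite_coulomb(ltb + ltk, mu, P - Q)
                    pref = TWO_PI_POW / (p * q * math.sqrt(p + q))
                    Rcomb = R[
                        idx_b[:, None, None, None, None, None]
                        + idx_k[None, None, None, :, None, None],
                        idx_b[None, :, None, None, None, None]
                        + idx_k[None, None, None, None, :, None],
                        idx_b[None, None, :, None, None, None]
                        + idx_k[None, None, None, None, None, :],
                    ]
                    block += pref * np.einsum(
                        "abtuv,cdxyz,tuvxyz->abcd",
                        E3b,
                        E3k,
                        Rcomb * sgn[None, None, None, :, :, :],
                        optimize=True,
                    )
            _scatter_4c(out, sh1, sh2, sh3, sh4, block)
    return out


def _scatter_4c(out, sh1, sh2, sh3, sh4, block):
    """Write a shell-quartet block and all its index-symmetry images."""
    s = [
        slice(sh.offset, sh.offset + sh.n_comp) for sh in (sh1, sh2, sh3, sh4)
    ]
    variants = {
        (0, 1, 2, 3): block,
        (1, 0, 2, 3): block.transpose(1, 0, 2, 3),
        (0, 1, 3, 2): block.transpose(0, 1, 3, 2),
        (1, 0, 3, 2): block.transpose(1, 0, 3, 2),
        (2, 3, 0, 1): block.transpose(2, 3, 0, 1),
        (3, 2, 0, 1): block.transpose(3, 2, 0, 1),
        (2, 3, 1, 0): block.transpose(2, 3, 1, 0),
        (3, 2, 1, 0): block.transpose(3, 2, 1, 0),
    }
    for perm, b in variants.items():
        out[s[perm[0]], s[perm[1]], s[perm[2]], s[perm[3]]] = b


def hermite_to_cartesian_1d(l: int, alpha: float) -> np.ndarray:
    """Change-of-basis matrix C with x^n exp(-a x^2) = sum_t C[n, t] Lambda_t.

    Lambda_t is the t-th Hermite Gaussian with exponent ``alpha`` at the same
    center; the matrix is lower triangular and exposes the exact span
    equivalence of Hermite and Cartesian functions of equal total index.
    """
    C = np.zeros((l + 1, l + 1))
    for n_pow in range(l + 1):
        e_n = np.zeros(n_pow + 1)
        e_n[n_pow] = 1.0
        h = nph.poly2herm(e_n)
        for t, coef in enumerate(h):
            C[n_pow, t] = coef * alpha ** (-(n_pow + t) / 2.0)
    return C
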