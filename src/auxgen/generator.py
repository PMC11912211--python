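"""Automatic generation of even-tempered shared-exponent auxiliary basis sets.

The GEN-Xn scheme (n = 2, 3, 4) builds, for one element, an auxiliary basis of
primitive Hermite Gaussian sets whose exponents form a geometric ladder with
ratio beta = 6 - n, anchored at twice the geometric mean of the highest-angular
-momentum ("polarization") orbital exponents, i.e. at the self-product of the
polarization function.  The ladder is extended up and down until it covers the
interval of orbital-product exponents [2*zeta_min, 2*zeta_max]; because the
terminating values may overshoot, the bounds are "fuzzy".  Each ladder exponent
then receives the set angularity L_set = min(2l, L_max) of the highest orbital
angular momentum l whose product-exponent range contains it, so that every
same-l product interval is covered by auxiliary functions of angularity >= 2l.

Increasing n shrinks the ladder spacing and therefore enlarges the basis:
GEN-X2 (beta=4) is the smallest, GEN-X4 (beta=2) the densest and most accurate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis_io import AtomicAuxBasis, AtomicOrbitalBasis, HermiteAuxSet, Molecule

__all__ = [
    "ObsProfile",
    "GenXConfig",
    "obs_profile",
    "scaling_factor",
    "start_exponent",
    "exponent_ladder",
    "product_ranges",
    "assign_angularities",
    "generate_genx",
    "set_function_count",
    "basis_counts",
]

DEFAULT_LMAX = 6  # highest auxiliary angularity (i functions)


@dataclass(frozen=True)
class ObsProfile:
    """Exponent ranges of an atomic orbital basis, per angular momentum and global.

    ``ranges[l] = (zeta_min, zeta_max)`` over all primitives of all shells with
    that l (contractions flattened); the global range is their union hull.
    """

    l_max: int
    ranges: dict[int, tuple[float, float]]
    global_range: tuple[float, float]
    lmax_exponents: tuple[float, ...] = ()


@dataclass(frozen=True)
class GenXConfig:
    """Initialization data of one GEN-Xn run: n, beta = 6 - n, alpha0, L_max."""

    n: int
    beta: float
    alpha0: float
    lmax: int = DEFAULT_LMAX

    def __post_init__(self) -> None:
        if self.n not in (2, 3, 4):
            raise ValueError(f"n must be 2, 3 or 4, got {self.n}")
        if abs(self.beta - (6 - self.n)) > 1e-12:
            raise ValueError("beta must equal 6 - n")
        if not self.alpha0 > 0:
            raise ValueError("alpha0 must be positive")
        if self.lmax > 6 or self.lmax % 2 != 0:
            raise ValueError("L_max must be even and <= 6")


def obs_profile(obs: AtomicOrbitalBasis) -> ObsProfile:
    """Collect per-l and global primitive-exponent ranges of an orbital basis."""
    per_l: dict[int, list[float]] = {}
    for shell in obs.shells:
        per_l.setdefault(shell.l, []).extend(p.exponent for p in shell.primitives)
    ranges = {l: (min(z), max(z)) for l, z in per_l.items()}
    all_z = [z for zs in per_l.values() for z in zs]
    l_max = max(per_l)
    return ObsProfile(
        l_max=l_max,
        ranges=ranges,
        global_range=(min(all_z), max(all_z)),
        lmax_exponents=tuple(per_l[l_max]),
    )


def scaling_factor(n: int) -> float:
    """Even-tempered progression factor beta = 6 - n for GEN-Xn (n in {2,3,4})."""
    if n not in (2, 3, 4):
        raise ValueError(f"GEN-Xn is defined for n in {{2, 3, 4}}, got {n}")
    return float(6 - n)


def start_exponent(profile: ObsProfile) -> float:
    """Starting auxiliary exponent alpha0 = 2 * geometric mean of the l_max primitives.

    With a single polarization primitive zeta this is the self-product exponent
    2*zeta; with several highest-l primitives the geometric mean reduces the
    rule covariantly.
    """
    zetas = np.asarray(
        profile.lmax_exponents or profile.ranges[profile.l_max], dtype=float
    )
    g = float(np.exp(np.mean(np.log(zetas))))
    return 2.0 * g


def exponent_ladder(alpha0: float, beta: float, lo: float, hi: float) -> list[float]:
    """Even-tempered ladder {alpha0 * beta^k} covering [lo, hi] with fuzzy bounds.

    Extended upward until the first value >= hi (inclusive) and downward until
    the first value <= lo (inclusive); if alpha0 already meets a bound no
    extension happens on that side.  Values are computed as explicit powers of
    beta so consecutive ratios are exactly beta in floating point.
    """
    if beta <= 1:
        raise ValueError(f"progression factor beta must exceed 1, got {beta}")
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    if not (lo * (1 - 1e-12) <= alpha0 <= hi * (1 + 1e-12)):
        raise ValueError("alpha0 must lie within [lo, hi]")
    ladder = [alpha0]
    k = 1
    while ladder[-1] < hi:
        ladder.append(alpha0 * beta**k)
        k += 1
    k = 1
    while ladder[0] > lo:
        ladder.insert(0, alpha0 * beta**-k)
        k += 1
    return sorted(ladder, reverse=True)


def product_ranges(profile: ObsProfile) -> dict[int, tuple[float, float]]:
    """Per-l orbital self-product exponent ranges [2*zeta_min^l, 2*zeta_max^l]."""
    return {l: (2.0 * lo, 2.0 * hi) for l, (lo, hi) in profile.ranges.items()}


def assign_angularities(
    ladder: list[float],
    ranges: dict[int, tuple[float, float]],
    lmax: int = DEFAULT_LMAX,
) -> list[int]:
    """Assign a set angularity to each ladder exponent.

    Base rule: L_set(alpha) is the largest min(2l, lmax) over all l whose
    closed product interval contains alpha, defaulting to 0 (an s set).
    A coverage repair pass then guarantees, for every l with target
    L* = min(2l, lmax), that some exponent with L_set >= L* lies at or below
    the interval's lower edge and another at or above its upper edge, by
    promoting the nearest bracketing ladder exponents when a product interval
    is narrower than one ladder step.
    """
    alphas = np.asarray(ladder, dtype=float)
    L = np.zeros(len(alphas), dtype=int)
    for l, (amin, amax) in ranges.items():
        target = min(2 * l, lmax)
        inside = (alphas >= amin) & (alphas <= amax)
        L[inside] = np.maximum(L[inside], target)
    # coverage repair
    for l in sorted(ranges):
        target = min(2 * l, lmax)
        if target == 0:
            continue
        amin, amax = ranges[l]
        below = alphas <= amin
        if not np.any(below & (L >= target)):
            idx = np.where(below)[0]
            if idx.size:
                j = idx[np.argmax(alphas[idx])]
                L[j] = max(L[j], target)
        above = alphas >= amax
        if not np.any(above & (L >= target)):
            idx = np.where(above)[0]
            if idx.size:
                j = idx[np.argmin(alphas[idx])]
                L[j] = max(L[j], target)
    return L.tolist()


def generate_genx(
    obs: AtomicOrbitalBasis, n: int, lmax: int = DEFAULT_LMAX
) -> AtomicAuxBasis:
    """Generate the GEN-Xn auxiliary basis for one element's orbital basis."""
    profile = obs_profile(obs)
    beta = scaling_factor(n)
    alpha0 = start_exponent(profile)
    lo, hi = profile.global_range
    ladder = exponent_ladder(alpha0, beta, 2.0 * lo, 2.0 * hi)
    ranges = product_ranges(profile)
    Ls = assign_angularities(ladder, ranges, lmax)
    sets = tuple(HermiteAuxSet(a, L) for a, L in zip(ladder, Ls))
    return AtomicAuxBasis(
        obs.element, sets, n=n, beta=beta, alpha0=alpha0, lmax=lmax
    )


def set_function_count(L: int) -> int:
    """Number of Hermite functions with angular index 0..L: (L+1)(L+2)(L+3)/6."""
    if not (0 <= L <= 6):
        raise ValueError(f"set angularity must be in 0..6, got {L}")
    return (L + 1) * (L + 2) * (L + 3) // 6


def basis_counts(
    mol: Molecule,
    obs_map: dict[str, AtomicOrbitalBasis],
    aux_map: dict[str, AtomicAuxBasis],
) -> tuple[int, int, float]:
    """Cartesian orbital and auxiliary function counts and their ratio gamma.

    gamma = N_aux / N_basis is the cost prefactor of three-center ERI
    algorithms relative to the orbital basis size.
    """
    n_basis = n_aux = 0
    for sym in mol.symbols:
        if sym not in obs_map or sym not in aux_map:
            raise KeyError(f"no basis entry for element {sym!r}")
        n_basis += obs_map[sym].n_cartesian
        n_aux += aux_map[sym].n_functions
    return n_basis, n_aux, n_aux / n_basis
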