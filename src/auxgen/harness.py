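"""Fixture systems, synthetic densities and the reproducible validation pipeline.

The fixtures are desk-scale closed-shell systems (small uncontracted bases,
one to three atoms) on which every variational-bound property of the fitting
engine can be checked pointwise: the bounds hold for *any* valid closed-shell
density, so seeded random densities replace SCF solutions entirely.  What the
fixtures do not emulate is chemical realism -- absolute fitted energies are
not comparable with production calculations, only the bound structure and the
GEN-Xn accuracy ordering are.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.linalg as sla

from .basis_io import (
    AtomicOrbitalBasis,
    ContractedShell,
    Molecule,
    PrimitiveGaussian,
)
from .fitting import (
    DensityState,
    assemble_J,
    coulomb_energies,
    error_metrics,
    exchange_fit,
    solve_fit,
)
from .generator import basis_counts, generate_genx
from .integrals import build_indexed_basis, eri_2c, eri_3c, eri_4c, overlap_matrix

__all__ = [
    "FixtureSystem",
    "ValidationConfig",
    "ValidationReport",
    "fixture_system",
    "fixture_names",
    "random_density",
    "validate_run",
    "toy_obs",
]

#: numerical slack on the exact variational bounds, relative to the energy
BOUND_SLACK = 1e-10


def _shell(l: int, *zetas: float) -> ContractedShell:
    return ContractedShell(l, tuple(PrimitiveGaussian(z) for z in zetas))


def toy_obs(element: str = "O") -> AtomicOrbitalBasis:
    """The s/p/d toy orbital basis used throughout the documentation examples.

    Uncontracted shells s:{50, 0.1}, p:{5, 0.5}, d:{0.8}; 14 Cartesian
    functions.
    """
    return AtomicOrbitalBasis(
        element,
        (
            _shell(0, 50.0),
            _shell(0, 0.1),
            _shell(1, 5.0),
            _shell(1, 0.5),
            _shell(2, 0.8),
        ),
    )


# uncontracted split-valence + polarization hydrogen basis; the exponent span
# of ~2 decades matches production bases and is what differentiates the
# GEN-Xn ladders from each other
_H_OBS = AtomicOrbitalBasis(
    "H",
    (
        _shell(0, 18.731),
        _shell(0, 2.8253),
        _shell(0, 0.6401),
        _shell(0, 0.1613),
        _shell(1, 1.1),
    ),
)


@dataclass(frozen=True)
class FixtureSystem:
    """A named molecule with per-element orbital bases and an electron count."""

    name: str
    molecule: Molecule
    obs_map: dict[str, AtomicOrbitalBasis]
    n_electrons: int

    def __post_init__(self) -> None:
        if self.n_electrons % 2 != 0:
            raise ValueError("fixture systems are closed-shell: even electron count")

    @property
    def n_occ(self) -> int:
        return self.n_electrons // 2


def _registry(seed: int = 0) -> dict[str, FixtureSystem]:
    systems = {
        "h2": FixtureSystem(
            "h2",
            Molecule(("H", "H"), np.array([[0.0, 0.0, -0.7], [0.0, 0.0, 0.7]])),
            {"H": _H_OBS},
            2,
        ),
        "heh+": FixtureSystem(
            "heh+",
            Molecule(("He", "H"), np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.4632]])),
            {
                "He": AtomicOrbitalBasis(
                    "He",
                    (_shell(0, 38.42), _shell(0, 5.778), _shell(0, 1.2418), _shell(0, 0.2976)),
                ),
                "H": _H_OBS,
            },
            2,
        ),
        "h2o_toy": FixtureSystem(
            "h2o_toy",
            Molecule(
                ("O", "H", "H"),
                np.array(
                    [[0.0, 0.0, 0.0], [1.431, 0.0, 1.108], [-1.431, 0.0, 1.108]]
                ),
            ),
            {"O": toy_obs("O"), "H": _H_OBS},
            10,
        ),
        "dimer_scan": FixtureSystem(
            "dimer_scan",
            Molecule(("Be", "Be"), np.array([[0.0, 0.0, -2.0], [0.0, 0.0, 2.0]])),
            {
                # core-to-valence span of ~4 decades, as in production bases
                "Be": AtomicOrbitalBasis(
                    "Be",
                    (
                        _shell(0, 1264.6),
                        _shell(0, 43.15),
                        _shell(0, 3.806),
                        _shell(0, 0.747),
                        _shell(0, 0.0823),
                        _shell(1, 0.4),
                    ),
                )
            },
            8,
        ),
    }
    rng = np.random.default_rng(seed)
    shells = [
        _shell(0, float(rng.uniform(200.0, 2000.0))),
        _shell(0, float(rng.uniform(5.0, 40.0))),
        _shell(0, float(rng.uniform(0.15, 1.0))),
    ]
    for l in range(1, int(rng.integers(1, 3)) + 1):
        shells.append(_shell(l, float(np.exp(rng.uniform(np.log(0.3), np.log(3.0))))))
    systems["random_obs"] = FixtureSystem(
        "random_obs",
        Molecule(
            ("Ne", "Ne"),
            np.array([[0.0, 0.0, 0.0], [0.0, 0.0, float(rng.uniform(2.2, 3.5))]]),
        ),
        {"Ne": AtomicOrbitalBasis("Ne", tuple(shells))},
        4,
    )
    return systems


def fixture_names() -> list[str]:
    return list(_registry())


def fixture_system(name: str, seed: int = 0) -> FixtureSystem:
    """Look up a fixture by name; ``random_obs`` draws its basis from ``seed``."""
    reg = _registry(seed)
    if name not in reg:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(reg)}")
    return reg[name]


def random_density(S: np.ndarray, n_occ: int, seed: int) -> DensityState:
    """Seeded random S-orthonormal occupied coefficients and the matching P.

    A standard-normal matrix is symmetrically orthogonalized in the S metric;
    identical seeds give bit-identical densities.
    """
    dim = S.shape[0]
    if n_occ > dim:
        raise ValueError(f"n_occ={n_occ} exceeds basis dimension {dim}")
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((dim, n_occ))
    overlap = M.T @ S @ M
    c = M @ np.asarray(sla.fractional_matrix_power(overlap, -0.5)).real
    return DensityState.from_coefficients(c)


@dataclass
class ValidationConfig:
    """Configuration of one validation run."""

    systems: tuple[str, ...] = ("h2", "heh+", "h2o_toy", "dimer_scan", "random_obs")
    n_values: tuple[int, ...] = (2, 3, 4)
    solver: str = "ted"
    seed: int = 1
    n_densities: int = 5
    lmax: int = 6


@dataclass
class ValidationReport:
    """Per-record bound checks plus suite-level error statistics."""

    config: dict
    records: list[dict]
    metrics: dict
    all_passed: bool
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


@dataclass
class _SystemCache:
    """Geometry/basis-dependent tensors, shared across densities and solvers."""

    basis: object
    S: np.ndarray
    eri4c: np.ndarray
    gamma: float
    G: np.ndarray
    eri3c: np.ndarray


def build_system(system: FixtureSystem, n: int, lmax: int = 6) -> _SystemCache:
    """Generate the GEN-Xn bases of a fixture and assemble all integral tensors."""
    aux_map = {
        sym: generate_genx(obs, n, lmax) for sym, obs in system.obs_map.items()
    }
    basis = build_indexed_basis(system.molecule, system.obs_map, aux_map)
    _, _, gamma = basis_counts(system.molecule, system.obs_map, aux_map)
    return _SystemCache(
        basis=basis,
        S=overlap_matrix(basis),
        eri4c=eri_4c(basis),
        gamma=gamma,
        G=eri_2c(basis),
        eri3c=eri_3c(basis),
    )


def evaluate_density(
    cache: _SystemCache,
    density: DensityState,
    solver: str = "ted",
) -> dict:
    """Fit one density on prebuilt tensors and check every bound invariant."""
    J = assemble_J(density.P, cache.eri3c)
    sol = solve_fit(cache.G, J, method=solver)
    cres = coulomb_energies(
        density.P, sol.x, cache.G, J, cache.eri4c, cache.eri3c, solution=sol,
    )
    xres = exchange_fit(
        density.c, cache.eri3c, cache.G, cache.eri4c, cache.S, method=solver
    )
    scale_H = max(abs(cres.E_H), 1.0)
    scale_F = max(abs(xres.E_F), 1.0)
    spread = max(
        abs(cres.E_a - cres.E_b), abs(cres.E_a - cres.E_c), abs(cres.E_a - cres.E_d)
    )
    checks = {
        "coulomb_bound": cres.eps2_H >= -BOUND_SLACK * scale_H,
        "exchange_bound": xres.eps2_F <= BOUND_SLACK * scale_F,
        "pair_bounds": bool(
            np.all(xres.pair_fitted <= xres.pair_exact + BOUND_SLACK * scale_F)
        ),
        "expression_spread": spread <= 1e-9 * scale_H,
    }
    return {
        "E_H": cres.E_H,
        "E_a": cres.E_a,
        "E_b": cres.E_b,
        "E_c": cres.E_c,
        "E_d": cres.E_d,
        "eps2_H": cres.eps2_H,
        "E_F": xres.E_F,
        "E_F_fitted": xres.E_F_fitted,
        "eps2_F": xres.eps2_F,
        "solver": {
            "method": sol.method,
            "dropped": sol.dropped,
            "iterations": sol.iterations,
            "residual": sol.residual,
        },
        "checks": checks,
    }


def validate_run(config: ValidationConfig) -> ValidationReport:
    """Run the full suite: generate, assemble, fit, check bounds, aggregate."""
    if not config.systems:
        raise ValueError("validation needs at least one system")
    records: list[dict] = []
    eps_h: list[float] = []
    eps_f: list[float] = []
    gammas: list[float] = []
    seed_seq = np.random.SeedSequence(config.seed)
    density_seeds = seed_seq.generate_state(config.n_densities).tolist()
    for sys_name in config.systems:
        system = fixture_system(sys_name, seed=config.seed)
        for n in config.n_values:
            cache = build_system(system, n, config.lmax)
            for dseed in density_seeds:
                density = random_density(cache.S, system.n_occ, int(dseed) % 2**31)
                rec = evaluate_density(cache, density, config.solver)
                rec.update(
                    system=sys_name, n=n, density_seed=int(dseed) % 2**31,
                    gamma=cache.gamma,
                )
                records.append(rec)
                eps_h.append(rec["eps2_H"])
                eps_f.append(rec["eps2_F"])
                gammas.append(cache.gamma)
    m_h = error_metrics(eps_h, gammas)
    m_f = error_metrics(eps_f, gammas)
    all_passed = all(all(r["checks"].values()) for r in records)
    return ValidationReport(
        config=asdict(config),
        records=records,
        metrics={
            "coulomb": asdict(m_h),
            "exchange": asdict(m_f),
        },
        all_passed=all_passed,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
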