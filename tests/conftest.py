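"""Shared fixtures: the documentation toy basis and prebuilt fixture-suite tensors."""

from __future__ import annotations

import numpy as np
import pytest

from auxgen.basis_io import AtomicOrbitalBasis, ContractedShell, PrimitiveGaussian
from auxgen.harness import (
    build_system,
    evaluate_density,
    fixture_names,
    fixture_system,
    random_density,
)

FIXTURE_SEED = 1
N_VALUES = (2, 3, 4)
N_DENSITIES = 14  # 5 systems x 3 n x 14 densities = 210 records


def shell(l, *zetas):
    return ContractedShell(l, tuple(PrimitiveGaussian(z) for z in zetas))


@pytest.fixture(scope="session")
def toy_obs():
    """The s/p/d toy orbital basis of the worked generator examples."""
    return AtomicOrbitalBasis(
        "O",
        (shell(0, 50.0), shell(0, 0.1), shell(1, 5.0), shell(1, 0.5), shell(2, 0.8)),
    )


@pytest.fixture(scope="session")
def suite_caches():
    """Integral tensors of every fixture system at every GEN-Xn level."""
    caches = {}
    for name in fixture_names():
        system = fixture_system(name, seed=FIXTURE_SEED)
        for n in N_VALUES:
            caches[name, n] = (system, build_system(system, n))
    return caches


@pytest.fixture(scope="session")
def suite_records(suite_caches):
    """Fitted-energy records for seeded random densities over the whole suite."""
    seeds = np.random.SeedSequence(FIXTURE_SEED).generate_state(N_DENSITIES)
    records = []
    for (name, n), (system, cache) in suite_caches.items():
        for ds in seeds:
            density = random_density(cache.S, system.n_occ, int(ds) % 2**31)
            rec = evaluate_density(cache, density, "ted")
            rec.update(system=name, n=n)
            records.append(rec)
    return records
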