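"""Shared fixtures: small typed systems with synthetic properties."""

from __future__ import annotations

import numpy as np
import pytest

import pairsapt as ps
from pairsapt.energy import System


@pytest.fixture(scope="session")
def library():
    return ps.make_monomer_library()


@pytest.fixture(scope="session")
def truth_params():
    return ps.ground_truth_parameters(seed=2024)


@pytest.fixture(scope="session")
def small_systems():
    """A handful of homo- and heterodimer systems (deterministic)."""
    spec = ps.SyntheticSpec(
        seed=7, monomer_names=["methane", "water", "methanol"],
        n_orientations=1,
    )
    return ps.sample_systems(spec)


@pytest.fixture(scope="session")
def water_dimer_system(small_systems) -> System:
    return next(
        s for s in small_systems if s.dimer.id.startswith("water--water")
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rotate_system(system: System, rotation: np.ndarray,
                  translation: np.ndarray) -> System:
    """Rigidly transform a whole system, co-rotating the multipoles."""
    dimer = ps.Dimer(
        system.dimer.monomer_a.transformed(rotation, translation),
        system.dimer.monomer_b.transformed(rotation, translation),
        id=system.dimer.id,
    )
    return System(dimer, [p.rotated(rotation) for p in system.props])
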