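"""Shared fixtures: small/medium synthetic ensembles and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from membranekit import BilayerSpec, ParticleEnsemble, build_bilayer_system
from membranekit.constants import rt

TEMP = 330.0
RT330 = rt(TEMP)


def double_well(z, depth=3.0, barrier=4.0, b=1.2, edge=2.0):
    """Membrane-like double-well PMF: flat (zero) beyond |z| = edge, smooth
    minima of -depth at |z| = b, central barrier at +barrier - depth... the
    center sits ``barrier`` above the minima and ``barrier - depth`` above
    bulk."""
    az = np.abs(np.asarray(z, dtype=float))
    out = np.zeros_like(az)
    rim = (az > b) & (az < edge)
    out[rim] = -depth / 2.0 * (1.0 + np.cos(np.pi * (az[rim] - b) / (edge - b)))
    core = az <= b
    out[core] = -depth + barrier / 2.0 * (1.0 + np.cos(np.pi * az[core] / b))
    return out


@pytest.fixture(scope="session")
def small_ensemble() -> ParticleEnsemble:
    """Tiny bilayer for fast structural/IO tests."""
    spec = BilayerSpec(n_per_leaflet=16, n_frames=5, n_solute=24, seed=11)
    return build_bilayer_system(spec)


@pytest.fixture(scope="session")
def medium_spec() -> BilayerSpec:
    return BilayerSpec(
        n_per_leaflet=64,
        n_frames=20,
        n_solute=400,
        solute_pmf=double_well,
        seed=5,
    )


@pytest.fixture(scope="session")
def medium_ensemble(medium_spec) -> ParticleEnsemble:
    """Bilayer with solutes drawn from a known double-well free-energy
    profile; used for generator round-trip tests."""
    return build_bilayer_system(medium_spec)


def ensemble_from_orientations(vectors: np.ndarray) -> ParticleEnsemble:
    """One-frame ensemble with one carbon per C-H vector, for exercising
    the order-parameter estimator on a prescribed orientation sample."""
    n = vectors.shape[0]
    box = np.array([50.0, 50.0, 50.0])
    carbons = np.column_stack(
        (
            np.random.default_rng(0).uniform(5, 45, n),
            np.random.default_rng(1).uniform(5, 45, n),
            np.full(n, 25.0),
        )
    )
    hydrogens = carbons + 0.109 * vectors
    coords = np.concatenate([carbons, hydrogens])[None, :, :]
    species = np.array(
        ["lipid-tail-carbon"] * n + ["tail-hydrogen"] * n, dtype=object
    )
    return ParticleEnsemble(
        coords=coords,
        box=box[None, :],
        species=species,
        mass=np.where(species == "tail-hydrogen", 1.008, 12.011),
        electron_count=np.where(species == "tail-hydrogen", 1.0, 6.0),
        resid=np.concatenate([np.arange(n), np.arange(n)]),
        leaflet=np.array(["upper"] * (2 * n), dtype=object),
        carbon_index=np.zeros(2 * n, dtype=int),
        parent_carbon=np.concatenate([np.full(n, -1), np.arange(n)]),
    )
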