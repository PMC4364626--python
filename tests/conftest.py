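import numpy as np
import pytest

from consensus_sdm.grids import EnvGrid, SpeciesDistribution
from consensus_sdm.synthetic import (LayerSpec, VirtualSpeciesSpec,
                                     default_landscape_specs, gen_landscape,
                                     gen_virtual_species)


@pytest.fixture(scope="session")
def env2():
    """Two-layer 40x40 landscape used by most unit tests."""
    specs = {"A": LayerSpec(mean=10, sd=3, autocorr_range=2),
             "B": LayerSpec(mean=0, sd=2, autocorr_range=2)}
    return gen_landscape(40, 40, specs, seed=42)


@pytest.fixture(scope="session")
def species2(env2):
    """A mid-prevalence virtual species on env2, niche centred off-mean."""
    a = env2.layer("A")[env2.mask]
    spec = VirtualSpeciesSpec(
        optimum={"A": float(a.mean() + a.std()), "B": 0.0},
        breadth={"A": float(a.std()), "B": 4.0},
        prevalence_target=0.2, seed=7,
    )
    species, suit = gen_virtual_species(env2, spec)
    return species, suit


@pytest.fixture(scope="session")
def full_env():
    """Small landscape with the full default (China-like) layer set."""
    return gen_landscape(40, 40, default_landscape_specs(), seed=3)


@pytest.fixture()
def toy_env():
    """Deterministic 10x10 3-layer grid for brute-force comparisons."""
    rng = np.random.default_rng(0)
    values = rng.normal(size=(3, 10, 10))
    mask = np.ones((10, 10), dtype=bool)
    mask[0, 0] = False
    return EnvGrid(layer_names=["x", "y", "z"], values=values, mask=mask,
                   cell_size_km=8.0, origin_latlon=(45.0, 100.0))


def make_species(env, presence_fraction=0.3, seed=0):
    """Uniform random species on an EnvGrid (no niche structure)."""
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(env.mask)
    k = max(2, int(presence_fraction * rows.size))
    idx = rng.choice(rows.size, size=k, replace=False)
    presence = np.zeros(env.shape, dtype=bool)
    presence[rows[idx], cols[idx]] = True
    return SpeciesDistribution(presence=presence, env=env)
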