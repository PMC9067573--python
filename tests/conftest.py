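import numpy as np
import pytest

from uniquacmc import (ComponentGeometry, PriorSpec, SymmetricInteractionSet,
                       fit_map, split_by_system)
from uniquacmc.synthetic import (GeneratorConfig, generate_antoine,
                                 generate_observations, generate_truth)


def random_uniquac_instance(rng: np.random.Generator, n: int):
    """A random n-component UNIQUAC parameter set: geometries with
    r, q in (1, 10) and symmetric energies in (-3000, 1000) J/mol."""
    ids = [f"c{k}" for k in range(n)]
    geometries = [ComponentGeometry(component_id=c,
                                    r=float(rng.uniform(1, 10)),
                                    q=float(rng.uniform(1, 10)))
                  for c in ids]
    U = rng.uniform(-3000.0, 1000.0, size=(n, n))
    U = np.triu(U) + np.triu(U, 1).T
    return ids, geometries, SymmetricInteractionSet(ids, U)


def random_composition(rng: np.random.Generator, n: int) -> np.ndarray:
    x = rng.dirichlet(np.ones(n))
    # keep strictly interior
    x = np.clip(x, 1e-6, None)
    return x / x.sum()


@pytest.fixture(scope="session")
def dense_clean():
    """Small noise-free, densely observed synthetic problem: every
    system observed, exact model values. Identifiability is easy, so
    fits should essentially interpolate."""
    config = GeneratorConfig(N_components=10, K_true=2,
                             observed_system_fraction=1.0,
                             records_per_system=10, noise_scale=0.0,
                             infinite_dilution_fraction=0.25, seed=11)
    truth = generate_truth(config)
    dataset = split_by_system(generate_observations(truth),
                              (0.8, 0.1, 0.1), seed=5)
    return truth, dataset


@pytest.fixture(scope="session")
def dense_clean_map_fit(dense_clean):
    truth, dataset = dense_clean
    summary = fit_map(dataset, PriorSpec(), truth.geometries,
                      truth.config.K_true, seed=4)
    return truth, dataset, summary


@pytest.fixture(scope="session")
def noisy_small():
    """Small noisy synthetic problem for baseline and consistency tests."""
    config = GeneratorConfig(N_components=6, K_true=2,
                             observed_system_fraction=1.0,
                             records_per_system=15, noise_scale=0.1, seed=23)
    truth = generate_truth(config)
    dataset = split_by_system(generate_observations(truth),
                              (0.8, 0.1, 0.1), seed=9)
    return truth, dataset


@pytest.fixture(scope="session")
def vle_fixture():
    """Two-component system with truth energies and Antoine tables."""
    config = GeneratorConfig(N_components=3, K_true=2, seed=31,
                             observed_system_fraction=1.0,
                             records_per_system=5)
    truth = generate_truth(config)
    antoine = generate_antoine(truth, seed=77)
    return truth, antoine
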