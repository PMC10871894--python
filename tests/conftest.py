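import numpy as np
import pytest

from hybridfgm.genome import MutationRegistry
from hybridfgm.population import Population, PopulationParams
from hybridfgm.scenarios import preset, run_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def registry():
    return MutationRegistry()


def small_params(system="diploid", N=20, **kwargs):
    defaults = dict(L=10_000, mu=0.0, r_bp=0.0, n_dims=2, lambda_mean=0.2, h=0.5)
    defaults.update(kwargs)
    return PopulationParams(system=system, N_pop=N, **defaults)


@pytest.fixture
def small_diploid(registry):
    return Population.founding("P1", small_params(), registry)


def seed_variant(pop, registry, delta, rows, position=100, h=0.5, generation=0):
    """Insert one segregating mutation into the given genome rows."""
    mut = registry.register(position, np.asarray(delta, dtype=float), h, generation, pop.label)
    M = pop.n_segregating
    j = int(np.searchsorted(pop.positions, mut.position))
    pop.G = np.insert(pop.G, j, 0, axis=1)
    pop.G[rows, j] = 1
    pop.positions = np.insert(pop.positions, j, mut.position)
    pop.mut_ids = np.insert(pop.mut_ids, j, mut.id)
    pop.effects = np.insert(pop.effects, j, mut.effect.delta, axis=0)
    pop.dominance = np.insert(pop.dominance, j, h)
    pop.prunable = np.insert(pop.prunable, j, True)
    pop._invalidate_caches()
    return mut


# ------------------------------------------------------------------------
# Shared scaled-down scenario runs (expensive; computed once per session).
# Population sizes, phase lengths, the 5x mutation-rate scaling, and the
# 10-replicate averaging are fixed study conditions for the reduced-scale
# reproductions; seeds are arbitrary constants.
# ------------------------------------------------------------------------

SCALED = dict(T_parental=500, T_novel=300, mu=5e-8, replicates=10)


@pytest.fixture(scope="session")
def fig2a_diploid():
    return run_scenario(preset("fig2A", system="diploid", N_pop=300, seed=101, **SCALED))


@pytest.fixture(scope="session")
def fig2a_haplodiploid():
    return run_scenario(
        preset("fig2A", system="haplodiploid", N_pop=400, seed=102, **SCALED)
    )


@pytest.fixture(scope="session")
def fig2c_diploid():
    return run_scenario(preset("fig2C", system="diploid", N_pop=300, seed=103, **SCALED))


# Criterion-9 contrast fixtures: only generations up to ~50 post-shift enter
# any statistic, and forward dynamics make those records independent of the
# later horizon, so the novel phase is shortened to 60 generations.
SHORT = dict(SCALED, T_novel=60)


@pytest.fixture(scope="session")
def fig2a_diploid_dominant():
    return run_scenario(
        preset("fig2A", system="diploid", N_pop=300, h=0.8, seed=101, **SHORT)
    )


@pytest.fixture(scope="session")
def fig2a_diploid_large_effects():
    return run_scenario(
        preset("fig2A", system="diploid", N_pop=300, lambda_mean=0.4, seed=101, **SHORT)
    )


@pytest.fixture(scope="session")
def fig2a_diploid_small_effects():
    return run_scenario(
        preset("fig2A", system="diploid", N_pop=300, lambda_mean=0.1, seed=101, **SHORT)
    )


@pytest.fixture(scope="session")
def fig3c_diploid():
    # divergently adapted parents (P1 -> {2,0,...}, P2 -> {0,2,...});
    # only the creation generation enters the diversity statistics
    return run_scenario(preset("fig3C", system="diploid", N_pop=300, seed=105, **SHORT))


@pytest.fixture(scope="session")
def fig2a_tetraploid():
    # N = 152 (hybrid creation needs N divisible by 4): 608 gene copies,
    # matching the diploid fixture's 600
    return run_scenario(
        preset("fig2A", system="tetraploid", N_pop=152, seed=104, **SHORT)
    )


def mean_trajectories(df):
    """Replicate-mean fitness per population, indexed by generation."""
    return (
        df.groupby(["population", "generation"]).mean_fitness_all.mean().unstack(0)
    )
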