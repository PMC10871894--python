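import numpy as np
import pytest

from hybridfgm.fgm import FitnessSurface, genotype_to_phenotype
from hybridfgm.genome import FEMALE, MALE, HaploidGenome, MutationRegistry
from hybridfgm.population import (
    Population,
    PopulationParams,
    SelectionCollapseError,
    allele_frequencies,
    apply_new_mutations,
    draw_gamete,
    fix_and_prune,
    next_generation,
)

from conftest import seed_variant, small_params


class TestDrawGamete:
    def test_no_recombination_transmits_one_copy_verbatim(self, registry, rng):
        pop = Population.founding("P1", small_params(N=4), registry)
        m = seed_variant(pop, registry, [0.1, 0.0], rows=[0])  # one copy in ind 0
        parent = pop.individuals()[0]
        gametes = {draw_gamete(parent, 0.0, 10_000, rng).mutation_ids for _ in range(40)}
        assert gametes <= {(), (m.id,)}
        assert len(gametes) == 2  # both copies transmitted eventually

    def test_haploid_parent_transmits_unchanged(self, registry, rng):
        params = small_params(system="haplodiploid", N=4)
        pop = Population.founding("P1", params, registry)
        male_row = int(pop.row_start[pop.n_females])
        m = seed_variant(pop, registry, [0.1, 0.0], rows=[male_row])
        male = pop.individuals()[pop.n_females]
        assert male.ploidy == 1
        for _ in range(5):
            assert draw_gamete(male, 1e-3, 10_000, rng).mutation_ids == (m.id,)

    def test_crossover_count_matches_poisson_mean(self, rng):
        r_bp, L = 1e-4, 10_000  # r * L = 1 expected crossover
        draws = rng.poisson(r_bp * L, 10_000)
        # sanity of the scale used below
        assert abs(draws.mean() - 1.0) < 0.05
        # a marker at each end: transmission switches between copies when an
        # odd number of crossovers falls between them
        registry = MutationRegistry()
        pop = Population.founding("P1", small_params(N=4, r_bp=r_bp), registry)
        m_left = seed_variant(pop, registry, [0.1, 0], rows=[0], position=0)
        m_right = seed_variant(pop, registry, [0.1, 0], rows=[0], position=9_999)
        parent = pop.individuals()[0]
        recombinant = 0
        trials = 4000
        for _ in range(trials):
            ids = set(draw_gamete(parent, r_bp, L, rng).mutation_ids)
            if (m_left.id in ids) != (m_right.id in ids):
                recombinant += 1
        # P(odd # crossovers over ~the whole map) = (1 - exp(-2 r d)) / 2
        d = 9_999
        expect = (1 - np.exp(-2 * r_bp * d)) / 2
        se = np.sqrt(expect * (1 - expect) / trials)
        assert abs(recombinant / trials - expect) < 4 * se

    def test_mendelian_segregation(self, registry, rng):
        pop = Population.founding("P1", small_params(N=4), registry)
        m = seed_variant(pop, registry, [0.1, 0.0], rows=[0])
        parent = pop.individuals()[0]
        carried = sum(
            m.id in draw_gamete(parent, 0.0, 10_000, rng).mutation_ids
            for _ in range(10_000)
        )
        assert abs(carried / 10_000 - 0.5) < 0.02

    def test_tetraploid_gamete_is_diploid(self, registry, rng):
        params = small_params(system="tetraploid", N=4)
        pop = Population.founding("P1", params, registry)
        seed_variant(pop, registry, [0.1, 0.0], rows=[0, 1, 2, 3])
        parent = pop.individuals()[0]
        gamete = draw_gamete(parent, 0.0, 10_000, rng)
        assert isinstance(gamete, tuple) and len(gamete) == 2
        assert all(isinstance(g, HaploidGenome) for g in gamete)


class TestApplyNewMutations:
    def test_zero_rate_is_identity(self, registry, rng):
        g = HaploidGenome()
        assert apply_new_mutations(g, 0.0, 10**6, 5, 0.2, 0.5, 0, "P1", rng) is g

    def test_poisson_mean_mu_L(self, registry):
        rng = np.random.default_rng(5)
        mu, L = 1e-8, 10**6
        total = sum(
            len(apply_new_mutations(HaploidGenome(), mu, L, 2, 0.2, 0.5, 0, "P1", rng, registry).mutations)
            for _ in range(100_000)
        )
        mean = total / 100_000
        se = np.sqrt(mu * L / 100_000)
        assert abs(mean - 0.01) < 4 * se

    def test_deterministic_given_seed(self, registry):
        out = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            reg = MutationRegistry()
            g = apply_new_mutations(HaploidGenome(), 1e-3, 10**4, 3, 0.2, 0.5, 1, "P2", rng, reg)
            out.append([(m.position, tuple(m.effect.delta)) for m in g.mutations])
        assert out[0] == out[1] and len(out[0]) > 0


class TestNextGeneration:
    def test_constant_size_and_exact_sex_ratio(self, registry, rng):
        for system, N in (("diploid", 21), ("haplodiploid", 10), ("tetraploid", 8)):
            pop = Population.founding("P1", small_params(system=system, N=N, mu=1e-4), registry)
            surface = FitnessSurface(optimum=np.zeros(2))
            for _ in range(5):
                pop = next_generation(pop, surface, rng)
                pop.check_invariants()
                assert pop.size == N
                assert pop.n_females == (N + 1) // 2
                assert pop.n_males == N // 2

    def test_haplodiploid_copy_counts(self, registry, rng):
        pop = Population.founding("P1", small_params(system="haplodiploid", N=10, mu=1e-4), registry)
        pop = next_generation(pop, None, rng)
        copies = pop.copies_per_individual
        assert np.all(copies[pop.sexes == FEMALE] == 2)
        assert np.all(copies[pop.sexes == MALE] == 1)

    def test_selection_collapse_raises(self, registry, rng):
        pop = Population.founding("P1", small_params(N=6), registry)
        # optimum absurdly far away: all fitnesses underflow to exactly 0
        surface = FitnessSurface(optimum=np.full(2, 1e6))
        with pytest.raises(SelectionCollapseError):
            next_generation(pop, surface, rng)

    def test_phenotypes_match_object_level_mapping(self, registry, rng):
        # the vectorised matrix path must agree with the per-individual
        # dosage-weight computation
        pop = Population.founding("P1", small_params(system="haplodiploid", N=8, mu=2e-4, r_bp=1e-5), registry)
        for _ in range(15):
            pop = next_generation(pop, None, rng)
        Z = pop.phenotypes()
        reg = pop.registry.mutations
        for i, ind in enumerate(pop.individuals()):
            ploidy = ind.ploidy
            dosage = [
                (reg[mid].effect, c, ploidy) for mid, c in ind.dosage().items()
            ]
            z = genotype_to_phenotype(pop.fixed_background, dosage)
            assert np.allclose(Z[i], z)

    def test_neutral_allele_fixes_at_initial_frequency(self, rng):
        # single-copy neutral allele in a small diploid population
        N, trials = 8, 4000
        fixed = 0
        for _ in range(trials):
            reg = MutationRegistry()
            pop = Population.founding("P1", small_params(N=N), reg)
            seed_variant(pop, reg, [0.0, 0.0], rows=[int(rng.integers(0, 2 * N))])
            while 0 < pop.n_segregating:
                if int(pop.G.sum()) == pop.total_copies:
                    fixed += 1
                    break
                pop = next_generation(pop, None, rng)
        p0 = 1 / (2 * N)
        se = np.sqrt(p0 * (1 - p0) / trials)
        assert abs(fixed / trials - p0) < 4 * se

    def test_neutral_drift_variance(self, rng):
        # one generation of pure drift: Var(dp) ~ p(1-p)/(gene copies)
        N, p0, reps = 20, 0.4, 3000
        copies = 2 * N
        # carriers at equal frequency in both sexes (each parent pool
        # contributes half the gametes, so unequal sex frequencies would
        # shift the expected frequency deterministically)
        k_sex = int(p0 * N)  # copies per sex (N gene copies per sex)
        rows = list(range(k_sex)) + list(range(N, N + k_sex))
        dps = []
        for _ in range(reps):
            reg = MutationRegistry()
            pop = Population.founding("P1", small_params(N=N), reg)
            seed_variant(pop, reg, [0.0, 0.0], rows=rows)
            nxt = next_generation(pop, None, rng)
            p1 = float(nxt.G.sum()) / nxt.total_copies if nxt.n_segregating else 0.0
            dps.append(p1 - p0)
        dps = np.asarray(dps)
        assert abs(dps.mean()) < 4 * dps.std() / np.sqrt(reps)
        expected_var = p0 * (1 - p0) / copies
        assert abs(dps.var() - expected_var) < 0.25 * expected_var


class TestAlleleFrequencies:
    def test_absent_and_fixed(self, registry, rng):
        pop = Population.founding("P1", small_params(N=4), registry)
        assert allele_frequencies(pop) == {}
        m = seed_variant(pop, registry, [0.1, 0.0], rows=list(range(8)))
        assert allele_frequencies(pop)[m.id] == 1.0

    def test_haplodiploid_copy_weighting(self, registry):
        # 2 females + 2 males = 6 gene copies; one copy in one female -> 1/6
        pop = Population.founding("P1", small_params(system="haplodiploid", N=4), registry)
        m = seed_variant(pop, registry, [0.1, 0.0], rows=[0])
        assert allele_frequencies(pop)[m.id] == pytest.approx(1 / 6)


class TestFixAndPrune:
    def _two_pops(self, registry):
        params = small_params(N=4)
        P1 = Population.founding("P1", params, registry)
        P2 = Population.founding("P2", params, registry)
        return P1, P2

    def test_private_fixation_stays_segregating_before_hybridisation(self, registry):
        P1, P2 = self._two_pops(registry)
        m = seed_variant(P1, registry, [0.1, 0.0], rows=list(range(8)))
        fix_and_prune([P1, P2], per_population=False)
        assert m.id in allele_frequencies(P1)
        assert P1.substitutions == []

    def test_shared_fixation_pruned_and_phenotypes_conserved(self, registry):
        P1, P2 = self._two_pops(registry)
        m1 = seed_variant(P1, registry, [0.1, -0.2], rows=list(range(8)))
        m2 = seed_variant(P2, registry, [0.1, -0.2], rows=list(range(8)), position=100)
        # same mutation id must be fixed in both: use a genuinely shared one
        shared = seed_variant(P1, registry, [0.3, 0.0], rows=list(range(8)), position=50)
        j = int(np.searchsorted(P2.positions, 50))
        P2.G = np.insert(P2.G, j, 1, axis=1)
        P2.positions = np.insert(P2.positions, j, 50)
        P2.mut_ids = np.insert(P2.mut_ids, j, shared.id)
        P2.effects = np.insert(P2.effects, j, shared.effect.delta, axis=0)
        P2.dominance = np.insert(P2.dominance, j, 0.5)
        P2.prunable = np.insert(P2.prunable, j, True)
        P2._invalidate_caches()
        z1_before, z2_before = P1.phenotypes().copy(), P2.phenotypes().copy()
        fix_and_prune([P1, P2], per_population=False)
        assert shared.id not in allele_frequencies(P1)
        assert shared.id not in allele_frequencies(P2)
        assert shared.id in {m.id for m in P1.substitutions}
        # privately fixed mutations survive
        assert m1.id in allele_frequencies(P1)
        assert m2.id in allele_frequencies(P2)
        assert np.allclose(P1.phenotypes(), z1_before)
        assert np.allclose(P2.phenotypes(), z2_before)

    def test_per_population_pruning_preserves_fitness(self, registry, rng):
        params = small_params(N=6, mu=5e-4, r_bp=1e-5)
        pop = Population.founding("H", params, registry)
        for _ in range(30):
            pop = next_generation(pop, None, rng)
        surface = FitnessSurface(optimum=np.array([0.2, 0.1]))
        w_before = pop.fitnesses(surface).copy()
        fix_and_prune([pop], per_population=True)
        pop.check_invariants()
        assert np.allclose(pop.fitnesses(surface), w_before, rtol=1e-12, atol=1e-12)
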