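"""Matrix-backed populations and one-generation Wright–Fisher reproduction.

A :class:`Population` stores its haploid genome copies as the rows of a
uint8 presence/absence matrix over the currently segregating mutations
(columns, kept sorted by chromosome position). Individuals own consecutive
rows: two per diploid, four per tetraploid, two per haplodiploid female and
one per haplodiploid male (females are stored first). This layout lets a
whole generation — phenotypes, fitnesses, parent sampling, recombination,
and new mutations — run as a handful of vectorised array operations, which
is what makes the fixation-probability and scenario experiments tractable
on one CPU.

Reproduction is Wright–Fisher with fitness-proportional parentage: each of
the exactly-``N`` offspring draws its mother in proportion to female
fitness and (where it has a father) its father in proportion to male
fitness, independently and with replacement. Haplodiploid sons develop from
a single maternal gamete (arrhenotoky); tetraploid meiosis pairs the four
copies into two random bivalents and transmits one recombinant product from
each.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fgm import FitnessSurface, MutationEffect, draw_mutation_effects
from .genome import (
    FEMALE,
    MALE,
    SYSTEMS,
    HaploidGenome,
    Individual,
    Mutation,
    MutationRegistry,
    copies_for,
)

__all__ = [
    "PopulationParams",
    "Population",
    "SelectionCollapseError",
    "next_generation",
    "draw_gamete",
    "apply_new_mutations",
    "allele_frequencies",
    "fix_and_prune",
]


class SelectionCollapseError(RuntimeError):
    """Raised when every individual's fitness underflows to zero, so
    fitness-proportional parent sampling is undefined."""


@dataclass(frozen=True)
class PopulationParams:
    """Static per-population simulation parameters.

    mu is the per-site per-generation mutation rate, r_bp the per-basepair
    crossover rate, L the chromosome length in sites, n_dims the trait
    dimensionality, lambda_mean the mean full-expression mutation size, and
    h the (global) phenotypic dominance of heterozygous mutations.
    """

    system: str
    N_pop: int
    L: int = 1_000_000
    mu: float = 1e-8
    r_bp: float = 1e-6
    n_dims: int = 5
    lambda_mean: float = 0.2
    h: float = 0.5

    def __post_init__(self):
        if self.system not in SYSTEMS:
            raise ValueError(f"unknown system {self.system!r}")
        if self.N_pop < 2:
            raise ValueError("N_pop must be at least 2")
        for name in ("mu", "r_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.L < 1 or self.n_dims < 1:
            raise ValueError("L and n_dims must be >= 1")
        if not self.lambda_mean > 0:
            raise ValueError("lambda_mean must be positive")
        if not (0.0 <= self.h <= 1.0):
            raise ValueError("dominance h must lie in [0, 1]")


def _sex_counts(n: int) -> tuple[int, int]:
    """Exact 50:50 offspring sex counts: ceil(n/2) females, floor(n/2) males."""
    n_f = (n + 1) // 2
    return n_f, n - n_f


class Population:
    """A single panmictic population of one genetic system."""

    def __init__(
        self,
        label: str,
        params: PopulationParams,
        registry: MutationRegistry,
        sexes: np.ndarray,
        G: np.ndarray,
        positions: np.ndarray,
        mut_ids: np.ndarray,
        effects: np.ndarray,
        dominance: np.ndarray,
        prunable: np.ndarray,
        fixed_background: np.ndarray,
        substitutions: list[Mutation],
        generation: int = 0,
    ) -> None:
        self.label = label
        self.params = params
        self.registry = registry
        self.sexes = np.asarray(sexes, dtype=np.uint8)
        self.G = np.ascontiguousarray(G, dtype=np.uint8)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.mut_ids = np.asarray(mut_ids, dtype=np.int64)
        self.effects = np.asarray(effects, dtype=float).reshape(len(mut_ids), params.n_dims)
        self.dominance = np.asarray(dominance, dtype=float)
        self.prunable = np.asarray(prunable, dtype=bool)
        self.fixed_background = np.asarray(fixed_background, dtype=float)
        self.substitutions = substitutions
        self.generation = generation
        self._copies_cache = None
        self._row_start_cache = None
        self._invalidate_caches()

    # ---------------------------------------------------------------- layout

    @classmethod
    def founding(
        cls,
        label: str,
        params: PopulationParams,
        registry: MutationRegistry,
    ) -> "Population":
        """A monomorphic population with every phenotype at the origin."""
        n_f, n_m = _sex_counts(params.N_pop)
        sexes = np.concatenate(
            [np.zeros(n_f, dtype=np.uint8), np.ones(n_m, dtype=np.uint8)]
        )
        copies = np.array([copies_for(params.system, s) for s in sexes])
        R = int(copies.sum())
        n = params.n_dims
        return cls(
            label=label,
            params=params,
            registry=registry,
            sexes=sexes,
            G=np.zeros((R, 0), dtype=np.uint8),
            positions=np.zeros(0, dtype=np.int64),
            mut_ids=np.zeros(0, dtype=np.int64),
            effects=np.zeros((0, n)),
            dominance=np.zeros(0),
            prunable=np.zeros(0, dtype=bool),
            fixed_background=np.zeros(n),
            substitutions=[],
            generation=0,
        )

    @property
    def size(self) -> int:
        return int(self.sexes.size)

    @property
    def n_females(self) -> int:
        return int(np.count_nonzero(self.sexes == FEMALE))

    @property
    def n_males(self) -> int:
        return self.size - self.n_females

    @property
    def n_segregating(self) -> int:
        return int(self.mut_ids.size)

    @property
    def copies_per_individual(self) -> np.ndarray:
        cached = self._copies_cache
        if cached is None:
            if self.params.system == "diploid":
                cached = np.full(self.size, 2, dtype=np.int64)
            elif self.params.system == "tetraploid":
                cached = np.full(self.size, 4, dtype=np.int64)
            else:
                cached = np.where(self.sexes == FEMALE, 2, 1).astype(np.int64)
            self._copies_cache = cached
        return cached

    @property
    def row_start(self) -> np.ndarray:
        cached = self._row_start_cache
        if cached is None:
            c = self.copies_per_individual
            cached = np.zeros(self.size, dtype=np.int64)
            np.cumsum(c[:-1], out=cached[1:])
            self._row_start_cache = cached
        return cached

    @property
    def total_copies(self) -> int:
        return int(self.G.shape[0])

    # ------------------------------------------------------------- genetics

    def _invalidate_caches(self) -> None:
        self._counts_cache = None
        self._phenotype_cache = None
        self._fitness_cache = None

    def counts(self) -> np.ndarray:
        """Per-individual mutation copy numbers, shape (N, M)."""
        cached = self._counts_cache
        if cached is not None:
            return cached
        if self.n_segregating == 0:
            cached = np.zeros((self.size, 0), dtype=np.uint8)
        else:
            # segments are <= 4 rows, so uint8 sums cannot overflow
            cached = np.add.reduceat(self.G, self.row_start, axis=0)
        self._counts_cache = cached
        return cached

    def _expression_weights(self, counts: np.ndarray) -> np.ndarray:
        """Dosage-to-expression weights, shape (N, M)."""
        system = self.params.system
        if system == "tetraploid":
            return counts / 4.0
        W = np.zeros(counts.shape, dtype=float)
        if system == "diploid":
            W += (counts == 1) * self.dominance[None, :]
            W += counts == 2
            return W
        # haplodiploid: females as diploids, males express carried alleles fully
        fem = self.sexes == FEMALE
        W[fem] = (counts[fem] == 1) * self.dominance[None, :] + (counts[fem] == 2)
        W[~fem] = counts[~fem]
        return W

    def phenotypes(self) -> np.ndarray:
        """Phenotype of every individual, shape (N, n_dims)."""
        cached = self._phenotype_cache
        if cached is not None:
            return cached
        if self.n_segregating == 0:
            cached = np.tile(self.fixed_background, (self.size, 1))
        else:
            W = self._expression_weights(self.counts())
            cached = self.fixed_background[None, :] + W @ self.effects
        self._phenotype_cache = cached
        return cached

    def fitnesses(
        self,
        surface: FitnessSurface | None,
        fitness_modifier=None,
    ) -> np.ndarray:
        """Per-individual fitness; a None surface means neutrality (all 1)."""
        cached = self._fitness_cache
        if cached is not None and cached[0] is surface and cached[1] is fitness_modifier:
            return cached[2]
        if surface is None:
            w = np.ones(self.size)
        else:
            z = self.phenotypes()
            if surface.n_dims != self.params.n_dims:
                raise ValueError("surface dimensionality does not match population")
            diff = z - surface.optimum[None, :]
            x = np.sqrt(np.einsum("ij,ij->i", diff, diff))
            w = surface.fitness_from_distance(x)
        if fitness_modifier is not None:
            w = w * fitness_modifier(self)
        self._fitness_cache = (surface, fitness_modifier, w)
        return w

    def allele_frequency_array(self) -> np.ndarray:
        """Frequency of each segregating column over all gene copies."""
        if self.n_segregating == 0:
            return np.zeros(0)
        return self.G.sum(axis=0, dtype=np.int64) / self.total_copies

    # ----------------------------------------------------------- object view

    def individuals(self) -> list[Individual]:
        """Object-level view of the population (for inspection and tests)."""
        reg = self.registry.mutations
        out = []
        rs = self.row_start
        copies = self.copies_per_individual
        for i in range(self.size):
            genomes = []
            for r in range(rs[i], rs[i] + copies[i]):
                cols = np.nonzero(self.G[r])[0]
                genomes.append(
                    HaploidGenome(tuple(reg[int(self.mut_ids[c])] for c in cols))
                )
            out.append(
                Individual(
                    sex="female" if self.sexes[i] == FEMALE else "male",
                    ploidy=int(copies[i]),
                    genomes=tuple(genomes),
                )
            )
        return out

    def check_invariants(self) -> None:
        """Raise if internal state is inconsistent (used heavily in tests)."""
        assert self.G.shape == (int(self.copies_per_individual.sum()), self.mut_ids.size)
        assert np.all(np.diff(self.positions) >= 0), "columns not sorted by position"
        assert len(set(self.mut_ids.tolist())) == self.mut_ids.size, "duplicate ids"
        assert np.all((self.positions >= 0) & (self.positions < self.params.L))
        seg = set(self.mut_ids.tolist())
        assert not seg & {m.id for m in self.substitutions}, (
            "mutation both segregating and substituted"
        )
        assert np.all(np.isfinite(self.fixed_background))


# ------------------------------------------------------------------ kernels


def _weighted_indices(rng: np.random.Generator, weights: np.ndarray, size: int) -> np.ndarray:
    """Sample `size` indices with probability proportional to weights."""
    cdf = np.cumsum(weights)
    total = cdf[-1]
    if not (total > 0) or not np.isfinite(total):
        raise SelectionCollapseError(
            "all fitnesses are zero (or non-finite): selection cannot choose parents"
        )
    u = rng.random(size) * total
    return np.searchsorted(cdf, u, side="right").astype(np.int64)


def _recombine_batch(
    G: np.ndarray,
    rows_a: np.ndarray,
    rows_b: np.ndarray,
    positions: np.ndarray,
    r_bp: float,
    L: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Produce one recombinant product per (rows_a[i], rows_b[i]) pair.

    Crossover count is Poisson(r_bp * L) per product, crossover points are
    uniform on [0, L), the product alternates between the two parental
    copies at each crossover, and the starting copy is chosen with
    probability 1/2.
    """
    n_pair = len(rows_a)
    k = rng.poisson(r_bp * L, n_pair) if r_bp > 0 else np.zeros(n_pair, dtype=np.int64)
    start = rng.integers(0, 2, n_pair)
    M = positions.size
    if M == 0:
        return np.zeros((n_pair, 0), dtype=np.uint8)
    kmax = int(k.max()) if n_pair else 0
    if kmax == 0:
        parity = np.broadcast_to(start[:, None], (n_pair, M))
    else:
        bp = rng.uniform(0.0, float(L), (n_pair, kmax))
        # segment parity at each site = (#crossovers left of it + start) mod 2;
        # handled per crossover-count class to avoid a padded 3-D broadcast
        parity = np.empty((n_pair, M), dtype=np.int64)
        for kv in np.unique(k):
            sel = k == kv
            if kv == 0:
                parity[sel] = start[sel, None]
            else:
                cnt = (bp[sel, None, :kv] <= positions[None, :, None]).sum(axis=2)
                parity[sel] = (cnt + start[sel, None]) & 1
    A = G[rows_a]
    B = G[rows_b]
    return np.where(parity == 0, A, B).astype(np.uint8)


def _mutate_rows(
    G: np.ndarray,
    positions: np.ndarray,
    mut_ids: np.ndarray,
    effects: np.ndarray,
    dominance: np.ndarray,
    prunable: np.ndarray,
    params: PopulationParams,
    generation: int,
    label: str,
    registry: MutationRegistry,
    rng: np.random.Generator,
):
    """Sprinkle new mutations over gamete rows; returns extended column state.

    Each row receives Poisson(mu * L) new mutations at uniform integer
    positions; a position already occupied simply gains an additional,
    independent mutation record (finite sites with stacking).
    """
    R = G.shape[0]
    if params.mu <= 0:
        return G, positions, mut_ids, effects, dominance, prunable
    per_row = rng.poisson(params.mu * params.L, R)
    total = int(per_row.sum())
    if total == 0:
        return G, positions, mut_ids, effects, dominance, prunable
    new_pos = rng.integers(0, params.L, total)
    deltas = draw_mutation_effects(params.n_dims, params.lambda_mean, total, rng)
    ids = registry.register_batch(new_pos, deltas, params.h, generation, label)
    rows = np.repeat(np.arange(R), per_row)

    M = positions.size
    G2 = np.zeros((R, M + total), dtype=np.uint8)
    G2[:, :M] = G
    G2[rows, M + np.arange(total)] = 1
    pos2 = np.concatenate([positions, new_pos])
    order = np.argsort(pos2, kind="stable")
    return (
        G2[:, order],
        pos2[order],
        np.concatenate([mut_ids, ids])[order],
        np.concatenate([effects, deltas])[order],
        np.concatenate([dominance, np.full(total, params.h)])[order],
        np.concatenate([prunable, np.ones(total, dtype=bool)])[order],
    )


def _maternal_paternal_rows(pop: Population, parents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row indices of the two genome copies of each (diploid-like) parent."""
    rs = pop.row_start[parents]
    return rs, rs + 1


def _tetraploid_bivalents(
    pop: Population, parents: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly pair each tetraploid parent's four copies into two bivalents.

    Returns (rows_a, rows_b), each of shape (2 * len(parents),): consecutive
    entries are the two bivalents of one gamete.
    """
    rs = pop.row_start[parents]
    n = len(parents)
    # random permutation of the 4 copies per parent via random-key sort
    keys = rng.random((n, 4))
    perm = np.argsort(keys, axis=1)
    rows = rs[:, None] + perm  # (n, 4)
    rows_a = rows[:, [0, 2]].reshape(-1)
    rows_b = rows[:, [1, 3]].reshape(-1)
    return rows_a, rows_b


def next_generation(
    pop: Population,
    surface: FitnessSurface | None,
    rng: np.random.Generator,
    n_offspring: int | None = None,
    fitness_modifier=None,
) -> Population:
    """One generation of Wright–Fisher reproduction with selection.

    Produces exactly ``n_offspring`` (default: the configured N_pop)
    offspring with exact 50:50 sex counts. Mothers are sampled with
    probability proportional to female fitness, fathers to male fitness,
    independently per offspring and with replacement. Lost mutations are
    dropped from the matrix; fixed mutations are retained for
    :func:`fix_and_prune` to handle.
    """
    if pop.size == 0:
        raise ValueError("cannot reproduce an empty population")
    n_f_par = pop.n_females
    if n_f_par == 0 or pop.n_males == 0:
        raise ValueError("both sexes must be present to reproduce")
    N_off = pop.params.N_pop if n_offspring is None else int(n_offspring)
    if N_off < 1:
        raise ValueError("offspring count must be >= 1")
    n_f, n_m = _sex_counts(N_off)

    w = pop.fitnesses(surface, fitness_modifier)
    w_fem = w[:n_f_par]
    w_mal = w[n_f_par:]

    system = pop.params.system
    params = pop.params
    p = pop.positions

    if system == "haplodiploid":
        # sons are fatherless: fathers sampled only for daughters
        mothers = _weighted_indices(rng, w_fem, N_off)
        fathers = n_f_par + _weighted_indices(rng, w_mal, n_f)
        mat_a, mat_b = _maternal_paternal_rows(pop, mothers)
        maternal = _recombine_batch(pop.G, mat_a, mat_b, p, params.r_bp, params.L, rng)
        # haploid fathers transmit their single copy verbatim (no recombination)
        paternal = pop.G[pop.row_start[fathers]]
        R_new = 2 * n_f + n_m
        G_new = np.empty((R_new, p.size), dtype=np.uint8)
        G_new[0 : 2 * n_f : 2] = maternal[:n_f]
        G_new[1 : 2 * n_f : 2] = paternal
        G_new[2 * n_f :] = maternal[n_f:]
    elif system == "diploid":
        mothers = _weighted_indices(rng, w_fem, N_off)
        fathers = n_f_par + _weighted_indices(rng, w_mal, N_off)
        mat_a, mat_b = _maternal_paternal_rows(pop, mothers)
        pat_a, pat_b = _maternal_paternal_rows(pop, fathers)
        maternal = _recombine_batch(pop.G, mat_a, mat_b, p, params.r_bp, params.L, rng)
        paternal = _recombine_batch(pop.G, pat_a, pat_b, p, params.r_bp, params.L, rng)
        G_new = np.empty((2 * N_off, p.size), dtype=np.uint8)
        G_new[0::2] = maternal
        G_new[1::2] = paternal
    else:  # tetraploid: diploid gametes, one product per random bivalent
        mothers = _weighted_indices(rng, w_fem, N_off)
        fathers = n_f_par + _weighted_indices(rng, w_mal, N_off)
        ma, mb = _tetraploid_bivalents(pop, mothers, rng)
        pa, pb = _tetraploid_bivalents(pop, fathers, rng)
        maternal = _recombine_batch(pop.G, ma, mb, p, params.r_bp, params.L, rng)
        paternal = _recombine_batch(pop.G, pa, pb, p, params.r_bp, params.L, rng)
        G_new = np.empty((4 * N_off, p.size), dtype=np.uint8)
        G_new[0::4] = maternal[0::2]
        G_new[1::4] = maternal[1::2]
        G_new[2::4] = paternal[0::2]
        G_new[3::4] = paternal[1::2]

    gen_new = pop.generation + 1
    G_new, pos, ids, eff, dom, prn = _mutate_rows(
        G_new,
        p,
        pop.mut_ids,
        pop.effects,
        pop.dominance,
        pop.prunable,
        params,
        gen_new,
        pop.label,
        pop.registry,
        rng,
    )

    # drop columns lost from the population
    colsum = G_new.sum(axis=0, dtype=np.int64)
    keep = colsum > 0
    if not keep.all():
        G_new = np.ascontiguousarray(G_new[:, keep])
        pos, ids, eff, dom, prn = pos[keep], ids[keep], eff[keep], dom[keep], prn[keep]

    sexes = np.concatenate(
        [np.zeros(n_f, dtype=np.uint8), np.ones(n_m, dtype=np.uint8)]
    )
    return Population(
        label=pop.label,
        params=params if N_off == params.N_pop else replace(params, N_pop=N_off),
        registry=pop.registry,
        sexes=sexes,
        G=G_new,
        positions=pos,
        mut_ids=ids,
        effects=eff,
        dominance=dom,
        prunable=prn,
        fixed_background=pop.fixed_background,
        substitutions=list(pop.substitutions),
        generation=gen_new,
    )


# -------------------------------------------------- object-level operations


def _genomes_to_columns(genomes: tuple[HaploidGenome, ...]):
    """Build a small presence matrix from an individual's genome copies."""
    muts: dict[int, Mutation] = {}
    for g in genomes:
        for m in g.mutations:
            muts[m.id] = m
    ordered = sorted(muts.values(), key=lambda m: (m.position, m.id))
    col_of = {m.id: j for j, m in enumerate(ordered)}
    G = np.zeros((len(genomes), len(ordered)), dtype=np.uint8)
    for r, g in enumerate(genomes):
        for m in g.mutations:
            G[r, col_of[m.id]] = 1
    positions = np.array([m.position for m in ordered], dtype=np.int64)
    return G, positions, ordered


def draw_gamete(
    parent: Individual,
    r_bp: float,
    L: int,
    rng: np.random.Generator,
):
    """Draw one gamete from a parent.

    Haploid parents transmit their single copy unchanged (no recombination).
    Diploid parents return one recombinant :class:`HaploidGenome`.
    Tetraploid parents return a tuple of two :class:`HaploidGenome` — one
    recombinant product from each of two randomly paired bivalents (the
    gamete is diploid).
    """
    if parent.ploidy == 1:
        return parent.genomes[0]
    G, positions, ordered = _genomes_to_columns(parent.genomes)
    if parent.ploidy == 2:
        out = _recombine_batch(
            G, np.array([0]), np.array([1]), positions, r_bp, L, rng
        )[0]
        return HaploidGenome(tuple(m for j, m in enumerate(ordered) if out[j]))
    # tetraploid: random bivalent pairing via a random permutation of copies
    perm = np.argsort(rng.random(4))
    rows_a = perm[[0, 2]]
    rows_b = perm[[1, 3]]
    out = _recombine_batch(G, rows_a, rows_b, positions, r_bp, L, rng)
    return tuple(
        HaploidGenome(tuple(m for j, m in enumerate(ordered) if row[j]))
        for row in out
    )


def apply_new_mutations(
    gamete: HaploidGenome,
    mu: float,
    L: int,
    n: int,
    lambda_mean: float,
    h: float,
    generation: int,
    pop_label: str,
    rng: np.random.Generator,
    registry: MutationRegistry | None = None,
) -> HaploidGenome:
    """Add Poisson(mu * L) new mutations to a gamete at uniform positions."""
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    registry = registry if registry is not None else MutationRegistry()
    k = int(rng.poisson(mu * L)) if mu > 0 else 0
    if k == 0:
        return gamete
    new_pos = rng.integers(0, L, k)
    deltas = draw_mutation_effects(n, lambda_mean, k, rng)
    new = [
        registry.register(int(pos), delta, h, generation, pop_label)
        for pos, delta in zip(new_pos, deltas)
    ]
    return HaploidGenome(tuple(gamete.mutations) + tuple(new))


def allele_frequencies(pop: Population) -> dict[int, float]:
    """Frequency of every segregating mutation over all gene copies.

    Gene copies are rows of the genome matrix, so haplodiploid totals
    automatically count two copies per female and one per male.
    """
    freqs = pop.allele_frequency_array()
    return {int(i): float(f) for i, f in zip(pop.mut_ids, freqs)}


def fix_and_prune(
    pops: list[Population],
    per_population: bool = False,
) -> list[Population]:
    """Fold fixed mutations into the constant background (in place).

    Before hybridisation (``per_population=False``) a mutation may be
    pruned only if it is fixed in *every* population in ``pops``: a
    mutation fixed in one parent but absent from the other must stay
    segregating so a future hybrid can be polymorphic for it. After the
    hybrid exists the populations never exchange genes again, so pruning is
    per population. Pruning never changes any phenotype or fitness.
    """
    if per_population:
        for pop in pops:
            _prune_one(pop, None)
    else:
        if not pops:
            return pops
        fixed_sets = []
        for pop in pops:
            freqs = pop.allele_frequency_array()
            fixed_sets.append(
                {int(i) for i, f in zip(pop.mut_ids, freqs) if f >= 1.0}
            )
        shared_fixed = set.intersection(*fixed_sets)
        for pop in pops:
            _prune_one(pop, shared_fixed)
    return pops


def _prune_one(pop: Population, allowed: set[int] | None) -> None:
    """Move fixed, prunable columns into the substitution ledger."""
    if pop.n_segregating == 0:
        return
    colsum = pop.G.sum(axis=0, dtype=np.int64)
    fixed = (colsum == pop.total_copies) & pop.prunable
    if allowed is not None:
        fixed &= np.isin(pop.mut_ids, np.fromiter(allowed, dtype=np.int64, count=len(allowed))) if allowed else np.zeros_like(fixed)
    if not fixed.any():
        return
    # a fixed column contributes its full delta to every individual
    pop.fixed_background = pop.fixed_background + pop.effects[fixed].sum(axis=0)
    pop.substitutions = pop.substitutions + [
        pop.registry.mutations[int(i)] for i in pop.mut_ids[fixed]
    ]
    keep = ~fixed
    pop.G = np.ascontiguousarray(pop.G[:, keep])
    pop.positions = pop.positions[keep]
    pop.mut_ids = pop.mut_ids[keep]
    pop.effects = pop.effects[keep]
    pop.dominance = pop.dominance[keep]
    pop.prunable = pop.prunable[keep]
    pop._invalidate_caches()
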