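"""Population-genetic validation experiments.

These drive the simulator's reproduction machinery through settings with
known theoretical expectations: the fixation probability of a new
beneficial mutation (2hs in diploids; (1/3)2s + (2/3)2hs in haplodiploids,
reflecting the one third of gene copies that are exposed haploid in males),
and neutral diversity at mutation–drift equilibrium (pi = 4 Ne mu with
Ne = gene copies / 2).

To realise an exact selection coefficient inside the model's geometry, the
trials use a one-dimensional trait with surface shape q = 1/2, i.e. fitness
exp(-|x|): a mutation of size d = log(1 + s) pointing at a distant optimum
has relative fitness exactly 1 + s when fully expressed. The classical
anchors are statements about selective advantages on the fitness scale
(2hs is Haldane's 2 x heterozygous advantage), so the trials use the
dominance value that makes the heterozygous fitness ratio exactly 1 + h*s,
namely log(1 + h*s) / log(1 + s); phenotype-scale dominance 0.5 would give
sqrt(1 + s) - 1, an O(s^2) distortion of the premise being tested.
"""

from __future__ import annotations

import numpy as np

from .fgm import FitnessSurface
from .genome import MutationRegistry
from .population import Population, PopulationParams, next_generation

__all__ = [
    "single_mutant_population",
    "fixation_probability",
    "fixation_theory",
    "neutral_diversity",
]


def single_mutant_population(
    system: str,
    N: int,
    effect_size: float,
    registry: MutationRegistry,
    rng: np.random.Generator,
    copies: int = 1,
    wildtype_distance: float = 1.0,
    dominance: float = 0.5,
) -> tuple[Population, FitnessSurface]:
    """A monomorphic population carrying one mutant allele in ``copies``
    random gene copies.

    The wild-type phenotype sits ``wildtype_distance`` below the optimum on
    a single trait axis; the mutation moves its carrier ``effect_size``
    toward the optimum. With the exp(-|x|) surface this gives the mutant a
    relative fitness advantage of exactly ``exp(effect_size) - 1`` at full
    expression and ``exp(dominance * effect_size) - 1`` when heterozygous.
    The mutant row is chosen uniformly over gene copies, so in
    haplodiploids it starts in a female with probability 2/3.
    """
    params = PopulationParams(
        system=system,
        N_pop=N,
        L=1000,
        mu=0.0,
        r_bp=0.0,
        n_dims=1,
        lambda_mean=max(effect_size, 1e-6),
        h=dominance,
    )
    pop = Population.founding("P1", params, registry)
    mut = registry.register(0, np.array([effect_size]), dominance, 0, "P1")
    row = int(rng.integers(0, pop.total_copies)) if copies == 1 else None
    G = np.zeros((pop.total_copies, 1), dtype=np.uint8)
    if copies == 1:
        G[row, 0] = 1
    else:
        rows = rng.choice(pop.total_copies, size=copies, replace=False)
        G[rows, 0] = 1
    pop.G = G
    pop.positions = np.array([0], dtype=np.int64)
    pop.mut_ids = np.array([mut.id], dtype=np.int64)
    pop.effects = np.array([[effect_size]])
    pop.dominance = np.array([dominance])
    pop.prunable = np.array([True])
    surface = FitnessSurface(optimum=np.array([wildtype_distance]), shape=0.5)
    return pop, surface


def fixation_probability(
    system: str,
    N: int,
    s: float,
    trials: int,
    rng: np.random.Generator,
    neutral: bool = False,
    copies: int = 1,
    h: float = 0.5,
    max_generations: int = 100_000,
) -> tuple[float, float]:
    """Monte-Carlo fixation probability of a mutant allele.

    Each trial seeds one mutant lineage (``copies`` gene copies) into a
    monomorphic Wright–Fisher population and follows it to loss or
    fixation. ``s`` is the full-expression selective advantage and ``h``
    the dominance of that advantage on the fitness scale: heterozygotes
    have relative fitness exactly ``1 + h*s`` (the quantity Haldane's
    ``2hs`` refers to). ``neutral=True`` runs with a flat fitness surface.
    Returns (estimate, standard error).
    """
    effect = float(np.log1p(s))
    dom = float(np.log1p(h * s) / np.log1p(s)) if s > 0 else 0.5
    fixed = 0
    for _ in range(trials):
        registry = MutationRegistry()
        pop, surface = single_mutant_population(
            system, N, effect, registry, rng, copies=copies, dominance=dom
        )
        surf = None if neutral else surface
        for _ in range(max_generations):
            pop = next_generation(pop, surf, rng)
            if pop.n_segregating == 0:
                break
            if int(pop.G.sum()) == pop.total_copies:
                fixed += 1
                break
        else:  # pragma: no cover
            raise RuntimeError("fixation trial failed to absorb")
    p = fixed / trials
    se = float(np.sqrt(p * (1 - p) / trials))
    return p, se


def fixation_theory(system: str, s: float, h: float = 0.5, exact: bool = False) -> float:
    """Branching-process fixation probability for a beneficial mutation.

    First order in s (default): diploids 2hs; haplodiploids, where a new
    mutation arises in a haploid male copy with probability 1/3 (fully
    exposed, advantage s) and in a diploid female copy with probability 2/3
    (advantage hs), (1/3) 2s + (2/3) 2hs.

    ``exact=True`` returns the exact survival probability of the
    Poisson-offspring branching process these formulas are the first-order
    expansion of — the value a Wright–Fisher simulation converges to. For
    diploids it solves ``u = 1 - exp(-(1 + hs) u)`` (a heterozygous carrier
    transmits Poisson(1 + hs) mutant copies). For haplodiploids it solves
    the two-type system — a copy in a heterozygous female seeds
    Poisson((1+hs)/2) copies in each sex, a copy in a male seeds
    Poisson(1+s) copies in females only::

        u_f = 1 - exp(-((1 + hs)/2)(u_f + u_m))
        u_m = 1 - exp(-(1 + s) u_f)

    and returns (2/3) u_f + (1/3) u_m for a uniformly placed new copy.
    """
    if system not in ("diploid", "haplodiploid"):
        raise ValueError("fixation theory implemented for diploid and haplodiploid")
    if not exact:
        if system == "diploid":
            return 2 * h * s
        return (1.0 / 3.0) * 2 * s + (2.0 / 3.0) * 2 * h * s
    if s <= 0:
        return 0.0
    from scipy.optimize import fsolve

    if system == "diploid":
        (u,) = fsolve(lambda u: 1.0 - np.exp(-(1.0 + h * s) * u) - u, 2 * h * s)
        return float(u)

    def equations(x):
        u_f, u_m = x
        return [
            1.0 - np.exp(-((1.0 + h * s) / 2.0) * (u_f + u_m)) - u_f,
            1.0 - np.exp(-(1.0 + s) * u_f) - u_m,
        ]

    guess = (1.0 / 3.0) * 2 * s + (2.0 / 3.0) * 2 * h * s
    u_f, u_m = fsolve(equations, [guess, guess])
    return float((2.0 / 3.0) * u_f + (1.0 / 3.0) * u_m)


def neutral_diversity(
    system: str,
    N: int,
    mu: float,
    L: int,
    generations: int,
    burn_in: int,
    replicates: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Mean equilibrium heterozygosity under pure drift (selection off).

    Runs ``replicates`` independent populations with a flat fitness
    surface, discards ``burn_in`` generations, and averages per-site pi
    over the remaining generations. Returns (mean pi, theory 4 Ne mu) with
    Ne = gene copies / 2.
    """
    from .stats import expected_heterozygosity

    params = PopulationParams(
        system=system, N_pop=N, L=L, mu=mu, r_bp=0.0, n_dims=1, lambda_mean=0.2, h=0.5
    )
    pis = []
    for _ in range(replicates):
        registry = MutationRegistry()
        pop = Population.founding("P1", params, registry)
        for g in range(generations):
            pop = next_generation(pop, None, rng)
            if g >= burn_in:
                pis.append(expected_heterozygosity(pop))
    ne = pop.total_copies / 2.0
    return float(np.mean(pis)), 4.0 * ne * mu
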