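"""Model extensions: intrinsic incompatibilities, demography, parameter sweeps.

Bateson–Dobzhansky–Muller incompatibilities (BDMIs) are pairs of loci whose
derived alleles arose in different lineages and reduce fitness only when an
individual carries both; they are intrinsic in the sense that the cost does
not depend on the environment. Here each pair is seeded at hybridisation
time as two phenotypically silent marker loci, one fixed in each parent, so
parents never pay a cost while hybrids segregate for both sides.

Demographic mode replaces constant census size with Poisson fecundity
scaled by mean fitness and truncated at a carrying capacity, allowing
decline and extinction after an environmental shift — and evolutionary
rescue when adaptation outpaces the decline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import FEMALE, Individual, MutationRegistry
from .population import Population

__all__ = [
    "BdmiLocus",
    "BdmiPair",
    "BdmiSettings",
    "DEFAULT_BDMI_DOMINANCE",
    "seed_bdmi_markers",
    "bdmi_fitness_multiplier",
    "bdmi_modifier",
    "DemographySettings",
    "demographic_update",
    "sweep",
]

# Cost multiplier per joint genotype class (rows: dosage class of the P1
# allele; columns: P2 allele). Classes: 0 = absent, 1 = partial dosage,
# 2 = full dosage. The default is multiplicative in dosage fractions
# (het = 1/2), so a double heterozygote pays cost/4 and the cost vanishes
# whenever either allele is absent.
DEFAULT_BDMI_DOMINANCE = np.array(
    [
        [0.0, 0.0, 0.0],
        [0.0, 0.25, 0.5],
        [0.0, 0.5, 1.0],
    ]
)


@dataclass(frozen=True)
class BdmiLocus:
    position: int
    lineage: str  # which parent the derived allele is fixed in: "P1" | "P2"
    mutation_id: int


@dataclass(frozen=True)
class BdmiPair:
    """One pairwise incompatibility between a P1-derived and P2-derived allele."""

    locus_a: BdmiLocus
    locus_b: BdmiLocus
    cost: float
    dominance_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_BDMI_DOMINANCE.copy()
    )

    def __post_init__(self):
        if not (0.0 <= self.cost <= 1.0):
            raise ValueError("BDMI cost must lie in [0, 1]")
        m = np.asarray(self.dominance_matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("dominance_matrix must be 3x3 (absent/partial/full)")
        if np.any(m[0, :] != 0.0) or np.any(m[:, 0] != 0.0):
            raise ValueError("cost multiplier must be 0 when either allele is absent")
        object.__setattr__(self, "dominance_matrix", m)


@dataclass(frozen=True)
class BdmiSettings:
    """Configuration for seeding intrinsic incompatibilities at hybridisation."""

    n_pairs: int = 1
    cost: float = 0.1
    dominance_matrix: tuple | None = None  # defaults to dosage-multiplicative

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not (0.0 <= self.cost <= 1.0):
            raise ValueError("cost must lie in [0, 1]")

    def matrix(self) -> np.ndarray:
        if self.dominance_matrix is None:
            return DEFAULT_BDMI_DOMINANCE.copy()
        return np.asarray(self.dominance_matrix, dtype=float)


def _insert_fixed_marker(pop: Population, mutation) -> None:
    """Insert a column fixed in every gene copy, keeping positions sorted."""
    j = int(np.searchsorted(pop.positions, mutation.position))
    pop.G = np.insert(pop.G, j, 1, axis=1)
    pop.positions = np.insert(pop.positions, j, mutation.position)
    pop.mut_ids = np.insert(pop.mut_ids, j, mutation.id)
    pop.effects = np.insert(pop.effects, j, mutation.effect.delta, axis=0)
    pop.dominance = np.insert(pop.dominance, j, mutation.effect.dominance_h)
    pop.prunable = np.insert(pop.prunable, j, False)
    pop._invalidate_caches()


def seed_bdmi_markers(
    P1: Population,
    P2: Population,
    settings: BdmiSettings,
    registry: MutationRegistry,
) -> list[BdmiPair]:
    """Fix one phenotypically silent marker per pair alternately in P1/P2.

    Markers are zero-effect mutations at deterministic, evenly spaced
    positions, flagged non-prunable so they are never folded into the fixed
    background (the incompatibility cost needs their dosage). Must be
    called just before hybrid creation.
    """
    n = P1.params.n_dims
    L = P1.params.L
    gen = P1.generation
    pairs = []
    k = settings.n_pairs
    for i in range(k):
        pos_a = int(L * (2 * i + 0.5) / (2 * k))
        pos_b = int(L * (2 * i + 1.5) / (2 * k))
        mut_a = registry.register(
            pos_a, np.zeros(n), P1.params.h, gen, "P1", prunable=False
        )
        mut_b = registry.register(
            pos_b, np.zeros(n), P2.params.h, gen, "P2", prunable=False
        )
        _insert_fixed_marker(P1, mut_a)
        _insert_fixed_marker(P2, mut_b)
        pairs.append(
            BdmiPair(
                locus_a=BdmiLocus(pos_a, "P1", mut_a.id),
                locus_b=BdmiLocus(pos_b, "P2", mut_b.id),
                cost=settings.cost,
                dominance_matrix=settings.matrix(),
            )
        )
    return pairs


def _dosage_class(copies: np.ndarray, ploidy: np.ndarray) -> np.ndarray:
    """0 = absent, 2 = full dosage, 1 = anything in between.

    Haploid carriers express fully, so one copy in a haplodiploid male is
    class 2 (ploidy 1)."""
    cls = np.ones_like(copies)
    cls[copies == 0] = 0
    cls[copies == ploidy] = 2
    return cls


def bdmi_fitness_multiplier(ind: Individual, pairs: list[BdmiPair]) -> float:
    """Multiplicative incompatibility penalty for one individual.

    ``prod over pairs of (1 - cost * m(class_a, class_b))`` where m comes
    from the pair's dominance matrix; carrying only one side of a pair
    costs nothing.
    """
    dosage = ind.dosage()
    mult = 1.0
    for pair in pairs:
        ca = dosage.get(pair.locus_a.mutation_id, 0)
        cb = dosage.get(pair.locus_b.mutation_id, 0)
        cls_a = 0 if ca == 0 else (2 if ca == ind.ploidy else 1)
        cls_b = 0 if cb == 0 else (2 if cb == ind.ploidy else 1)
        mult *= 1.0 - pair.cost * pair.dominance_matrix[cls_a, cls_b]
    return float(mult)


def bdmi_modifier(pairs: list[BdmiPair]):
    """A vectorised fitness modifier over a whole population.

    Returns a callable suitable for ``next_generation(fitness_modifier=...)``
    that computes the per-individual BDMI multiplier; a marker lost from a
    population simply contributes dosage 0.
    """

    def modifier(pop: Population) -> np.ndarray:
        ploidy = pop.copies_per_individual
        rs = pop.row_start
        mult = np.ones(pop.size)
        for pair in pairs:
            classes = []
            for locus in (pair.locus_a, pair.locus_b):
                col = np.nonzero(pop.mut_ids == locus.mutation_id)[0]
                if col.size == 0:
                    copies = np.zeros(pop.size, dtype=np.int64)
                else:
                    copies = np.add.reduceat(
                        pop.G[:, col[0]].astype(np.int64), rs
                    )
                classes.append(_dosage_class(copies, ploidy))
            mult *= 1.0 - pair.cost * pair.dominance_matrix[classes[0], classes[1]]
        return mult

    return modifier


# ------------------------------------------------------------- demography


@dataclass(frozen=True)
class DemographySettings:
    """Poisson fecundity demography with a carrying capacity.

    Next census size ~ min(Poisson(N * W_mean * growth_factor), K); the
    population is extinct when the drawn size falls to ``extinction_threshold``
    or below (sizes below 2 cannot reproduce and also count as extinct).
    """

    carrying_capacity: int
    growth_factor: float = 2.0
    extinction_threshold: int = 0

    def __post_init__(self):
        if self.carrying_capacity < self.extinction_threshold:
            raise ValueError("carrying capacity must be >= extinction threshold")
        if not self.growth_factor > 0:
            raise ValueError("growth_factor must be positive")
        if self.extinction_threshold < 0:
            raise ValueError("extinction_threshold must be >= 0")


def demographic_update(
    pop: Population,
    settings: DemographySettings,
    w_mean: float,
    rng: np.random.Generator,
) -> tuple[int, bool]:
    """Draw the next census size from the current mean fitness.

    Returns ``(size, extinct)``. Uses its own random stream (supplied by
    the caller) so that demography that never binds leaves the genetic
    dynamics untouched.
    """
    if not (0.0 <= w_mean <= 1.0):
        raise ValueError("mean fitness must lie in [0, 1]")
    lam = pop.size * w_mean * settings.growth_factor
    size = int(min(rng.poisson(lam), settings.carrying_capacity))
    extinct = size <= settings.extinction_threshold or size < 2
    return size, extinct


# ------------------------------------------------------------------ sweeps


def sweep(
    base_kwargs: dict,
    grid: dict[str, list],
    seed: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Run a scenario over a full factorial parameter grid.

    ``base_kwargs`` are keyword arguments for
    :func:`hybridfgm.scenarios.make_config` (plus optional ``preset`` naming
    one of the canonical scenarios); ``grid`` maps parameter names (h,
    lambda_mean, n_dims, shape_q, system, ...) to value lists. Each grid
    point runs with an independently derived seed. Invalid points are
    reported in the output (``error`` column) and do not abort the sweep.
    """
    import itertools

    from .scenarios import SYSTEM_DEFAULTS, make_config, preset, run_scenario

    keys = sorted(grid)
    points = list(itertools.product(*(grid[k] for k in keys)))
    root = np.random.SeedSequence(seed)
    seeds = root.generate_state(len(points))
    frames = []
    for i, values in enumerate(points):
        override = dict(zip(keys, values))
        kwargs = dict(base_kwargs)
        preset_name = kwargs.pop("preset", None)
        kwargs.update(override)
        # switching system implies that system's default N and r unless the
        # caller pinned them explicitly
        if "system" in override:
            for key in ("N_pop", "r_bp"):
                if key not in base_kwargs and key not in override:
                    kwargs.pop(key, None)
        kwargs["seed"] = int(seeds[i]) % (2**31)
        try:
            if preset_name is not None:
                system = kwargs.pop("system", "diploid")
                config = preset(preset_name, system=system, **kwargs)
            else:
                config = make_config(**kwargs)
            df = run_scenario(config, progress=progress)
            df["error"] = ""
        except (ValueError, TypeError) as exc:
            df = pd.DataFrame([{"error": str(exc)}])
        for k, v in override.items():
            df[k] = v
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
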