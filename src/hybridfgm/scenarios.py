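"""Two-phase adaptation scenarios: parental adaptation, hybrid creation,
and a shared novel environment.

The canonical design: two allopatric populations, P1 and P2, start
genetically identical (monomorphic, phenotype at the origin) and adapt for
``T_parental`` generations to identical or divergent optima. At generation
``T_parental`` a hybrid population H is founded from N/2 descendants of
each parent (no further gene flow), the optimum shifts for everyone, and
all three populations adapt independently to the novel environment while
per-generation statistics are recorded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fgm import FitnessSurface
from .genome import FEMALE, MALE, MutationRegistry, copies_for
from .population import (
    Population,
    PopulationParams,
    fix_and_prune,
    next_generation,
)
from . import stats as _stats

__all__ = [
    "OptimumSchedule",
    "ScenarioConfig",
    "make_config",
    "preset",
    "PRESET_NAMES",
    "SYSTEM_DEFAULTS",
    "run_parental_phase",
    "create_hybrid_population",
    "run_novel_phase",
    "run_replicate",
    "run_scenario",
]

# N_pop and per-bp recombination rates scaled so diploids and haplodiploids
# have comparable effective sizes and population recombination rates. The
# tetraploid row matches the diploid gene-copy count (750 x 4 = 3000).
SYSTEM_DEFAULTS = {
    "diploid": {"N_pop": 1500, "r_bp": (2.0 / 3.0) * 1e-6},
    "haplodiploid": {"N_pop": 2000, "r_bp": 1e-6},
    "tetraploid": {"N_pop": 750, "r_bp": (2.0 / 3.0) * 1e-6},
}

POP_LABELS = ("P1", "P2", "H")


@dataclass(frozen=True)
class OptimumSchedule:
    """Per-population optimum change points.

    ``entries`` maps a population label to a tuple of ``(generation,
    optimum)`` pairs with strictly increasing generations. The optimum in
    force at generation g is the last change point at or before g. P1 and
    P2 must define a generation-0 optimum.
    """

    entries: dict[str, tuple[tuple[int, tuple[float, ...]], ...]]

    def __post_init__(self):
        norm: dict[str, tuple[tuple[int, tuple[float, ...]], ...]] = {}
        n_dims = None
        for label, points in self.entries.items():
            if label not in POP_LABELS:
                raise ValueError(f"unknown population label {label!r}")
            pts = []
            last_gen = -1
            for gen, opt in points:
                gen = int(gen)
                if gen <= last_gen:
                    raise ValueError(
                        f"schedule for {label} has non-increasing change points"
                    )
                last_gen = gen
                opt = tuple(float(v) for v in np.asarray(opt, dtype=float))
                if n_dims is None:
                    n_dims = len(opt)
                elif len(opt) != n_dims:
                    raise ValueError("all scheduled optima must share one length")
                pts.append((gen, opt))
            norm[label] = tuple(pts)
        for label in ("P1", "P2"):
            if label in norm and (not norm[label] or norm[label][0][0] != 0):
                raise ValueError(f"schedule for {label} must start at generation 0")
        object.__setattr__(self, "entries", norm)

    @property
    def n_dims(self) -> int:
        for pts in self.entries.values():
            for _, opt in pts:
                return len(opt)
        raise ValueError("empty schedule")

    def optimum_at(self, label: str, generation: int) -> np.ndarray:
        points = self.entries.get(label)
        if not points:
            raise ValueError(f"no schedule for population {label!r}")
        current = None
        for gen, opt in points:
            if gen <= generation:
                current = opt
        if current is None:
            raise ValueError(
                f"{label} has no optimum defined at generation {generation}"
            )
        return np.asarray(current, dtype=float)

    @classmethod
    def two_phase(
        cls,
        parental_p1,
        parental_p2,
        novel,
        t_shift: int,
    ) -> "OptimumSchedule":
        """The standard design: parental optima from generation 0, a shared
        novel optimum for P1, P2, and H from generation ``t_shift``."""
        novel = tuple(float(v) for v in novel)
        return cls(
            entries={
                "P1": ((0, tuple(parental_p1)), (t_shift, novel)),
                "P2": ((0, tuple(parental_p2)), (t_shift, novel)),
                "H": ((t_shift, novel),),
            }
        )


def _origin_schedule(n_dims: int, t_parental: int) -> OptimumSchedule:
    origin = (0.0,) * n_dims
    return OptimumSchedule.two_phase(origin, origin, origin, t_parental)


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete specification of one simulation scenario."""

    system: str
    N_pop: int
    L: int
    mu: float
    r_bp: float
    n_dims: int
    lambda_mean: float
    h: float
    shape_q: float
    schedule: OptimumSchedule
    T_parental: int = 1500
    T_novel: int = 1000
    replicates: int = 100
    seed: int = 0
    bdmi: object | None = None  # extensions.BdmiSettings
    demography: object | None = None  # extensions.DemographySettings

    def __post_init__(self):
        PopulationParams(
            system=self.system,
            N_pop=self.N_pop,
            L=self.L,
            mu=self.mu,
            r_bp=self.r_bp,
            n_dims=self.n_dims,
            lambda_mean=self.lambda_mean,
            h=self.h,
        )  # reuse its validation
        if self.T_parental < 1 or self.T_novel < 1:
            raise ValueError("T_parental and T_novel must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.shape_q > 0:
            raise ValueError("shape_q must be positive")
        if self.schedule.n_dims != self.n_dims:
            raise ValueError("schedule optima do not match n_dims")

    def population_params(self) -> PopulationParams:
        return PopulationParams(
            system=self.system,
            N_pop=self.N_pop,
            L=self.L,
            mu=self.mu,
            r_bp=self.r_bp,
            n_dims=self.n_dims,
            lambda_mean=self.lambda_mean,
            h=self.h,
        )

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)


def make_config(system: str = "diploid", schedule: OptimumSchedule | None = None, **kwargs) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` with defaults filled per system.

    Unspecified values fall back to the standard study conditions: one
    megabase, mu = 1e-8 per site, n = 5 trait dimensions, exponential
    mutation size with mean 0.2, codominant phenotypes (h = 0.5), Gaussian
    fitness (q = 1), and the system-specific N_pop and recombination rate.
    """
    if system not in SYSTEM_DEFAULTS:
        raise ValueError(
            f"unknown system {system!r}; expected one of {sorted(SYSTEM_DEFAULTS)}"
        )
    defaults = dict(
        system=system,
        N_pop=SYSTEM_DEFAULTS[system]["N_pop"],
        r_bp=SYSTEM_DEFAULTS[system]["r_bp"],
        L=1_000_000,
        mu=1e-8,
        n_dims=5,
        lambda_mean=0.2,
        h=0.5,
        shape_q=1.0,
        T_parental=1500,
        T_novel=1000,
        replicates=100,
        seed=0,
        bdmi=None,
        demography=None,
    )
    unknown = set(kwargs) - set(defaults)
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    defaults.update(kwargs)
    if schedule is None:
        schedule = _origin_schedule(defaults["n_dims"], defaults["T_parental"])
    return ScenarioConfig(schedule=schedule, **defaults)


# --------------------------------------------------------------- presets

_PRESET_OPTIMA = {
    # name: (P1 parental, P2 parental, shared novel)
    "fig2A": ((1, 0, 0, 0, 0), (1, 0, 0, 0, 0), (2, 0, 0, 0, 0)),
    "fig2B": ((3, 0, 0, 0, 0), (3, 0, 0, 0, 0), (2, 0, 0, 0, 0)),
    "fig2C": ((3, 0, 0, 0, 0), (3, 0, 0, 0, 0), (2.5, 0, 0, 0, 0)),
    "fig3A": ((3, 0, 0, 0, 0), (3, 0, 0, 0, 0), (0, 2, 0, 0, 0)),
    "fig3B": ((2, 0, 0, 0, 0), (0, 2, 0, 0, 0), (2, 2, 0, 0, 0)),
    "fig3C": ((2, 0, 0, 0, 0), (0, 2, 0, 0, 0), (0, 0, 2, 0, 0)),
}

PRESET_NAMES = tuple(_PRESET_OPTIMA)


def preset(name: str, system: str = "diploid", **overrides) -> ScenarioConfig:
    """One of the six canonical optimum-shift scenarios.

    A/B/C of the first family shift the optimum along the axis the parents
    adapted on; the second family shifts it to a different axis, with
    divergently adapted parents in B and C. Keyword overrides (e.g. a
    smaller ``N_pop`` or shorter phases for scaled-down runs) are applied
    after the preset defaults.
    """
    if name not in _PRESET_OPTIMA:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    p1, p2, novel = _PRESET_OPTIMA[name]
    t_par = int(overrides.get("T_parental", 1500))
    schedule = OptimumSchedule.two_phase(p1, p2, novel, t_par)
    return make_config(system=system, schedule=schedule, **overrides)


# ------------------------------------------------------------ simulation


def _surface(config: ScenarioConfig, label: str, generation: int) -> FitnessSurface:
    return FitnessSurface(
        optimum=config.schedule.optimum_at(label, generation),
        shape=config.shape_q,
    )


def _record(
    records: list,
    pop: Population,
    surface: FitnessSurface,
    config: ScenarioConfig,
    replicate: int,
    fitness_modifier=None,
) -> None:
    w_f, w_m, w_all = _stats.mean_fitness_by_sex(pop, surface, fitness_modifier)
    records.append(
        _stats.GenerationRecord(
            generation=pop.generation,
            population=pop.label,
            N=pop.size,
            mean_fitness_female=w_f,
            mean_fitness_male=w_m,
            mean_fitness_all=w_all,
            pi=_stats.expected_heterozygosity(pop),
            replicate=replicate,
        )
    )


def run_parental_phase(
    config: ScenarioConfig,
    rng_p1: np.random.Generator,
    rng_p2: np.random.Generator,
    registry: MutationRegistry | None = None,
    records: list | None = None,
    replicate: int = 0,
) -> tuple[Population, Population]:
    """Evolve the two allopatric parents for T_parental generations.

    Both start monomorphic at the origin. Each population has its own
    random stream, so seeding the two streams identically yields identical
    parental populations. Records (if requested) cover generations
    0 .. T_parental - 1 under the parental optima.
    """
    registry = registry if registry is not None else MutationRegistry()
    params = config.population_params()
    P1 = Population.founding("P1", params, registry)
    P2 = Population.founding("P2", params, registry)
    for g in range(config.T_parental):
        s1 = _surface(config, "P1", g)
        s2 = _surface(config, "P2", g)
        if records is not None:
            _record(records, P1, s1, config, replicate)
            _record(records, P2, s2, config, replicate)
        P1 = next_generation(P1, s1, rng_p1)
        P2 = next_generation(P2, s2, rng_p2)
        # cross-population pruning: only mutations fixed in *both* parents
        # may be folded away before the hybrid exists
        fix_and_prune([P1, P2], per_population=False)
    return P1, P2


def create_hybrid_population(
    P1: Population,
    P2: Population,
    rng: np.random.Generator,
    label: str = "H",
) -> Population:
    """Found the hybrid population from N/2 descendants of each parent.

    Exactly N/4 females and N/4 males are sampled uniformly without
    replacement from each parent, preserving 50:50 sexes and 50:50
    ancestry. Founders are copies; no state is shared with the parents and
    there is no later gene flow.
    """
    if P1.params != P2.params:
        raise ValueError("parent populations have mismatched parameters")
    if P1.params.system != P2.params.system:
        raise ValueError("parent populations have mismatched genetic systems")
    N = P1.params.N_pop
    if N % 4 != 0:
        raise ValueError("hybrid creation requires N_pop divisible by 4")
    if not np.array_equal(P1.fixed_background, P2.fixed_background):
        raise ValueError(
            "parents have diverged fixed backgrounds; shared pruning was violated"
        )
    quarter = N // 4

    def _pick(pop: Population, sex: int, k: int, rng) -> np.ndarray:
        idx = np.nonzero(pop.sexes == sex)[0]
        if idx.size < k:
            raise ValueError(f"parent {pop.label} lacks {k} individuals of a sex")
        return np.sort(rng.choice(idx, size=k, replace=False))

    sel = [
        (P1, _pick(P1, FEMALE, quarter, rng)),
        (P2, _pick(P2, FEMALE, quarter, rng)),
        (P1, _pick(P1, MALE, quarter, rng)),
        (P2, _pick(P2, MALE, quarter, rng)),
    ]

    # merged column set (ids are unique across populations via the shared registry)
    ids = np.concatenate([P1.mut_ids, P2.mut_ids])
    pos = np.concatenate([P1.positions, P2.positions])
    eff = np.vstack([P1.effects, P2.effects])
    dom = np.concatenate([P1.dominance, P2.dominance])
    prn = np.concatenate([P1.prunable, P2.prunable])
    uids, first = np.unique(ids, return_index=True)
    order = np.lexsort((uids, pos[first]))
    col_ids = uids[order]
    col_pos = pos[first][order]
    col_eff = eff[first][order]
    col_dom = dom[first][order]
    col_prn = prn[first][order]
    col_of = {int(i): j for j, i in enumerate(col_ids)}

    blocks = []
    sexes = []
    for pop, chosen in sel:
        rs = pop.row_start[chosen]
        copies = pop.copies_per_individual[chosen]
        rows = np.concatenate([np.arange(s, s + c) for s, c in zip(rs, copies)])
        sub = pop.G[rows]
        block = np.zeros((sub.shape[0], col_ids.size), dtype=np.uint8)
        if pop.mut_ids.size:
            cols = np.array([col_of[int(i)] for i in pop.mut_ids], dtype=np.int64)
            block[:, cols] = sub
        blocks.append(block)
        sexes.append(pop.sexes[chosen])

    G_H = np.vstack(blocks)
    sexes = np.concatenate(sexes)
    return Population(
        label=label,
        params=P1.params,
        registry=P1.registry,
        sexes=sexes,
        G=G_H,
        positions=col_pos,
        mut_ids=col_ids,
        effects=col_eff,
        dominance=col_dom,
        prunable=col_prn,
        fixed_background=P1.fixed_background.copy(),
        substitutions=list(P1.substitutions),
        generation=P1.generation,
    )


def run_novel_phase(
    P1: Population,
    P2: Population,
    H: Population,
    config: ScenarioConfig,
    rngs: dict[str, np.random.Generator],
    records: list,
    replicate: int = 0,
    fitness_modifier=None,
    rng_demo: np.random.Generator | None = None,
) -> dict[str, Population]:
    """Evolve P1, P2, and H independently through the novel environment.

    Records are emitted for every generation from T_parental through
    T_parental + T_novel under each population's scheduled optimum. When
    demographic settings are configured, the next census size is drawn each
    generation from the current mean fitness (on a dedicated random stream)
    and an extinct population stops being simulated and recorded.
    """
    from .extensions import demographic_update  # local import: no cycle

    pops: dict[str, Population | None] = {"P1": P1, "P2": P2, "H": H}
    t_end = config.T_parental + config.T_novel
    for g in range(config.T_parental, t_end + 1):
        for label in POP_LABELS:
            pop = pops[label]
            if pop is None:
                continue
            surface = _surface(config, label, g)
            _record(records, pop, surface, config, replicate, fitness_modifier)
            if g == t_end:
                continue
            n_next = None
            if config.demography is not None:
                w_mean = float(pop.fitnesses(surface, fitness_modifier).mean())
                n_next, extinct = demographic_update(
                    pop, config.demography, w_mean, rng_demo
                )
                if extinct:
                    pops[label] = None
                    continue
            pop = next_generation(
                pop, surface, rngs[label], n_offspring=n_next,
                fitness_modifier=fitness_modifier,
            )
            fix_and_prune([pop], per_population=True)
            pops[label] = pop
    return {k: v for k, v in pops.items() if v is not None}


def run_replicate(
    config: ScenarioConfig,
    seed_seq: np.random.SeedSequence,
    replicate: int = 0,
) -> tuple[pd.DataFrame, dict[str, Population]]:
    """One full replicate: parental phase, hybrid creation, novel phase.

    Returns the per-generation record table (with adaptation rates filled)
    and the final populations.
    """
    from .extensions import bdmi_modifier, seed_bdmi_markers

    ss = seed_seq.spawn(5)
    rng_p1 = np.random.default_rng(ss[0])
    rng_p2 = np.random.default_rng(ss[1])
    rng_h = np.random.default_rng(ss[2])
    rng_demo = np.random.default_rng(ss[3])
    registry = MutationRegistry()
    records: list = []
    P1, P2 = run_parental_phase(
        config, rng_p1, rng_p2, registry, records=records, replicate=replicate
    )
    fitness_modifier = None
    pairs = None
    # cost 0 means no incompatibility at all: skip marker seeding so the
    # run reproduces the base model bit-for-bit under the same seed
    if config.bdmi is not None and config.bdmi.cost > 0:
        pairs = seed_bdmi_markers(P1, P2, config.bdmi, registry)
        fitness_modifier = bdmi_modifier(pairs)
    H = create_hybrid_population(P1, P2, rng_h)
    final = run_novel_phase(
        P1,
        P2,
        H,
        config,
        rngs={"P1": rng_p1, "P2": rng_p2, "H": rng_h},
        records=records,
        replicate=replicate,
        fitness_modifier=fitness_modifier,
        rng_demo=rng_demo,
    )
    df = _stats.add_adaptation_rates(_stats.records_to_dataframe(records))
    return df, final


def run_scenario(config: ScenarioConfig, progress: bool = False) -> pd.DataFrame:
    """Run all replicates of a scenario; returns the combined record table.

    All randomness derives from ``config.seed``: replicate r uses the r-th
    spawn of the root seed sequence, so runs are reproducible end to end
    and replicates are independent.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.replicates)
    frames = []
    for r, child in enumerate(children):
        df, _ = run_replicate(config, child, replicate=r)
        frames.append(df)
        if progress:  # pragma: no cover
            import sys

            print(f"replicate {r + 1}/{config.replicates} done", file=sys.stderr)
    return pd.concat(frames, ignore_index=True)
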