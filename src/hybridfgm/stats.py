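"""Per-generation summary statistics and replicate aggregation.

Three statistics drive the analyses: mean fitness by sex, the adaptation
rate ``(W(t+1) - W(t)) / (1 - W(t))`` (per-generation fitness gain relative
to the remaining distance from full adaptation), and the expected
heterozygosity ``pi`` — the probability that two randomly chosen gene
copies differ at a site, averaged over all sites in the genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .fgm import FitnessSurface
from .genome import FEMALE
from .population import Population

__all__ = [
    "GenerationRecord",
    "mean_fitness_by_sex",
    "adaptation_rate",
    "expected_heterozygosity",
    "records_to_dataframe",
    "add_adaptation_rates",
    "aggregate_replicates",
]

STAT_COLUMNS = [
    "mean_fitness_female",
    "mean_fitness_male",
    "mean_fitness_all",
    "adaptation_rate",
    "pi",
]


@dataclass
class GenerationRecord:
    """One population's summary for one generation of one replicate.

    ``adaptation_rate`` is NaN until filled by :func:`add_adaptation_rates`
    (it needs the following generation) and stays NaN where it is undefined
    (mean fitness exactly 1, or no following generation).
    """

    generation: int
    population: str
    N: int
    mean_fitness_female: float
    mean_fitness_male: float
    mean_fitness_all: float
    pi: float
    replicate: int = 0
    adaptation_rate: float = math.nan


def mean_fitness_by_sex(
    pop: Population,
    surface: FitnessSurface | None,
    fitness_modifier=None,
) -> tuple[float, float, float]:
    """Arithmetic mean fitness of females, males, and all individuals.

    An empty sex class yields NaN for that sex rather than an error.
    """
    if pop.size == 0:
        raise ValueError("population is empty")
    w = pop.fitnesses(surface, fitness_modifier)
    fem = pop.sexes == FEMALE
    w_f = float(w[fem].mean()) if fem.any() else math.nan
    w_m = float(w[~fem].mean()) if (~fem).any() else math.nan
    return w_f, w_m, float(w.mean())


def adaptation_rate(W_t: float, W_next: float) -> float:
    """Per-generation adaptation rate ``(W_next - W_t) / (1 - W_t)``.

    NaN (undefined) when the population is already at full fitness.
    """
    for w in (W_t, W_next):
        if not (0.0 <= w <= 1.0):
            raise ValueError("mean fitnesses must lie in [0, 1]")
    if W_t == 1.0:
        return math.nan
    return (W_next - W_t) / (1.0 - W_t)


def expected_heterozygosity(pop: Population, L: int | None = None) -> float:
    """Expected heterozygosity pi, averaged over all L sites.

    Uses population allele frequencies over gene copies (two per
    haplodiploid female, one per male): each biallelic segregating site
    contributes ``2 p (1 - p)``; a site carrying several stacked mutations
    contributes ``1 - sum_c p_c**2`` over its allele classes (the distinct
    local haplotype patterns, including the ancestral class). Fixed
    substitutions and monomorphic sites contribute zero.
    """
    L = pop.params.L if L is None else int(L)
    if pop.n_segregating == 0:
        return 0.0
    R = pop.total_copies
    p = pop.G.sum(axis=0, dtype=np.int64) / R
    positions = pop.positions
    # fast path: all segregating sites biallelic
    dup = np.zeros(positions.size, dtype=bool)
    if positions.size > 1:
        same = positions[1:] == positions[:-1]
        dup[1:] = same
        dup[:-1] |= same
    het = float((2.0 * p[~dup] * (1.0 - p[~dup])).sum())
    if dup.any():
        dup_pos = np.unique(positions[dup])
        for site in dup_pos:
            cols = np.nonzero(positions == site)[0]
            patterns, counts = np.unique(pop.G[:, cols], axis=0, return_counts=True)
            pc = counts / R
            het += float(1.0 - (pc * pc).sum())
    return het / L


def records_to_dataframe(records: list[GenerationRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(GenerationRecord)]
    df = pd.DataFrame([[getattr(r, c) for c in cols] for r in records], columns=cols)
    order = [
        "replicate",
        "generation",
        "population",
        "N",
        "mean_fitness_female",
        "mean_fitness_male",
        "mean_fitness_all",
        "adaptation_rate",
        "pi",
    ]
    return df[order].sort_values(["replicate", "generation", "population"]).reset_index(drop=True)


def add_adaptation_rates(df: pd.DataFrame) -> pd.DataFrame:
    """Fill the adaptation-rate column from each population's own fitness
    trajectory: rate(t) uses the change from t to t+1 within one replicate.

    Rates are computed per replicate before any averaging, so aggregated
    rates are means of per-replicate rates, not rates of mean trajectories.
    """
    df = df.sort_values(["replicate", "population", "generation"]).copy()
    grouped = df.groupby(["replicate", "population"], sort=False)["mean_fitness_all"]
    w_t = df["mean_fitness_all"].to_numpy()
    w_next = grouped.shift(-1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = (w_next - w_t) / (1.0 - w_t)
    rate[w_t >= 1.0] = np.nan
    df["adaptation_rate"] = rate
    return df.sort_values(["replicate", "generation", "population"]).reset_index(drop=True)


def aggregate_replicates(records) -> pd.DataFrame:
    """Replicate-wise mean and standard error of every statistic.

    Accepts a record list or DataFrame. Undefined (NaN) values are excluded,
    with the contributing replicate count reported per statistic as
    ``<stat>_n``. The SE of a single replicate is NaN.
    """
    df = records_to_dataframe(records) if not isinstance(records, pd.DataFrame) else records
    g = df.groupby(["population", "generation"], sort=True)
    out = {}
    for stat in STAT_COLUMNS + ["N"]:
        if stat not in df.columns:
            continue
        out[f"{stat}_mean"] = g[stat].mean()
        out[f"{stat}_se"] = g[stat].apply(
            lambda s: s.std(ddof=1) / math.sqrt(s.count()) if s.count() > 1 else math.nan
        )
        out[f"{stat}_n"] = g[stat].count()
    return pd.DataFrame(out).reset_index()
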