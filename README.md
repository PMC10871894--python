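# hybridfgm

Individual-based simulation of hybrid and parental adaptation to shifted
fitness optima under Fisher's geometric model, for diploid, haplodiploid,
and autotetraploid genetic systems.

Two allopatric parental populations adapt independently to their optima for
`T_parental` generations. A hybrid population is then founded from equal
numbers of both parents, the optimum shifts, and all three populations adapt
to the novel environment while per-generation fitness, adaptation rate, and
expected heterozygosity are recorded. The central question the design
addresses: do hybrid populations — with their elevated standing variation —
adapt faster than their parents, and how does that depend on the genetic
system, dominance, and the geometry of the optimum shift?

## Model summary

- **Phenotypes and fitness.** Each individual is a point in `n`-dimensional
  trait space (default `n = 5`). Fitness is Gaussian in distance `x` from
  the current optimum, `w = exp(-(x^2)^q)` with shape `q = 1` by default,
  dropping from a height of one.
- **Mutation.** Poisson mutation at rate `mu = 1e-8` per site over
  `L = 1e6` sites per haploid genome per generation. Each mutation displaces
  the phenotype in a uniformly random direction with exponentially
  distributed magnitude (mean `lambda = 0.2`). Mutations are codominant by
  default (`h = 0.5`); tetraploids express additive dosage (`copies / 4`).
- **Reproduction.** Discrete generations, Wright–Fisher sampling with
  fitness-proportional parentage, separate sexes (50:50), Poisson crossovers
  at the per-bp rate `r`. Haplodiploids follow arrhenotoky: females are
  diploid, males develop from unfertilised eggs and are haploid, expressing
  every allele they carry.
- **Defaults** match effective sizes across systems: diploids
  `N = 1500, r = (2/3)e-6`; haplodiploids `N = 2000, r = 1e-6`;
  tetraploids `N = 750, r = (2/3)e-6` (all 3000 gene copies).

Optional extensions: pairwise intrinsic (Bateson–Dobzhansky–Muller)
incompatibilities seeded as fixed differences between the parents, and
fecundity-based demography with carrying capacity and extinction.

## Worked example

Run a scaled-down version of the canonical scenario in which both parents
adapt to an optimum at distance 1 and the optimum then shifts one unit
further along the same axis (preset `fig2A`):

```bash
hybridfgm run --preset fig2A --system diploid \
    --n-pop 300 --t-parental 500 --t-novel 300 \
    --mu 5e-8 --replicates 10 --seed 42 --out results/fig2A
hybridfgm stats results/fig2A/records.tsv --out results/fig2A/aggregated.tsv
```

This writes `records.tsv` (one row per replicate × generation × population),
`config.yaml` (the fully resolved configuration), and `manifest.json`
(seeds and file checksums; reruns with the same seed are byte-identical).
The aggregated table has replicate means and standard errors per generation.

The same scenario from Python:

```python
from hybridfgm import preset, run_scenario, aggregate_replicates

config = preset("fig2A", system="diploid", N_pop=300,
                T_parental=500, T_novel=300, mu=5e-8,
                replicates=10, seed=42)
records = run_scenario(config)
agg = aggregate_replicates(records)

shift = config.T_parental
post = agg[agg.generation.between(shift, shift + 50)]
print(post.pivot(index="generation", columns="population",
                 values="mean_fitness_all_mean"))
```

In the first tens of generations after the shift the hybrid population (`H`)
typically out-adapts both parents (`P1`, `P2`): it starts with more standing
variation, visible as elevated heterozygosity `pi` at the creation
generation. Presets `fig2B`/`fig2C` probe smaller back-shifts (where hybrids
can instead pay a cost), and `fig3A`–`fig3C` shift the optimum to new trait
axes with identically or divergently adapted parents.

List all presets:

```bash
hybridfgm presets
```

Sweep dominance and mutation size over a preset:

```bash
hybridfgm sweep --preset fig2A --param h=0.2,0.5,0.8 \
    --param lambda_mean=0.1,0.2,0.4 \
    --n-pop 100 --t-parental 200 --t-novel 100 --replicates 3 \
    --out results/sweep.tsv
```

## Package layout

| Module | Contents |
| --- | --- |
| `hybridfgm.fgm` | fitness surface, mutation-effect law, dosage → phenotype mapping |
| `hybridfgm.genome` | mutations, registries, haploid genomes, individuals |
| `hybridfgm.population` | matrix-backed populations, recombination, Wright–Fisher reproduction, fixation pruning |
| `hybridfgm.scenarios` | optimum schedules, configs, presets, the two-phase scenario driver |
| `hybridfgm.stats` | mean fitness, adaptation rate ΔW/(1−W), expected heterozygosity, aggregation |
| `hybridfgm.extensions` | BDMIs, demography/extinction, parameter sweeps |
| `hybridfgm.validation` | fixation-probability and neutral-diversity oracles |
| `hybridfgm.io`, `hybridfgm.cli` | configs, TSV records, manifests, command-line interface |

See `docs/methods.md` for the full model description and the reasoning
behind implementation choices.
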