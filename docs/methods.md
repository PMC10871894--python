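# Methods

This note documents the simulation model precisely enough to reimplement
it, and records the choices made where the model description leaves room.

## 1. Phenotypes and fitness

An individual's phenotype is a vector `z` in `R^n` (default `n = 5`),
computed additively from its genotype:

```
z = fixed_background + sum over segregating mutations of w(c, P) * delta
```

where `delta` is the mutation's full-expression displacement, `c` the
number of copies the individual carries, `P` its ploidy, and the dosage
weight `w` is

- `w = 1` when `c = P` (homozygous, or hemizygous in haploid males),
- diploid heterozygote: `w = h` (global dominance parameter, default 0.5),
- tetraploid: `w = c / 4` (pure additive dosage; `h` is not applied),
- haploid carrier: `w = 1`.

Fitness declines with Euclidean distance `x` from the current optimum:

```
w(x) = exp(-(x^2)^q)
```

with shape `q = 1` (Gaussian) by default. Fitness is 1 at the optimum.
Dominance and epistasis *in fitness* are emergent: a codominant mutation
can overshoot the optimum when homozygous and be favoured only as a
heterozygote.

## 2. Mutation

Gamete mutation counts are Poisson with mean `mu * L` (`mu = 1e-8`,
`L = 1e6`). Each new mutation gets a uniform random integer position and an
effect vector `delta = m * u`, where `u` is uniform on the unit
`(n-1)`-sphere (normalised standard Gaussian vector) and `m` is exponential
with mean `lambda = 0.2`, independent of direction. Every mutation is a new
allele at its position (infinite-alleles at the site level); two mutations
at one position stack additively.

## 3. Reproduction and genetic systems

Generations are discrete and populations have fixed census size `N` with
exactly `ceil(N/2)` females and `floor(N/2)` males (constant-size mode).
Mothers and fathers are drawn independently, proportional to fitness,
with replacement.

Gametes are produced with Poisson(`r * L`) crossovers at uniform positions;
the transmitted allele at each site follows the crossover parity from a
random starting copy.

- **Diploids:** both sexes diploid; offspring get one recombinant gamete
  from each parent.
- **Haplodiploids (arrhenotoky):** females diploid, males haploid. Daughters
  get a maternal and a paternal gamete; sons get only a maternal gamete
  (no father is drawn). Males transmit their single genome unchanged and
  express all alleles fully.
- **Autotetraploids:** all individuals carry 4 copies. Meiosis forms random
  bivalents (random pairing of the 4 copies), each pair recombines, and a
  diploid gamete takes one recombinant product of each bivalent. Offspring
  combine two diploid gametes.

Selection acts through parentage only (fecundity selection); if every
individual has fitness 0 the simulation raises an error rather than
sampling uniformly.

## 4. Two-phase scenario

1. **Parental phase.** P1 and P2 start monomorphic at the phenotypic origin
   and evolve independently for `T_parental = 1500` generations toward
   their scheduled optima (each population has its own random stream).
2. **Hybrid creation.** At generation `T_parental`, H is founded from
   exactly `N/4` females and `N/4` males sampled without replacement from
   each parent (50:50 ancestry and sexes; requires `N % 4 == 0`). Founders
   are copies; there is no later gene flow.
3. **Novel phase.** The optimum shifts per the schedule and P1, P2, H adapt
   independently for `T_novel` generations.

Canonical optimum schedules (presets, `n = 5`, axes shown as vectors):

| preset | P1 | P2 | novel |
| --- | --- | --- | --- |
| fig2A | (1,0,0,0,0) | same | (2,0,0,0,0) |
| fig2B | (3,0,0,0,0) | same | (2,0,0,0,0) |
| fig2C | (3,0,0,0,0) | same | (2.5,0,0,0,0) |
| fig3A | (3,0,0,0,0) | same | (0,2,0,0,0) |
| fig3B | (2,0,0,0,0) | (0,2,0,0,0) | (2,2,0,0,0) |
| fig3C | (2,0,0,0,0) | (0,2,0,0,0) | (0,0,2,0,0) |

Default sizes: diploid `N = 1500`, `r = (2/3)e-6`; haplodiploid `N = 2000`,
`r = 1e-6` (matched gene-copy count 3000 and population recombination
rate); tetraploid `N = 750`, `r = (2/3)e-6` (same copy count; a
reimplementation choice, as is the tetraploid additive-dosage rule).

### Fixation handling

Mutations fixed in a population are folded into its `fixed_background` and
recorded as substitutions — but, **before hybrid creation**, only mutations
fixed in *both* parents are folded. Privately fixed mutations stay as
(fixed) segregating columns so the hybrid population is genuinely
polymorphic at divergent sites. After hybrid creation each population prunes
its own fixations independently. Pruning is exactly phenotype- and
fitness-neutral.

## 5. Statistics

Per generation, per population, per replicate:

- mean fitness of females, males, and all individuals;
- **adaptation rate** `(W(t+1) - W(t)) / (1 - W(t))` — the fraction of the
  remaining fitness deficit gained per generation; computed within each
  replicate trajectory *before* averaging across replicates; undefined
  (NA) at `W = 1` and for a trajectory's last recorded generation;
- **expected heterozygosity** `pi`: mean over all `L` sites of the
  probability that two random gene copies differ; biallelic sites
  contribute `2p(1-p)`, stacked sites `1 - sum of squared allele-class
  frequencies`. Gene copies are counted as carried (two per haplodiploid
  female, one per male).

Records are written as deterministic TSV (`NA` for undefined); the manifest
stores the root seed, derived per-replicate seed keys, and SHA-256 file
checksums.

## 6. Extensions

**Intrinsic incompatibilities (BDMIs).** Just before hybrid creation, `k`
pairs of phenotypically silent marker mutations are fixed — one side of
each pair in each parent — at deterministic, evenly spaced positions,
flagged so pruning never folds them away. An individual carrying both sides
of a pair multiplies its fitness by `1 - cost * m(class_a, class_b)`, where
each class is absent / partial / full dosage and `m` defaults to the
dosage-multiplicative matrix (`m = 1/4` for a double heterozygote, 1 for a
double homozygote, 0 if either side is absent; haploid carriers count as
full). Parents never pay a cost. A configured cost of exactly 0 disables
the extension entirely (no markers are seeded), so it reproduces the base
model bit-for-bit. The exact BDMI construction (pair count, cost, dominance
matrix) is a configurable reimplementation choice.

**Demography.** Optionally the next census size is drawn as
`min(Poisson(N * W_mean * growth_factor), K)` during the novel phase, from
a dedicated random stream so that demography that never binds reproduces
constant-size dynamics bit-for-bit. A population at or below the extinction
threshold (or below 2) is extinct and stops being simulated/recorded.

## 7. Determinism and random streams

All randomness derives from the configured seed through numpy
`SeedSequence` spawning: one child per replicate; within a replicate,
separate streams for P1, P2, H, and demography. Consequences used by the
test suite: identical seeds give byte-identical outputs; P1 and P2 are
exchangeable; seeding the two parental streams identically yields identical
parents; BDMI with cost 0 is bit-identical to the base model; a
never-binding carrying capacity changes nothing.

## 8. Validation oracles

- **Fixation probability.** Trials seed one mutant gene copy into a
  monomorphic population on a 1-D trait with surface shape `q = 1/2`
  (fitness `exp(-|x|)`), which makes selection exactly multiplicative: a
  mutation of size `d = log(1+s)` has full-expression advantage exactly
  `s`, and the trial dominance is set to `log(1+hs)/log(1+s)` so the
  heterozygous fitness ratio is exactly `1 + hs` — the quantity the `2hs`
  anchor refers to (phenotype-scale dominance 0.5 would give
  `sqrt(1+s) - 1`, an O(s^2) distortion of the premise). The classical
  formulas — diploid `2hs`; haplodiploid `(1/3)2s + (2/3)2hs` (a new copy
  is haploid-exposed with probability 1/3); neutral `1/(gene copies)` —
  are first-order in `s`; the Monte-Carlo estimator converges to the exact
  Poisson-branching survival probability (diploid: the root of
  `u = 1 - exp(-(1+hs)u)`, 0.0484 at `s = 0.05`; haplodiploid: the
  analogous two-type system, 0.0637), so the stochastic comparison targets
  the exact values and the first-order formulas are checked against them
  analytically.
- **Neutral diversity.** With selection off, equilibrium
  `pi = 4 Ne mu`, `Ne = gene copies / 2`.

## 9. Performance notes

Populations store a `uint8` presence matrix (rows = haploid genome copies,
columns = segregating mutations ordered by position). Dosage counts use
`np.add.reduceat` over per-individual row segments; recombination draws are
grouped by crossover count and vectorised. A scaled scenario replicate
(N = 300, 800 generations, three populations) takes seconds; the full
default conditions run in minutes per replicate.
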