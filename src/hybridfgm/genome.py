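"""Genome- and individual-level types.

The simulation engine stores populations as presence/absence matrices for
speed (see :mod:`hybridfgm.population`); the classes here are the
object-level view of that state: a :class:`Mutation` is a segregating
variant with a chromosome position and a phenotypic effect, a
:class:`HaploidGenome` is one ordered set of mutations, and an
:class:`Individual` carries one, two, or four genome copies depending on
sex and genetic system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fgm import MutationEffect

__all__ = ["Mutation", "MutationRegistry", "HaploidGenome", "Individual"]

FEMALE = 0
MALE = 1

SYSTEMS = ("diploid", "haplodiploid", "tetraploid")


def copies_for(system: str, sex: int) -> int:
    """Genome copies carried by an individual of the given sex and system."""
    if system == "diploid":
        return 2
    if system == "haplodiploid":
        return 2 if sex == FEMALE else 1
    if system == "tetraploid":
        return 4
    raise ValueError(f"unknown genetic system {system!r}; expected one of {SYSTEMS}")


@dataclass(frozen=True)
class Mutation:
    """A segregating (or fixed) variant.

    ``effect.delta`` is the full-expression phenotypic displacement;
    ``prunable`` is False for bookkeeping markers (e.g. incompatibility
    loci) that must never be folded into the fixed background.
    """

    id: int
    position: int
    effect: MutationEffect
    origin_generation: int
    origin_population: str
    prunable: bool = True


class MutationRegistry:
    """Run-scoped allocator of unique mutation ids.

    All populations of one simulation replicate share a registry so that
    ids stay unique across populations and hybrid creation can merge
    mutation sets without collisions.
    """

    def __init__(self) -> None:
        self._next_id = 0
        self.mutations: dict[int, Mutation] = {}

    def register(
        self,
        position: int,
        delta: np.ndarray,
        dominance_h: float,
        origin_generation: int,
        origin_population: str,
        prunable: bool = True,
    ) -> Mutation:
        mut = Mutation(
            id=self._next_id,
            position=int(position),
            effect=MutationEffect(delta=np.asarray(delta, dtype=float), dominance_h=dominance_h),
            origin_generation=origin_generation,
            origin_population=origin_population,
            prunable=prunable,
        )
        self._next_id += 1
        self.mutations[mut.id] = mut
        return mut

    def register_batch(
        self,
        positions: np.ndarray,
        deltas: np.ndarray,
        dominance_h: float,
        origin_generation: int,
        origin_population: str,
    ) -> np.ndarray:
        """Register many mutations at once; returns their ids."""
        ids = np.arange(self._next_id, self._next_id + len(positions), dtype=np.int64)
        for i, (pos, delta) in enumerate(zip(positions, deltas)):
            mut = Mutation(
                id=int(ids[i]),
                position=int(pos),
                effect=MutationEffect(delta=np.asarray(delta, dtype=float), dominance_h=dominance_h),
                origin_generation=origin_generation,
                origin_population=origin_population,
            )
            self.mutations[mut.id] = mut
        self._next_id += len(positions)
        return ids


@dataclass(frozen=True)
class HaploidGenome:
    """One genome copy: mutations ordered by chromosome position."""

    mutations: tuple[Mutation, ...] = ()

    def __post_init__(self):
        muts = tuple(self.mutations)
        if any(
            (a.position, a.id) > (b.position, b.id) for a, b in zip(muts, muts[1:])
        ):
            muts = tuple(sorted(muts, key=lambda m: (m.position, m.id)))
        ids = [m.id for m in muts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate mutation ids within one haploid genome")
        object.__setattr__(self, "mutations", muts)

    @property
    def mutation_ids(self) -> tuple[int, ...]:
        return tuple(m.id for m in self.mutations)


@dataclass(frozen=True)
class Individual:
    """One organism: sex, number of genome copies carried, and the copies."""

    sex: str  # "female" | "male"
    ploidy: int  # genome copies actually carried: 1, 2, or 4
    genomes: tuple[HaploidGenome, ...]

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")
        if self.ploidy not in (1, 2, 4):
            raise ValueError("carried genome copies must be 1, 2, or 4")
        if len(self.genomes) != self.ploidy:
            raise ValueError(
                f"individual declares {self.ploidy} copies but carries {len(self.genomes)}"
            )
        object.__setattr__(self, "genomes", tuple(self.genomes))

    def dosage(self) -> dict[int, int]:
        """Copy number of each mutation carried across genome copies."""
        d: dict[int, int] = {}
        for g in self.genomes:
            for m in g.mutations:
                d[m.id] = d.get(m.id, 0) + 1
        return d
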