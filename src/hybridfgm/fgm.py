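"""Core mathematics of Fisher's geometric model.

Phenotypes are points in an ``n``-dimensional trait space. Fitness declines
with Euclidean distance ``x`` from a single optimum as ``exp(-(x**2)**q)``;
with the default shape exponent ``q = 1`` this is the classic Gaussian
surface whose height is exactly 1 at the optimum. Mutations are random
displacement vectors: direction uniform on the unit sphere, magnitude
exponential. Dominance and epistasis in *fitness* are emergent properties of
the geometry even though mutations act additively on the *phenotype*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FitnessSurface",
    "MutationEffect",
    "distance_to_optimum",
    "fitness",
    "draw_mutation_effect",
    "draw_mutation_effects",
    "genotype_to_phenotype",
    "dosage_weight",
]


def _as_phenotype(values, n: int | None = None) -> np.ndarray:
    """Validate and coerce a phenotype vector to a float array."""
    z = np.asarray(values, dtype=float)
    if z.ndim != 1 or z.size < 1:
        raise ValueError("phenotype must be a 1-D vector of length >= 1")
    if not np.all(np.isfinite(z)):
        raise ValueError("phenotype contains non-finite entries")
    if n is not None and z.size != n:
        raise ValueError(f"phenotype has length {z.size}, expected {n}")
    return z


@dataclass(frozen=True)
class FitnessSurface:
    """A single-optimum fitness surface ``w(z) = exp(-(x**2)**shape)``.

    Parameters
    ----------
    optimum
        Position of the fitness peak in trait space.
    shape
        Positive shape exponent ``q`` applied to the squared distance.
        ``shape = 1`` gives the Gaussian surface ``exp(-x**2)``; smaller
        values flatten the peak into ``exp(-|x|**(2q))``.
    """

    optimum: np.ndarray
    shape: float = 1.0

    def __post_init__(self):
        opt = _as_phenotype(self.optimum)
        object.__setattr__(self, "optimum", opt)
        if not (self.shape > 0 and np.isfinite(self.shape)):
            raise ValueError("shape exponent must be a positive finite real")

    @property
    def n_dims(self) -> int:
        return self.optimum.size

    def fitness_from_distance(self, x):
        """Fitness of phenotypes a Euclidean distance ``x`` from the optimum."""
        x = np.asarray(x, dtype=float)
        return np.exp(-((x * x) ** self.shape))


@dataclass(frozen=True)
class MutationEffect:
    """Full-expression phenotypic displacement of a mutation.

    ``delta`` is the displacement when the mutation is fully expressed
    (haploid carriers, or homozygous diploids). ``dominance_h`` scales the
    displacement in diploid heterozygotes; the default 0.5 is codominance.
    """

    delta: np.ndarray
    dominance_h: float = 0.5

    def __post_init__(self):
        d = _as_phenotype(self.delta)
        object.__setattr__(self, "delta", d)
        if not (0.0 <= self.dominance_h <= 1.0):
            raise ValueError("dominance_h must lie in [0, 1]")

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.delta))


def distance_to_optimum(z, surface: FitnessSurface) -> float:
    """Euclidean distance of phenotype ``z`` from the surface optimum."""
    z = _as_phenotype(z, n=surface.n_dims)
    return float(np.linalg.norm(z - surface.optimum))


def fitness(z, surface: FitnessSurface) -> float:
    """Fitness of phenotype ``z``: ``exp(-(x**2)**q)`` with ``x`` the distance
    to the optimum. Equals 1 exactly at the optimum and decreases strictly
    with distance for any ``q > 0``."""
    x = distance_to_optimum(z, surface)
    return float(surface.fitness_from_distance(x))


def draw_mutation_effects(
    n: int,
    lambda_mean: float,
    size: int,
    rng: np.random.Generator,
    dominance_h: float = 0.5,
) -> np.ndarray:
    """Draw ``size`` mutation displacement vectors as a ``(size, n)`` array.

    Direction is uniform on the unit (n-1)-sphere (normalised i.i.d.
    standard Gaussians) and magnitude is exponential with mean
    ``lambda_mean``; the two are independent.
    """
    if n < 1:
        raise ValueError("trait dimensionality n must be >= 1")
    if not lambda_mean > 0:
        raise ValueError("lambda_mean must be positive")
    del dominance_h  # recorded by callers; the displacement does not depend on it
    gauss = rng.standard_normal((size, n))
    norms = np.linalg.norm(gauss, axis=1)
    # a zero Gaussian vector has probability zero; guard for numerical safety
    while np.any(norms == 0.0):  # pragma: no cover
        bad = norms == 0.0
        gauss[bad] = rng.standard_normal((int(bad.sum()), n))
        norms = np.linalg.norm(gauss, axis=1)
    magnitudes = rng.exponential(scale=lambda_mean, size=size)
    return gauss * (magnitudes / norms)[:, None]


def draw_mutation_effect(
    n: int,
    lambda_mean: float,
    rng: np.random.Generator,
    dominance_h: float = 0.5,
) -> MutationEffect:
    """Draw a single mutation effect (see :func:`draw_mutation_effects`)."""
    delta = draw_mutation_effects(n, lambda_mean, 1, rng)[0]
    return MutationEffect(delta=delta, dominance_h=dominance_h)


def dosage_weight(copies: int, ploidy: int, dominance_h: float) -> float:
    """Expression weight of a mutation carried in ``copies`` of ``ploidy``
    genome copies.

    Full dosage always expresses the full displacement. Diploid
    heterozygotes express ``h``; haploids carry either 0 or full dosage;
    tetraploids express additively in dosage (``copies / 4``), so a single
    copy has a quarter effect on the phenotype.
    """
    if ploidy not in (1, 2, 4):
        raise ValueError("ploidy must be 1, 2, or 4")
    if not (0 <= copies <= ploidy):
        raise ValueError(f"copies={copies} outside [0, ploidy={ploidy}]")
    if copies == 0:
        return 0.0
    if copies == ploidy:
        return 1.0
    if ploidy == 2:
        return float(dominance_h)
    # tetraploid partial dosage: additive in copy number
    return copies / 4.0


def genotype_to_phenotype(fixed_background, dosage_list) -> np.ndarray:
    """Map a genotype to its phenotype.

    Parameters
    ----------
    fixed_background
        Phenotypic contribution of all fixed substitutions.
    dosage_list
        Iterable of ``(MutationEffect, copies, ploidy)`` triples for the
        segregating mutations carried. Contributions are additive across
        loci; there is no inter-locus interaction at the phenotype level.
    """
    z = _as_phenotype(fixed_background).copy()
    for effect, copies, ploidy in dosage_list:
        if copies < 1:
            raise ValueError("dosage_list entries must have copies >= 1")
        w = dosage_weight(copies, ploidy, effect.dominance_h)
        delta = _as_phenotype(effect.delta, n=z.size)
        z += w * delta
    return z
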