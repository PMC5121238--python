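"""Diploid genetics: two selected loci with a Dobzhansky-Muller incompatibility.

Genotypes carry ``n_loci`` biallelic loci with two allele copies each
(values in {0, 1}).  Locus 0 is the A-locus (allele 1 = "A"), locus 1 the
B-locus (allele 1 = "B"); the remaining loci are neutral.  Alleles "a" and
"B" are jointly lethal: the four genotype classes carrying both (AaBB, AaBb,
aaBB, aaBb) have zero viability wherever they settle.  The five viable
classes experience habitat-dependent survival built from the selection
strength ``s``: the favored homozygote survives settlement with probability
0.5 + s/2 in its own habitat and 0.5 - s/2 in the other, while AABb, AAbb
and Aabb sit at the 0.5 baseline everywhere.

Inheritance is Mendelian with free recombination (every locus segregates
independently) and mutation follows the K-allele model with K = 2, i.e. an
allele flips to its alternative state with the per-copy rate ``mu``.

A genotype is a ``(n_loci, 2)`` uint8 array; population-scale arrays are
``(n, n_loci, 2)`` and the vectorized helpers below operate on those.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SELECTED_CLASSES",
    "INCOMPATIBLE_CLASSES",
    "VIABLE_CLASSES",
    "classify",
    "classify_counts",
    "class_index",
    "FitnessTable",
    "build_fitness_table",
    "mendelian_offspring",
    "mendelian_offspring_many",
    "mutate",
    "init_genotypes",
]

# 9 two-locus classes indexed by (A-allele count, B-allele count):
# index = a_count * 3 + b_count
SELECTED_CLASSES: tuple[str, ...] = (
    "aabb", "aaBb", "aaBB",
    "Aabb", "AaBb", "AaBB",
    "AAbb", "AABb", "AABB",
)

INCOMPATIBLE_CLASSES: frozenset[str] = frozenset({"AaBB", "AaBb", "aaBB", "aaBb"})
VIABLE_CLASSES: tuple[str, ...] = ("AABB", "AABb", "AAbb", "Aabb", "aabb")

_CLASS_TO_INDEX = {name: i for i, name in enumerate(SELECTED_CLASSES)}


def class_index(name: str) -> int:
    """Integer code (0..8) of a selected-genotype class name."""
    return _CLASS_TO_INDEX[name]


def classify(genotype: np.ndarray) -> str:
    """Selected-genotype class of one individual (e.g. ``"AaBb"``)."""
    g = np.asarray(genotype)
    a = int(g[0, 0]) + int(g[0, 1])
    b = int(g[1, 0]) + int(g[1, 1])
    return SELECTED_CLASSES[a * 3 + b]


def classify_counts(genotypes: np.ndarray) -> np.ndarray:
    """Class codes (0..8) for an ``(n, n_loci, 2)`` genotype array."""
    a = genotypes[:, 0, :].sum(axis=1)
    b = genotypes[:, 1, :].sum(axis=1)
    return (a * 3 + b).astype(np.int64)


@dataclass(frozen=True)
class FitnessTable:
    """Settlement survival probability per (selected class, habitat).

    ``survival[class_code, habitat]`` with habitat 1 = AABB habitat,
    habitat 0 = aabb habitat.  Mirror symmetry holds by construction:
    the AABB survival in one habitat equals the aabb survival in the other.
    """

    s: float
    survival: np.ndarray = field(repr=False)  # (9, 2)

    def get(self, selected_class: str, habitat: int) -> float:
        return float(self.survival[_CLASS_TO_INDEX[selected_class], habitat])


def build_fitness_table(s: float, het_gradient: bool = False) -> FitnessTable:
    """Build the genotype x habitat survival table for selection strength ``s``.

    ``s`` is the fitness difference between the two favored homozygotes
    across habitats, applied as density-independent mortality around the 0.5
    baseline.  With ``het_gradient`` the single-locus heterozygotes AABb and
    Aabb get a half-strength gradient (0.5 +/- s/4) following the habitat
    preference of their homozygous background instead of the flat 0.5.
    """
    if not (0.0 <= s < 1.0):
        raise ValueError(f"selection strength must lie in [0, 1), got {s}")
    surv = np.zeros((9, 2))
    hi, lo = 0.5 + s / 2.0, 0.5 - s / 2.0
    surv[_CLASS_TO_INDEX["AABB"]] = (lo, hi)  # (aabb habitat, AABB habitat)
    surv[_CLASS_TO_INDEX["aabb"]] = (hi, lo)
    surv[_CLASS_TO_INDEX["AAbb"]] = (0.5, 0.5)
    if het_gradient:
        surv[_CLASS_TO_INDEX["AABb"]] = (0.5 - s / 4.0, 0.5 + s / 4.0)
        surv[_CLASS_TO_INDEX["Aabb"]] = (0.5 + s / 4.0, 0.5 - s / 4.0)
    else:
        surv[_CLASS_TO_INDEX["AABb"]] = (0.5, 0.5)
        surv[_CLASS_TO_INDEX["Aabb"]] = (0.5, 0.5)
    # AaBB, AaBb, aaBB, aaBb stay at 0: a and B alleles are jointly lethal.
    # Round away sub-ulp subtraction noise so a decimal s yields the exact
    # decimal survival values (e.g. s = 0.32 -> 0.34, not 0.33999...97).
    return FitnessTable(s=s, survival=np.round(surv, 12))


def mendelian_offspring(mother: np.ndarray, father: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """One offspring genotype: an independent uniform allele pick per parent
    at every locus (free recombination, no linkage)."""
    n_loci = mother.shape[0]
    mi = rng.integers(0, 2, size=n_loci)
    fi = rng.integers(0, 2, size=n_loci)
    child = np.empty((n_loci, 2), dtype=np.uint8)
    child[:, 0] = mother[np.arange(n_loci), mi]
    child[:, 1] = father[np.arange(n_loci), fi]
    return child


def mendelian_offspring_many(mothers: np.ndarray, fathers: np.ndarray,
                             rng: np.random.Generator) -> np.ndarray:
    """Vectorized inheritance for matched ``(n, n_loci, 2)`` parent arrays."""
    n, n_loci, _ = mothers.shape
    mi = rng.integers(0, 2, size=(n, n_loci))
    fi = rng.integers(0, 2, size=(n, n_loci))
    out = np.empty((n, n_loci, 2), dtype=np.uint8)
    out[:, :, 0] = np.take_along_axis(mothers, mi[:, :, None], axis=2)[:, :, 0]
    out[:, :, 1] = np.take_along_axis(fathers, fi[:, :, None], axis=2)[:, :, 0]
    return out


def mutate(genotypes: np.ndarray, mu: float, rng: np.random.Generator) -> np.ndarray:
    """K-allele mutation with K = 2: each allele copy flips with probability mu.

    Works on a single ``(n_loci, 2)`` genotype or a stacked population array;
    returns a new array.
    """
    if not (0.0 <= mu <= 1.0):
        raise ValueError(f"mutation rate must lie in [0, 1], got {mu}")
    g = np.asarray(genotypes, dtype=np.uint8)
    if mu == 0.0:
        return g.copy()
    flips = rng.random(g.shape) < mu
    return np.where(flips, 1 - g, g).astype(np.uint8)


def init_genotypes(n: int, n_loci: int, rng: np.random.Generator) -> np.ndarray:
    """Maximum-diversity initialization: every allele i.i.d. uniform on {0, 1}."""
    return rng.integers(0, 2, size=(n, n_loci, 2), dtype=np.uint8)
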