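"""Generational engine: distance-limited mating, dispersal and viability selection.

The model is a continuously distributed dioecious population occupying a
fixed set of home sites (the carrying capacity) on a binary habitat map.
Generations are non-overlapping.  Each generation:

1. every female picks one male within the maximum movement distance, with
   probability proportional to inverse-squared distance (males mate with
   replacement; females with no male in range produce nothing);
2. each pair produces a Poisson-distributed number of offspring; loci
   segregate independently and every allele copy may mutate;
3. all adults die;
4. offspring disperse, in random order, from their natal site to a vacant
   site drawn from the same truncated inverse-square kernel.  On arrival the
   settler survives with the probability its two-locus genotype class has in
   the local habitat (during burn-in all settlers survive).  Failed settlers
   die; settlement ends when every site is occupied or the pool is spent.

Excess offspring are discarded once all sites fill, which holds the
population at exactly the carrying capacity whenever enough viable
offspring are produced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .genetics import (
    FitnessTable,
    classify_counts,
    init_genotypes,
    mendelian_offspring_many,
    mutate,
)
from .landscape import LandscapeGrid, habitat_at

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SiteSet",
    "Individual",
    "GenerationRecord",
    "PopulationState",
    "movement_kernel",
    "generate_sites",
    "init_population",
    "select_mates",
    "reproduce",
    "disperse_and_settle",
    "step_generation",
    "run_simulation",
]

# class codes of the two mutually incompatible homozygotes
_AABB_CODE = 8  # a_count=2, b_count=2
_AABB_LOWER_CODE = 0  # aabb


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation run.

    ``max_move_frac`` scales both the mating and the dispersal radius as a
    fraction of the maximum landscape extent.  ``s`` is the selection
    strength feeding the fitness table; selection (including the
    zero-viability incompatibility rule) is active only after ``burn_in``
    generations.
    """

    n_sites: int = 5000
    n_loci: int = 100
    mu: float = 0.0005
    offspring_mean: float = 4.0
    max_move_frac: float = 0.10
    s: float = 0.0
    burn_in: int = 250
    total_gens: int = 1250
    seed: int = 0
    # The zero-viability rule for a/B carriers applies in every generation
    # by default; burn-in only withholds the habitat-dependent mortality.
    # A sudden activation of the incompatibility after a fully neutral
    # burn-in makes ~9/16 of offspring inviable at once and crashes the
    # population; purging a/B combinations from the start instead lets the
    # spatial genetic pattern build up gradually.  Set False for fully
    # neutral (e.g. drift-validation) runs.
    incompatibility_during_burn_in: bool = True
    # movement probability within the truncation radius: "inverse_square"
    # (the isolation-by-distance model) or "uniform" (random mating within
    # range; with max_move_frac = 1 this is the panmictic Wright-Fisher
    # parameterization)
    kernel: str = "inverse_square"

    def __post_init__(self) -> None:
        if not (0.0 < self.max_move_frac <= 1.0):
            raise ValueError("max_move_frac must lie in (0, 1]")
        if self.burn_in > self.total_gens:
            raise ValueError("burn_in cannot exceed total_gens")
        if self.n_sites <= 0 or self.n_loci < 2:
            raise ValueError("need n_sites > 0 and n_loci >= 2")
        if self.kernel not in ("inverse_square", "uniform"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


@dataclass
class SiteSet:
    """Fixed home-site coordinates; each site holds at most one individual."""

    coords: np.ndarray  # (n_sites, 2)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValueError("site coordinates must be unique")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class Individual:
    """Convenience view of one individual (engine state is array-based)."""

    site: int
    sex: str  # "F" or "M"
    genotype: np.ndarray


@dataclass
class GenerationRecord:
    """Per-generation summary kept for downstream cluster detection."""

    generation: int
    selection_on: bool
    pop_size: int
    class_counts: np.ndarray  # (9,) individuals per selected class
    coords_aabb_upper: np.ndarray  # (k, 2) positions of AABB carriers
    coords_aabb_lower: np.ndarray  # (m, 2) positions of aabb carriers


@dataclass
class PopulationState:
    """Occupied sites, sexes and genotypes at one generation."""

    generation: int
    sites: SiteSet
    site_idx: np.ndarray  # (n,) indices into sites
    sexes: np.ndarray  # (n,) 0 = female, 1 = male
    genotypes: np.ndarray  # (n, n_loci, 2)
    records: list[GenerationRecord] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.site_idx)

    @property
    def coords(self) -> np.ndarray:
        return self.sites.coords[self.site_idx]

    def individuals(self) -> list[Individual]:
        return [
            Individual(int(s), "F" if x == 0 else "M", g)
            for s, x, g in zip(self.site_idx, self.sexes, self.genotypes)
        ]


def _kernel_weights(distances: np.ndarray, max_dist: float,
                    kernel: str = "inverse_square") -> np.ndarray | None:
    """Unnormalized movement weights, truncated at max_dist.

    Zero-distance entries are infeasible (the source itself is never a
    candidate).  Returns None when no candidate is in range.
    """
    feasible = (distances > 0.0) & (distances <= max_dist)
    if not feasible.any():
        return None
    w = np.zeros_like(distances, dtype=float)
    if kernel == "uniform":
        w[feasible] = 1.0
    else:
        w[feasible] = distances[feasible] ** -2.0
    return w


def movement_kernel(source, candidates, max_dist: float,
                    kernel: str = "inverse_square") -> np.ndarray | None:
    """Truncated inverse-square movement probabilities.

    p_i is proportional to d_i^-2 for candidates within ``max_dist`` of
    ``source`` and 0 beyond; probabilities sum to 1.  Returns None (the
    empty-set signal) when every candidate is out of range.  ``kernel =
    "uniform"`` gives equal probability within range instead.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    source = np.asarray(source, dtype=float)
    candidates = np.asarray(candidates, dtype=float).reshape(-1, 2)
    d = np.hypot(candidates[:, 0] - source[0], candidates[:, 1] - source[1])
    w = _kernel_weights(d, max_dist, kernel)
    if w is None:
        return None
    return w / w.sum()


def generate_sites(n_sites: int, extent: tuple[float, float],
                   rng: np.random.Generator) -> SiteSet:
    """Draw ``n_sites`` unique uniform home sites over the landscape extent."""
    coords = rng.uniform((0.0, 0.0), extent, size=(n_sites, 2))
    return SiteSet(coords)


def init_population(config: SimConfig, sites: SiteSet,
                    rng: np.random.Generator) -> PopulationState:
    """Fill every site with a random-sex, maximum-diversity individual."""
    n = len(sites)
    return PopulationState(
        generation=0,
        sites=sites,
        site_idx=np.arange(n),
        sexes=rng.integers(0, 2, size=n),
        genotypes=init_genotypes(n, config.n_loci, rng),
    )


def _max_move_dist(config: SimConfig, landscape: LandscapeGrid) -> float:
    return config.max_move_frac * max(landscape.extent)


def select_mates(state: PopulationState, landscape: LandscapeGrid,
                 config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Pair every female that has a male in range with one kernel-drawn male.

    Returns an (n_pairs, 2) array of (female, male) indices into the state
    arrays.  Males are drawn with replacement.  An empty array is valid (the
    population will crash) and is logged.
    """
    females = np.flatnonzero(state.sexes == 0)
    males = np.flatnonzero(state.sexes == 1)
    if len(females) == 0 or len(males) == 0:
        logger.warning("generation %d: no mating pairs (missing sex)",
                       state.generation)
        return np.empty((0, 2), dtype=np.int64)
    max_dist = _max_move_dist(config, landscape)
    coords = state.coords
    dmat = cdist(coords[females], coords[males])
    pairs = []
    for i, f in enumerate(females):
        w = _kernel_weights(dmat[i], max_dist, config.kernel)
        if w is None:
            continue
        m = males[rng.choice(len(males), p=w / w.sum())]
        pairs.append((f, m))
    if not pairs:
        logger.warning("generation %d: no female found a male in range",
                       state.generation)
        return np.empty((0, 2), dtype=np.int64)
    return np.asarray(pairs, dtype=np.int64)


@dataclass
class OffspringPool:
    """Offspring awaiting dispersal; natal coordinates are the mothers' sites."""

    genotypes: np.ndarray  # (n, n_loci, 2)
    sexes: np.ndarray  # (n,)
    natal_site: np.ndarray  # (n,) site indices of the mothers

    def __len__(self) -> int:
        return len(self.sexes)


def reproduce(state: PopulationState, pairs: np.ndarray, config: SimConfig,
              rng: np.random.Generator) -> OffspringPool:
    """Poisson fecundity per pair, Mendelian inheritance, then mutation."""
    if len(pairs) == 0:
        n_loci = state.genotypes.shape[1] if state.size else config.n_loci
        return OffspringPool(
            genotypes=np.empty((0, n_loci, 2), dtype=np.uint8),
            sexes=np.empty(0, dtype=np.int64),
            natal_site=np.empty(0, dtype=np.int64),
        )
    counts = rng.poisson(config.offspring_mean, size=len(pairs))
    mother_rows = np.repeat(pairs[:, 0], counts)
    father_rows = np.repeat(pairs[:, 1], counts)
    kids = mendelian_offspring_many(
        state.genotypes[mother_rows], state.genotypes[father_rows], rng
    )
    kids = mutate(kids, config.mu, rng)
    return OffspringPool(
        genotypes=kids,
        sexes=rng.integers(0, 2, size=len(mother_rows)),
        natal_site=state.site_idx[mother_rows],
    )


def disperse_and_settle(
    pool: OffspringPool,
    sites: SiteSet,
    landscape: LandscapeGrid,
    fitness: FitnessTable,
    config: SimConfig,
    rng: np.random.Generator,
    selection_on: bool,
    site_habitat: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Settle offspring one at a time until sites fill or the pool is spent.

    Offspring are processed in random order.  Each draws one vacant site from
    the truncated inverse-square kernel around its natal site; with selection
    on, it then survives with the survival probability of its genotype class
    in the habitat of that site, otherwise it dies and the site stays vacant
    for later settlers.  Returns (site_idx, sexes, genotypes) of survivors.
    """
    n_sites = len(sites)
    n_loci = pool.genotypes.shape[1] if len(pool) else config.n_loci
    if len(pool) == 0:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
                np.empty((0, n_loci, 2), dtype=np.uint8))

    max_dist = _max_move_dist(config, landscape)
    if site_habitat is None:
        site_habitat = habitat_at(landscape, sites.coords)
    class_codes = classify_counts(pool.genotypes)
    # survival prob per offspring per habitat.  During burn-in the
    # habitat-dependent mortality is withheld: viable classes settle
    # unconditionally, and the a/B incompatibility still kills (unless the
    # run is configured fully neutral).
    viable = fitness.survival.max(axis=1) > 0.0
    if selection_on:
        surv = fitness.survival[class_codes]
        doomed = ~viable[class_codes]  # zero in both habitats: never settles
    elif config.incompatibility_during_burn_in:
        surv = None
        doomed = ~viable[class_codes]
    else:
        surv = None
        doomed = np.zeros(len(pool), dtype=bool)

    # distances from each distinct natal site to every site, computed once
    natal_unique, natal_rows = np.unique(pool.natal_site, return_inverse=True)
    dmat = cdist(sites.coords[natal_unique], sites.coords)

    order = rng.permutation(len(pool))
    order = order[~doomed[order]]  # inviable offspring die before settling
    vacant = np.ones(n_sites, dtype=bool)
    n_vacant = n_sites
    settled_sites: list[int] = []
    settled_off: list[int] = []
    for i in order:
        if n_vacant == 0:
            break
        d = dmat[natal_rows[i]]
        feasible = vacant & (d > 0.0) & (d <= max_dist)
        idx = np.flatnonzero(feasible)
        if idx.size == 0:
            continue  # nowhere to go: offspring dies
        if config.kernel == "uniform":
            j = idx[rng.integers(idx.size)]
        else:
            w = d[idx] ** -2.0
            j = idx[rng.choice(idx.size, p=w / w.sum())]
        if selection_on and rng.random() >= surv[i, site_habitat[j]]:
            continue  # dies at settlement; site stays vacant
        vacant[j] = False
        n_vacant -= 1
        settled_sites.append(int(j))
        settled_off.append(int(i))

    if n_vacant > 0:
        logger.debug("under-filled generation: %d of %d sites vacant",
                     n_vacant, n_sites)
    sel = np.asarray(settled_off, dtype=np.int64)
    return (np.asarray(settled_sites, dtype=np.int64), pool.sexes[sel],
            pool.genotypes[sel])


def _record(generation: int, selection_on: bool,
            state_site_idx: np.ndarray, genotypes: np.ndarray,
            sites: SiteSet) -> GenerationRecord:
    codes = classify_counts(genotypes) if len(genotypes) else np.empty(0, int)
    counts = np.bincount(codes, minlength=9)
    coords = sites.coords[state_site_idx]
    return GenerationRecord(
        generation=generation,
        selection_on=selection_on,
        pop_size=len(state_site_idx),
        class_counts=counts,
        coords_aabb_upper=coords[codes == _AABB_CODE],
        coords_aabb_lower=coords[codes == _AABB_LOWER_CODE],
    )


def step_generation(state: PopulationState, landscape: LandscapeGrid,
                    fitness: FitnessTable, config: SimConfig,
                    rng: np.random.Generator,
                    site_habitat: np.ndarray | None = None) -> PopulationState:
    """Advance one generation: mate, reproduce, kill adults, settle offspring."""
    gen = state.generation + 1
    selection_on = gen > config.burn_in
    pairs = select_mates(state, landscape, config, rng)
    pool = reproduce(state, pairs, config, rng)
    site_idx, sexes, genotypes = disperse_and_settle(
        pool, state.sites, landscape, fitness, config, rng, selection_on,
        site_habitat=site_habitat,
    )
    new_state = PopulationState(
        generation=gen,
        sites=state.sites,
        site_idx=site_idx,
        sexes=sexes,
        genotypes=genotypes,
        records=state.records,
    )
    new_state.records.append(
        _record(gen, selection_on, site_idx, genotypes, state.sites)
    )
    return new_state


def run_simulation(config: SimConfig, landscape: LandscapeGrid,
                   sites: SiteSet | None = None) -> PopulationState:
    """Run ``total_gens`` generations; deterministic given (config.seed, sites).

    The returned state carries one :class:`GenerationRecord` per generation
    (generation 0 summarizes the initial population).  Home sites default to
    a uniform draw from a seed stream separate from the dynamics, so the same
    seed reproduces both the site map and the trajectory.
    """
    site_ss, dyn_ss = np.random.SeedSequence(config.seed).spawn(2)
    if sites is None:
        sites = generate_sites(config.n_sites, landscape.extent,
                               np.random.default_rng(site_ss))
    elif len(sites) != config.n_sites:
        raise ValueError("sites must contain exactly n_sites coordinates")
    rng = np.random.default_rng(dyn_ss)
    state = init_population(config, sites, rng)
    state.records.append(
        _record(0, False, state.site_idx, state.genotypes, sites)
    )
    site_habitat = habitat_at(landscape, sites.coords)
    fitness = fitness_for(config)
    for _ in range(config.total_gens):
        state = step_generation(state, landscape, fitness,
                                config, rng, site_habitat=site_habitat)
        if state.size == 0:
            logger.warning("population extinct at generation %d; stopping",
                           state.generation)
            break
    return state


def fitness_for(config: SimConfig) -> FitnessTable:
    """Fitness table implied by the config's selection strength."""
    from .genetics import build_fitness_table

    return build_fitness_table(config.s)
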