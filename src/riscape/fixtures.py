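"""Synthetic inputs with known ground truth.

These generators emulate the simulator's per-generation outputs (genotype
point tables) and its inputs (toy habitat maps, miniature configs) so each
downstream stage — cluster detection, event tracking, the factorial
analysis — is testable in isolation.  Everything is pure: the same spec and
seed reproduce identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import LandscapeGrid
from .simulator import GenerationRecord, SimConfig

__all__ = [
    "PlantedPattern",
    "make_planted_pattern",
    "make_toy_landscape",
    "make_mini_config",
]


@dataclass(frozen=True)
class PlantedPattern:
    """Ground-truth point pattern: Gaussian clusters plus uniform noise.

    ``centers_upper``/``centers_lower`` are cluster centers for AABB and
    aabb carriers respectively; each cluster gets ``points_per_cluster``
    points drawn isotropic-normal with standard deviation ``spread``.
    ``noise_points`` uniform background points are split evenly between the
    two genotypes over ``extent``.
    """

    centers_upper: tuple[tuple[float, float], ...] = ()
    centers_lower: tuple[tuple[float, float], ...] = ()
    points_per_cluster: int = 20
    spread: float = 200.0
    noise_points: int = 0
    extent: tuple[float, float] = (102_400.0, 102_400.0)
    generation: int = 0
    seed: int = 0


@dataclass
class PlantedRecord:
    """A GenerationRecord look-alike carrying planted ground truth."""

    record: GenerationRecord
    truth_upper: np.ndarray  # per-point planted cluster id, -1 = noise
    truth_lower: np.ndarray


def make_planted_pattern(spec: PlantedPattern) -> PlantedRecord:
    """Draw the planted pattern and package it as a generation record."""
    rng = np.random.default_rng(spec.seed)

    def draw(centers: tuple[tuple[float, float], ...], n_noise: int):
        pts, truth = [], []
        for cid, c in enumerate(centers):
            pts.append(rng.normal(loc=c, scale=spec.spread,
                                  size=(spec.points_per_cluster, 2)))
            truth.append(np.full(spec.points_per_cluster, cid))
        if n_noise:
            pts.append(rng.uniform((0, 0), spec.extent, size=(n_noise, 2)))
            truth.append(np.full(n_noise, -1))
        if not pts:
            return np.empty((0, 2)), np.empty(0, dtype=int)
        return np.concatenate(pts), np.concatenate(truth).astype(int)

    upper, truth_u = draw(spec.centers_upper, spec.noise_points // 2)
    lower, truth_l = draw(spec.centers_lower,
                          spec.noise_points - spec.noise_points // 2)
    counts = np.zeros(9, dtype=np.int64)
    counts[8] = len(upper)
    counts[0] = len(lower)
    rec = GenerationRecord(
        generation=spec.generation,
        selection_on=True,
        pop_size=len(upper) + len(lower),
        class_counts=counts,
        coords_aabb_upper=upper,
        coords_aabb_lower=lower,
    )
    return PlantedRecord(record=rec, truth_upper=truth_u, truth_lower=truth_l)


def make_toy_landscape(kind: str = "half_split",
                       dims: tuple[int, int] = (64, 64),
                       block: int = 8,
                       cell_size: float = 100.0) -> LandscapeGrid:
    """Deterministic toy habitat maps with exact 50/50 proportions.

    ``half_split``: left half habitat 1.  ``checkerboard``: alternating
    blocks of side ``block``.  ``uniform``: all habitat 1 (not 50/50; for
    habitat-independence checks).
    """
    rows, cols = dims
    if kind == "half_split":
        cells = np.zeros(dims, dtype=np.int8)
        cells[:, : cols // 2] = 1
    elif kind == "checkerboard":
        r = np.arange(rows) // block
        c = np.arange(cols) // block
        cells = ((r[:, None] + c[None, :]) % 2).astype(np.int8)
    elif kind == "uniform":
        cells = np.ones(dims, dtype=np.int8)
    else:
        raise ValueError(f"unknown toy landscape kind {kind!r}")
    return LandscapeGrid(cells, cell_size=cell_size)


def make_mini_config(**overrides) -> SimConfig:
    """Miniature run for invariant tests: 200 sites, 20 loci, 60 generations."""
    defaults = dict(
        n_sites=200,
        n_loci=20,
        mu=0.0005,
        offspring_mean=4.0,
        max_move_frac=0.25,
        s=0.16,
        burn_in=10,
        total_gens=60,
        seed=1234,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)
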