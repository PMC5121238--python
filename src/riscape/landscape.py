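"""Binary neutral landscapes with tunable spatial aggregation.

Habitat maps are generated as midpoint-displacement fractal surfaces whose
roughness is controlled by the aggregation parameter ``H`` (0 = maximally
fragmented, 1 = maximally aggregated), then rank-binarized so that an exact
proportion ``p`` of cells carries habitat type 1.  Type 1 cells are the
habitat favoring the AABB genotype; type 0 cells favor aabb.

Rasters use the ESRI ASCII grid dialect on disk; in memory a
:class:`LandscapeGrid` stores the cell array (row 0 = northernmost row, as in
the file format), the cell size, and the lower-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandscapeConfig",
    "LandscapeGrid",
    "generate_fractal_surface",
    "binarize",
    "generate_landscape",
    "habitat_at",
    "join_count_aggregation",
    "write_grid",
    "read_grid",
]


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of a binary neutral landscape.

    Parameters
    ----------
    dims
        (rows, cols) of the raster in pixels.
    H
        Aggregation parameter in [0, 1]; higher values give more aggregated
        (blockier) habitat.
    p
        Proportion of habitat type 1.
    cell_size
        Distance units per pixel edge.  The default of 100 puts a
        1024 x 1024 map at an extent of 102,400 units, so the cluster
        detection radius of 2000 units is ~2% of the extent.
    seed
        RNG seed for the fractal surface.
    """

    dims: tuple[int, int] = (1024, 1024)
    H: float = 0.5
    p: float = 0.5
    cell_size: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.H <= 1.0):
            raise ValueError(f"H must lie in [0, 1], got {self.H}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p must lie in (0, 1], got {self.p}")
        if self.dims[0] <= 0 or self.dims[1] <= 0:
            raise ValueError(f"dims must be positive, got {self.dims}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")


@dataclass
class LandscapeGrid:
    """Binary habitat raster; 1 = AABB habitat, 0 = aabb habitat."""

    cells: np.ndarray  # (rows, cols) over {0, 1}; row 0 is the top row
    cell_size: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)  # (x, y) of the lower-left corner

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.ndim != 2:
            raise ValueError("cells must be a 2-D array")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("cells must contain only 0 and 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) in distance units."""
        rows, cols = self.cells.shape
        return cols * self.cell_size, rows * self.cell_size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandscapeGrid):
            return NotImplemented
        return (
            np.array_equal(self.cells, other.cells)
            and self.cell_size == other.cell_size
            and self.origin == other.origin
        )


def _next_pow2(n: int) -> int:
    k = 1
    while k < n:
        k *= 2
    return k


def generate_fractal_surface(config: LandscapeConfig) -> np.ndarray:
    """Midpoint-displacement fractional Brownian surface.

    Runs the diamond-square recursion on a padded (2^n + 1) grid and crops to
    ``config.dims``.  The displacement standard deviation shrinks by 2^-H per
    subdivision level, so H tunes the roughness: H near 0 leaves variance at
    every scale (fragmented maps after binarization), H near 1 concentrates
    variance at coarse scales (aggregated maps).  Deterministic given seed.
    """
    rows, cols = config.dims
    rng = np.random.default_rng(config.seed)
    size = _next_pow2(max(rows, cols))  # grid is (size+1) x (size+1)
    n = size + 1
    surf = np.zeros((n, n))
    surf[0, 0], surf[0, -1], surf[-1, 0], surf[-1, -1] = rng.normal(size=4)

    step = size
    scale = 1.0
    while step > 1:
        half = step // 2
        # diamond step: centers of squares
        cr = np.arange(half, n, step)
        cc = np.arange(half, n, step)
        ci, cj = np.meshgrid(cr, cc, indexing="ij")
        avg = 0.25 * (
            surf[ci - half, cj - half]
            + surf[ci - half, cj + half]
            + surf[ci + half, cj - half]
            + surf[ci + half, cj + half]
        )
        surf[ci, cj] = avg + rng.normal(scale=scale, size=ci.shape)

        # square step: edge midpoints on two interleaved lattices, averaging
        # the in-bounds diamond neighbors
        r1, c1 = np.meshgrid(np.arange(0, n, step), np.arange(half, n, step), indexing="ij")
        r2, c2 = np.meshgrid(np.arange(half, n, step), np.arange(0, n, step), indexing="ij")
        ei = np.concatenate([r1.ravel(), r2.ravel()])
        ej = np.concatenate([c1.ravel(), c2.ravel()])
        total = np.zeros(ei.shape)
        count = np.zeros(ei.shape)
        for dr, dc in ((-half, 0), (half, 0), (0, -half), (0, half)):
            rr, cc_ = ei + dr, ej + dc
            ok = (rr >= 0) & (rr < n) & (cc_ >= 0) & (cc_ < n)
            total[ok] += surf[rr[ok], cc_[ok]]
            count[ok] += 1
        surf[ei, ej] = total / count + rng.normal(scale=scale, size=ei.shape)

        step = half
        scale *= 2.0 ** (-config.H)

    return surf[:rows, :cols].copy()


def binarize(surface: np.ndarray, p: float, cell_size: float = 100.0,
             origin: tuple[float, float] = (0.0, 0.0)) -> LandscapeGrid:
    """Rank-threshold a surface into a binary grid with exactly round(p*n) 1-cells.

    The round(p*n) highest-valued cells become habitat 1; ties are broken by
    raster-scan order (lower flat index wins), so the result is deterministic
    even on degenerate constant surfaces.
    """
    surface = np.asarray(surface, dtype=float)
    if not np.isfinite(surface).all():
        raise ValueError("surface must be finite-valued")
    n = surface.size
    k = int(round(p * n))
    order = np.argsort(-surface.ravel(), kind="stable")  # stable: ties by scan order
    cells = np.zeros(n, dtype=np.int8)
    cells[order[:k]] = 1
    return LandscapeGrid(cells.reshape(surface.shape), cell_size=cell_size, origin=origin)


def generate_landscape(config: LandscapeConfig) -> LandscapeGrid:
    """Fractal surface + rank binarization in one call."""
    return binarize(generate_fractal_surface(config), config.p,
                    cell_size=config.cell_size)


def habitat_at(grid: LandscapeGrid, xy) -> int:
    """Habitat label of the pixel containing ``xy``.

    Pixel membership uses half-open intervals [x0, x0 + cell_size) so each
    coordinate maps to exactly one pixel; coordinates outside the extent
    raise ValueError.  Accepts a single (x, y) pair or an (n, 2) array.
    """
    xy = np.asarray(xy, dtype=float)
    single = xy.ndim == 1
    pts = np.atleast_2d(xy)
    rows, cols = grid.cells.shape
    x0, y0 = grid.origin
    col = np.floor((pts[:, 0] - x0) / grid.cell_size).astype(int)
    # row 0 of the array is the top row; y increases upward from the origin
    row_from_bottom = np.floor((pts[:, 1] - y0) / grid.cell_size).astype(int)
    row = rows - 1 - row_from_bottom
    if ((col < 0) | (col >= cols) | (row < 0) | (row >= rows)).any():
        raise ValueError("coordinate outside landscape extent")
    labels = grid.cells[row, col]
    return int(labels[0]) if single else labels.astype(int)


def join_count_aggregation(grid: LandscapeGrid) -> float:
    """Proportion of rook-adjacent cell pairs with matching habitat.

    A standard join-count aggregation summary: 0.5 for a random map at
    p = 0.5, approaching 1 for fully aggregated maps.
    """
    c = grid.cells
    horiz = c[:, :-1] == c[:, 1:]
    vert = c[:-1, :] == c[1:, :]
    return float((horiz.sum() + vert.sum()) / (horiz.size + vert.size))


def write_grid(grid: LandscapeGrid, path) -> None:
    """Write a grid as an ESRI ASCII raster."""
    rows, cols = grid.cells.shape
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {grid.origin[0]}\n"
        f"yllcorner {grid.origin[1]}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.cells, fmt="%d")


def read_grid(path) -> LandscapeGrid:
    """Read an ESRI ASCII raster written by :func:`write_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        cells = np.loadtxt(fh, dtype=np.int8, ndmin=2)
    if cells.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid body does not match header dimensions")
    return LandscapeGrid(
        cells,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )
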