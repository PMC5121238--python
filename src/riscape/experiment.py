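"""Factorial simulation experiment and its analysis of variance.

The full design crosses six dispersal levels (3–50% of landscape extent),
six selection strengths (0.02–0.64) and three landscape aggregation levels
(H = 0.1, 0.5, 0.9), with replicate landscapes and Monte Carlo replicates
per cell.  Each run is summarized by the mean duration, number, and size of
reproductively isolated clusters; cell means feed a balanced three-way
factorial ANOVA (main effects and two-way interactions, with the three-way
stratum as residual).

The ``desk`` profile keeps the full 6 x 6 x 3 factor structure but shrinks
the population, landscape and run length so the sweep fits on a workstation;
the ``full`` profile reproduces the published scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .landscape import LandscapeConfig, LandscapeGrid, generate_landscape
from .ri import DBSCANParams, detect_ri, summarize, track_events
from .simulator import SimConfig, run_simulation

__all__ = [
    "Design",
    "build_design",
    "run_scenario",
    "run_experiment",
    "scenario_means",
    "factorial_anova",
    "render_outputs",
]

DISPERSAL_LEVELS = (0.03, 0.05, 0.10, 0.15, 0.25, 0.50)
SELECTION_LEVELS = (0.02, 0.04, 0.08, 0.16, 0.32, 0.64)
H_LEVELS = (0.1, 0.5, 0.9)

RESPONSES = ("duration", "number", "size")

# full-scale population density: 5000 sites on a 1024 x 1024 map of
# 100-unit cells; desk landscapes shrink but keep this density
_FULL_EXTENT = 1024 * 100.0
_FULL_DENSITY = 5000 / _FULL_EXTENT**2


@dataclass(frozen=True)
class Design:
    """Factor levels, replication and per-run scale of the experiment."""

    dispersal_levels: tuple[float, ...] = DISPERSAL_LEVELS
    selection_levels: tuple[float, ...] = SELECTION_LEVELS
    H_levels: tuple[float, ...] = H_LEVELS
    n_landscape_reps: int = 10
    n_mc_reps: int = 10
    profile: str = "full"
    # per-run scale
    n_sites: int = 5000
    dims: tuple[int, int] = (1024, 1024)
    cell_size: float = 100.0
    n_loci: int = 100
    mu: float = 0.0005
    offspring_mean: float = 4.0
    burn_in: int = 250
    total_gens: int = 1250
    pairing: str = "paired"  # landscape rep i runs with MC seed i
    dbscan: DBSCANParams = field(default_factory=DBSCANParams)

    @property
    def n_cells(self) -> int:
        return (len(self.dispersal_levels) * len(self.selection_levels)
                * len(self.H_levels))

    def cells(self) -> list[tuple[float, float, float]]:
        return [(d, s, h)
                for h in self.H_levels
                for s in self.selection_levels
                for d in self.dispersal_levels]


def build_design(profile: str = "desk", **overrides) -> Design:
    """``full`` reproduces the published 108-cell scale; ``desk`` shrinks
    population (500), landscape (256 x 256 at matched site density), run
    length (300 generations incl. 50 burn-in) and replication (3 x 3)."""
    if profile == "full":
        design = Design(profile="full")
    elif profile == "desk":
        dims = (256, 256)
        # 2000 is the smallest population for which desk-scale mating
        # neighborhoods stay viable: the expected number of mates within
        # reach scales as pi * N * D^2, so at D = 0.05 an N = 500
        # population would average ~2 reachable males and collapse through
        # mate-finding failure regardless of selection.
        n_sites = 2000
        # keep individuals per unit area equal to the full-scale design
        extent = np.sqrt(n_sites / _FULL_DENSITY)
        design = Design(
            profile="desk",
            n_landscape_reps=3,
            n_mc_reps=3,
            n_sites=n_sites,
            dims=dims,
            cell_size=float(extent / dims[0]),
            burn_in=50,
            total_gens=300,
        )
    else:
        raise ValueError(f"unknown profile {profile!r}")
    return replace(design, **overrides) if overrides else design


def _derived_seed(*parts: int) -> int:
    """Deterministic sub-seed below 2**31 from integer indices."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % 2**31)


def landscape_for(design: Design, H: float, rep: int,
                  base_seed: int = 0) -> LandscapeGrid:
    """Replicate landscape ``rep`` for aggregation level ``H``."""
    h_idx = design.H_levels.index(H)
    cfg = LandscapeConfig(
        dims=design.dims, H=H, p=0.5, cell_size=design.cell_size,
        seed=_derived_seed(base_seed, 1, h_idx, rep),
    )
    return generate_landscape(cfg)


def run_scenario(design: Design, dispersal: float, s: float, H: float,
                 rep: int, base_seed: int = 0,
                 landscape: LandscapeGrid | None = None) -> dict:
    """One replicate run of one factorial cell, summarized.

    Detection runs on post-burn-in generations only; a run with no RI event
    contributes 0 for all three responses, keeping the design balanced.
    """
    if landscape is None:
        landscape = landscape_for(design, H, rep, base_seed)
    # the dynamics seed depends on (D, H, rep) but not on s: runs differing
    # only in selection strength share sites, initial population and burn-in
    # (common random numbers), which sharpens paired contrasts across s
    run_key = (int(round(dispersal * 1000)), int(round(H * 10)), rep)
    config = SimConfig(
        n_sites=design.n_sites, n_loci=design.n_loci, mu=design.mu,
        offspring_mean=design.offspring_mean, max_move_frac=dispersal, s=s,
        burn_in=design.burn_in, total_gens=design.total_gens,
        seed=_derived_seed(base_seed, 2, *run_key),
    )
    state = run_simulation(config, landscape)
    detections = [detect_ri(r, design.dbscan)
                  for r in state.records if r.selection_on]
    events = track_events(detections)
    duration, number, size = summarize(events, detections)
    return {
        "D": dispersal, "S": s, "H": H, "rep": rep,
        "duration": duration, "number": number, "size": size,
        "n_events": len(events),
        "final_pop": state.size,
    }


def run_experiment(design: Design, base_seed: int = 0,
                   out_dir: str | Path | None = None,
                   progress: bool = False) -> pd.DataFrame:
    """Run every (cell, replicate) of the design; one summary row per run.

    With ``out_dir`` the per-cell tables are written as CSV as they finish
    and existing files are skipped, so an interrupted sweep resumes.
    Pairing is ``paired`` (landscape replicate i runs with MC seed i, the
    default) — replication count is then ``n_landscape_reps``.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    n_reps = design.n_landscape_reps
    frames = []
    # landscapes are shared across cells with the same H
    cache: dict[tuple[float, int], LandscapeGrid] = {}
    for ci, (d, s, h) in enumerate(design.cells()):
        path = out / f"cell_{ci:03d}.csv" if out is not None else None
        if path is not None and path.exists():
            frames.append(pd.read_csv(path))
            continue
        rows = []
        for rep in range(n_reps):
            key = (h, rep)
            if key not in cache:
                cache[key] = landscape_for(design, h, rep, base_seed)
            rows.append(run_scenario(design, d, s, h, rep, base_seed,
                                     landscape=cache[key]))
        cell = pd.DataFrame(rows)
        if path is not None:
            cell.to_csv(path, index=False)
        frames.append(cell)
        if progress:
            print(f"cell {ci + 1}/{design.n_cells}: D={d} S={s} H={h} done")
    return pd.concat(frames, ignore_index=True)


def scenario_means(results: pd.DataFrame) -> pd.DataFrame:
    """Average replicate rows into one row per (D, S, H) cell."""
    return (results.groupby(["D", "S", "H"], as_index=False)
            [list(RESPONSES)].mean())


_TERMS = {
    "C(H)": "Heterogeneity",
    "C(S)": "Selection",
    "C(D)": "Dispersal",
    "C(H):C(S)": "Heterogeneity:Selection",
    "C(H):C(D)": "Heterogeneity:Dispersal",
    "C(S):C(D)": "Selection:Dispersal",
    "Residual": "Residuals",
}


def factorial_anova(summary: pd.DataFrame, response: str = "duration") -> pd.DataFrame:
    """Three-way factorial ANOVA on a balanced table of cell means.

    Fits main effects plus all two-way interactions; the three-way
    interaction stratum is the residual.  Sums of squares are sequential
    (type I), which is unique under balance.  Rejects unbalanced input.
    """
    if response not in summary.columns:
        raise ValueError(f"response {response!r} not in table")
    counts = summary.groupby(["D", "S", "H"]).size()
    n_cells = (summary["D"].nunique() * summary["S"].nunique()
               * summary["H"].nunique())
    if len(counts) != n_cells or counts.nunique() != 1:
        raise ValueError("factorial_anova requires a balanced full cross "
                         "with equal replication per cell")
    data = summary.rename(columns={response: "y"})
    if np.ptp(data["y"].to_numpy(float)) == 0.0:
        # degenerate constant response: every stratum SS is exactly 0 and
        # the F ratios are undefined
        a, b, c = (data[f].nunique() for f in ("H", "S", "D"))
        dfs = [a - 1, b - 1, c - 1, (a - 1) * (b - 1), (a - 1) * (c - 1),
               (b - 1) * (c - 1)]
        dfs.append(len(data) - 1 - sum(dfs))
        return pd.DataFrame(
            {"DF": dfs, "SS": 0.0, "Mean square": 0.0,
             "F-value": np.nan, "Pr > F": np.nan},
            index=list(_TERMS.values()),
        )
    model = smf.ols(
        "y ~ C(H) + C(S) + C(D) + C(H):C(S) + C(H):C(D) + C(S):C(D)",
        data=data,
    ).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table = table.rename(index=_TERMS)
    table = table.rename(columns={
        "df": "DF", "sum_sq": "SS", "mean_sq": "Mean square",
        "F": "F-value", "PR(>F)": "Pr > F",
    })
    table["DF"] = table["DF"].astype(int)
    return table.loc[list(_TERMS.values())]


def render_outputs(summary: pd.DataFrame,
                   anovas: dict[str, pd.DataFrame],
                   out_dir: str | Path,
                   plots: bool = True) -> list[Path]:
    """Write the cell-mean table, per-response ANOVA tables, and response
    surfaces (6 x 6 dispersal x selection panels per aggregation level)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = [out / "summary.csv"]
    summary.to_csv(written[0], index=False)
    for resp, table in anovas.items():
        p = out / f"anova_{resp}.csv"
        table.to_csv(p, index_label="Term")
        written.append(p)
    if plots:
        written.extend(_plot_response_surfaces(summary, out))
    return written


def plot_genotype_map(state, path: str | Path) -> Path:
    """Map of the two incompatible homozygote classes at one generation:
    AABB orange, aabb blue, every other genotype grey."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .genetics import classify_counts

    codes = classify_counts(state.genotypes)
    coords = state.coords
    fig, ax = plt.subplots(figsize=(6, 6))
    other = (codes != 8) & (codes != 0)
    ax.scatter(*coords[other].T, s=6, c="0.7", label="other")
    ax.scatter(*coords[codes == 8].T, s=8, c="tab:orange", label="AABB")
    ax.scatter(*coords[codes == 0].T, s=8, c="tab:blue", label="aabb")
    ax.set_aspect("equal")
    ax.legend(loc="upper right", fontsize=8)
    ax.set_title(f"generation {state.generation}")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def _plot_response_surfaces(summary: pd.DataFrame, out: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    h_levels = sorted(summary["H"].unique())
    for resp in RESPONSES:
        fig, axes = plt.subplots(1, len(h_levels),
                                 figsize=(4 * len(h_levels), 3.5),
                                 squeeze=False)
        vmax = max(summary[resp].max(), 1e-9)
        for ax, h in zip(axes[0], h_levels):
            pivot = (summary[summary["H"] == h]
                     .pivot(index="S", columns="D", values=resp)
                     .sort_index(ascending=False))
            im = ax.imshow(pivot.to_numpy(), vmin=0, vmax=vmax, cmap="viridis",
                           aspect="auto")
            ax.set_xticks(range(len(pivot.columns)),
                          [f"{d:g}" for d in pivot.columns])
            ax.set_yticks(range(len(pivot.index)),
                          [f"{s:g}" for s in pivot.index])
            ax.set_xlabel("dispersal (fraction of extent)")
            ax.set_ylabel("selection strength s")
            ax.set_title(f"H = {h:g}")
        fig.colorbar(im, ax=axes[0], label=f"mean {resp}")
        p = out / f"surface_{resp}.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths
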