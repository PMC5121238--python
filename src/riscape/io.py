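"""Plain-text serialization of simulator output.

Per-generation individual tables use a flat CSV layout: one row per
individual with id, coordinates, sex, the selected two-locus class, and
optionally the full allele dump (two columns per locus,
``L<i>_a1``/``L<i>_a2``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genetics import SELECTED_CLASSES, classify_counts
from .simulator import GenerationRecord, PopulationState, SimConfig

__all__ = [
    "state_to_frame",
    "write_state_csv",
    "read_points_csv",
    "records_to_frame",
    "write_config",
    "read_config",
]


def state_to_frame(state: PopulationState, alleles: bool = False) -> pd.DataFrame:
    """One row per living individual."""
    coords = state.coords
    codes = classify_counts(state.genotypes) if state.size else np.empty(0, int)
    df = pd.DataFrame({
        "id": np.arange(state.size),
        "x": coords[:, 0] if state.size else [],
        "y": coords[:, 1] if state.size else [],
        "sex": np.where(state.sexes == 0, "F", "M") if state.size else [],
        "selected_class": [SELECTED_CLASSES[c] for c in codes],
    })
    if alleles and state.size:
        n_loci = state.genotypes.shape[1]
        flat = state.genotypes.reshape(state.size, n_loci * 2)
        cols = [f"L{i}_a{j + 1}" for i in range(n_loci) for j in range(2)]
        df = pd.concat([df, pd.DataFrame(flat, columns=cols)], axis=1)
    return df


def write_state_csv(state: PopulationState, path, alleles: bool = False) -> None:
    state_to_frame(state, alleles=alleles).to_csv(path, index=False)


def read_points_csv(path) -> GenerationRecord:
    """Rebuild a generation record (coordinates keyed by selected class)
    from an individual table written by :func:`write_state_csv` or by the
    fixtures CSV emitter."""
    df = pd.read_csv(path)
    counts = np.zeros(9, dtype=np.int64)
    for i, name in enumerate(SELECTED_CLASSES):
        counts[i] = int((df["selected_class"] == name).sum())
    upper = df.loc[df["selected_class"] == "AABB", ["x", "y"]].to_numpy(float)
    lower = df.loc[df["selected_class"] == "aabb", ["x", "y"]].to_numpy(float)
    return GenerationRecord(
        generation=0,
        selection_on=True,
        pop_size=len(df),
        class_counts=counts,
        coords_aabb_upper=upper,
        coords_aabb_lower=lower,
    )


def write_points_csv(record: GenerationRecord, path) -> None:
    """Write a generation record's selected-class carriers in the same CSV
    dialect as :func:`write_state_csv` (other classes are not positioned in
    a bare record, so only AABB/aabb rows appear)."""
    n_u = len(record.coords_aabb_upper)
    n_l = len(record.coords_aabb_lower)
    xy = np.concatenate([
        record.coords_aabb_upper.reshape(-1, 2),
        record.coords_aabb_lower.reshape(-1, 2),
    ]) if n_u + n_l else np.empty((0, 2))
    pd.DataFrame({
        "id": np.arange(n_u + n_l),
        "x": xy[:, 0],
        "y": xy[:, 1],
        "sex": "U",
        "selected_class": ["AABB"] * n_u + ["aabb"] * n_l,
    }).to_csv(path, index=False)


def records_to_frame(records: list[GenerationRecord]) -> pd.DataFrame:
    """Tidy per-generation summary table."""
    rows = []
    for r in records:
        row = {
            "generation": r.generation,
            "selection_on": r.selection_on,
            "pop_size": r.pop_size,
            "n_AABB": int(r.class_counts[8]),
            "n_aabb": int(r.class_counts[0]),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def write_config(config: SimConfig, path) -> None:
    """Key-value YAML mirroring the SimConfig field names."""
    Path(path).write_text(yaml.safe_dump(dict(vars(config)), sort_keys=False))


def read_config(path) -> SimConfig:
    data = yaml.safe_load(Path(path).read_text())
    return SimConfig(**data)
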