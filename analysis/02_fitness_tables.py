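#!/usr/bin/env python
"""Build the genotype x habitat survival tables for all selection levels.

Writes results/fitness_table.csv: one row per selection strength, one
column per two-locus genotype class, entries = survival probability in
AABB habitat (the aabb-habitat table is its genotype mirror image).
"""

from pathlib import Path

import pandas as pd

from riscape.genetics import SELECTED_CLASSES, build_fitness_table

OUT = Path(__file__).resolve().parents[1] / "results"
SELECTION_LEVELS = (0.02, 0.04, 0.08, 0.16, 0.32, 0.64)
COLUMN_ORDER = ["AABB", "AABb", "AAbb", "AaBB", "AaBb", "Aabb",
                "aaBB", "aaBb", "aabb"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in SELECTION_LEVELS:
        table = build_fitness_table(s)
        rows.append({"selection_pct": int(s * 100)}
                    | {cls: table.get(cls, habitat=1) for cls in COLUMN_ORDER})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "fitness_table.csv", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
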