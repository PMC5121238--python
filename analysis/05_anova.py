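#!/usr/bin/env python
"""Factorial ANOVA of the sweep's cell means and response surfaces.

Reads results/sweep/summary.csv (written by 04_factorial_sweep.py), fits
the three-way factorial ANOVA (main effects + two-way interactions,
three-way stratum as residual) for each response, and writes
anova_{duration,number,size}.csv plus response-surface figures.  With the
full 108-cell design the degrees-of-freedom column is
(2, 5, 5, 10, 10, 25, 50); sub-designs give correspondingly smaller strata.
"""

from pathlib import Path

import pandas as pd

from riscape.experiment import RESPONSES, factorial_anova, render_outputs

SWEEP = Path(__file__).resolve().parents[1] / "results" / "sweep"


def main() -> None:
    summary = pd.read_csv(SWEEP / "summary.csv")
    anovas = {}
    for resp in RESPONSES:
        anovas[resp] = factorial_anova(summary, resp)
        print(f"\n=== {resp} ===")
        print(anovas[resp].round(3).to_string())
    written = render_outputs(summary, anovas, SWEEP)
    print("\nwrote:", *[p.name for p in written])


if __name__ == "__main__":
    main()
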