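#!/usr/bin/env python
"""GNP-LEM dosimetry: survival reduction by particle size and distribution.

Builds the calibrated radial-dose kernel, samples 367,000 GNPs in each of
the three intracellular distribution scenarios, superposes the kernels onto
10,000 nucleus integration points at 2 Gy, and converts the heterogeneous
dose field to survival with the local effect model (alpha = 0.002 / Gy,
beta = 0.079 / Gy^2). Three seeds per scenario, for 10 nm and 2 nm GNPs.
Writes results/lem_reductions.csv. Takes a few minutes.
"""

from pathlib import Path

import pandas as pd

from gnplem.lem import run_scenario

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

frames = []
for diameter in (10.0, 2.0):
    for scenario in ("uniform_cytoplasm", "perinuclear", "vesicle"):
        df = run_scenario(scenario, 367_000, diameter, seeds=(0, 1, 2))
        frames.append(df)
        print(
            f"{diameter:4.0f} nm  {scenario:18s}  "
            f"SF reduction {df['reduction_pct'].mean():.4f}% "
            f"(seed spread {df['reduction_pct'].std():.4f})"
        )
all_runs = pd.concat(frames, ignore_index=True)
all_runs.to_csv(OUT / "lem_reductions.csv", index=False)

summary = all_runs.groupby(["diameter_nm", "scenario"])["reduction_pct"].mean()
best10 = summary.loc[10.0].idxmax()
print(
    f"\nLargest physical-dose effect: {best10} distribution of 10 nm GNPs "
    f"({summary.loc[(10.0, best10)]:.3f}% survival reduction) — a small fraction "
    "of the ~19% measured biologically, so physics dosimetry alone does not "
    "explain the observed sensitization."
)
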