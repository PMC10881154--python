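#!/usr/bin/env python
"""Orientation-bin summaries per condition from the simulated angle tables.

For each condition: the percentage of parallel (≤30°), oblique, and
perpendicular (≥60°) divisions, the median and quartiles, and the pairwise
two-sample KS tests between conditions. Writes results/angle_bins.csv and
results/angle_ks_tests.csv.
"""

import itertools
from pathlib import Path

import pandas as pd

from spindlestats.angle_geometry import AngleSample, distribution_summary
from spindlestats.randomization import ks_two_sample

OUT = Path("results")


def main() -> None:
    df = pd.read_csv(OUT / "simulated" / "angles.csv")
    samples = {
        str(cond): AngleSample(condition=str(cond), angles=tuple(grp["angle_deg"]))
        for cond, grp in df.groupby("condition", sort=False)
    }
    rows = []
    for cond, sample in samples.items():
        s = distribution_summary(sample)
        rows.append({"condition": cond, "n": sample.n,
                     "pct_parallel": s.pct_parallel, "pct_oblique": s.pct_oblique,
                     "pct_perpendicular": s.pct_perpendicular,
                     "median_deg": s.median, "q25_deg": s.q25, "q75_deg": s.q75})
    bins = pd.DataFrame(rows)
    bins.to_csv(OUT / "angle_bins.csv", index=False)

    ks_rows = []
    for a, b in itertools.combinations(samples, 2):
        d, p = ks_two_sample(samples[a].angles, samples[b].angles)
        ks_rows.append({"condition_a": a, "condition_b": b, "ks_d": d, "ks_p": p})
    pd.DataFrame(ks_rows).to_csv(OUT / "angle_ks_tests.csv", index=False)

    print(bins.to_string(index=False))
    print(f"\nwrote {OUT/'angle_bins.csv'} and {OUT/'angle_ks_tests.csv'}")


if __name__ == "__main__":
    main()
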