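#!/usr/bin/env python
"""Tissue morphometry from the simulated section counts.

Pools sections per animal (counts and lengths sum before any division),
then averages per condition: basal/spinous densities per µm of basement
membrane, tissue folding, marker fractions, and rare-event frequencies.
Writes results/morphometry_per_animal.csv and results/morphometry.json.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from spindlestats import io as sio
from spindlestats.morphometry import condition_means, summarize_animals

OUT = Path("results")


def main() -> None:
    sections = sio.read_counts(OUT / "simulated" / "counts.csv",
                               OUT / "simulated" / "geometry.csv")
    animals = summarize_animals(sections)
    rows = []
    for (cond, mouse), s in animals.items():
        rows.append({"condition": cond, "mouse_id": mouse,
                     "basal_density": s.basal_density,
                     "spinous_density": s.spinous_density,
                     "folding": s.folding,
                     "krt10_basal_pct": s.krt10_basal_fraction,
                     "ki67_basal_pct": s.ki67_basal_fraction,
                     "phh3_basal_pct": s.phh3_basal_fraction,
                     **{f"freq[{k}]": v
                        for k, v in s.rare_event_frequency_by_class.items()}})
    per_animal = pd.DataFrame(rows)
    per_animal.to_csv(OUT / "morphometry_per_animal.csv", index=False)
    conds = {c: dataclasses.asdict(s) for c, s in condition_means(animals).items()}
    (OUT / "morphometry.json").write_text(json.dumps({
        "per_condition": conds,
        "aggregation": "mean of per-animal values (animal = unit of replication)",
    }, indent=2))
    print(per_animal.to_string(index=False))
    print(f"\nwrote {OUT/'morphometry_per_animal.csv'} and {OUT/'morphometry.json'}")


if __name__ == "__main__":
    main()
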