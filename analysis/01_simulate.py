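#!/usr/bin/env python
"""Generate the synthetic study pack every later driver consumes.

Emulates the study's four experimental conditions: fixed-tissue angle
samples with the published bin percentages at the published sample sizes,
folded tissue sections at homeostatic densities, a two-genotype tumor
cohort, and live-imaging division tracks. Writes CSV tables plus a
ground-truth JSON under results/simulated/.
"""

import json
from pathlib import Path

import pandas as pd

from spindlestats import io as sio
from spindlestats.synth import (
    PAPER_LIKE_SCENARIO,
    AngleSimSpec,
    CohortSimSpec,
    TissueSimSpec,
    TrackSimSpec,
    binned_angle_sample,
    simulate_cohort,
    simulate_tissue,
    simulate_tracks,
)

SEED = 2025
OUT = Path("results/simulated")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth: dict = {"seed": SEED}

    # fixed-tissue angle samples, one per condition, exact printed bins
    rows = []
    for i, (cond, pcts, n) in enumerate(PAPER_LIKE_SCENARIO):
        sample = binned_angle_sample(*pcts, n=n, seed=SEED + i)
        rows += [{"condition": cond, "angle_deg": a} for a in sample.angles]
    pd.DataFrame(rows).to_csv(OUT / "angles.csv", index=False)
    truth["angle_bins"] = {c: p for c, p, _ in PAPER_LIKE_SCENARIO}

    # homeostatic tissue: wild-type-like densities, mild folding
    tissue = TissueSimSpec(span_um=2500.0, folding_target=1.2,
                           basal_density=0.16, spinous_density=0.19,
                           marker_fractions={"basal": {"KRT10+": 0.46,
                                                       "Ki67+": 0.27,
                                                       "pHH3+": 0.02}},
                           rare_event_rates={"spinous:Ki67+KRT10+KRT5-": 0.0002},
                           n_sections=4, n_mice=3, condition="wt", seed=SEED + 10)
    sections, trace = simulate_tissue(tissue)
    sio.write_counts(sections, OUT / "counts.csv", OUT / "geometry.csv")
    sio.write_traces({"bm": trace}, OUT / "trace.csv")
    truth["tissue"] = {"basal_density": 0.16, "spinous_density": 0.19,
                      "folding": 1.2, "krt10_basal_fraction": 46.0}

    # tumor cohort: low-incidence vs high-incidence genotype
    low = simulate_cohort(CohortSimSpec(n_mice=17, incidence_prob=0.12,
                                        count_mean=1.0, volume_mu=-1.0,
                                        volume_sigma=0.8, genotype="PTEN LGN+/+",
                                        seed=SEED + 20))
    high = simulate_cohort(CohortSimSpec(n_mice=20, incidence_prob=0.35,
                                         count_mean=2.0, volume_mu=2.5,
                                         volume_sigma=1.0, genotype="PTEN LGN-/-",
                                         seed=SEED + 21))
    sio.write_tumors(low + high, OUT / "tumors.csv")
    truth["cohort"] = {"PTEN LGN+/+": {"incidence": 0.12},
                      "PTEN LGN-/-": {"incidence": 0.35}}

    # live-imaging tracks: mostly planar onset, sparse resolution,
    # partial reintegration
    tracks, track_truth = simulate_tracks(
        TrackSimSpec(n_tracks=60,
                     t0_spec=AngleSimSpec(n=1, p_planar=0.7, p_uniform=0.3,
                                          planar_sd=8),
                     resolution_prob=0.2, reintegration_prob=0.4,
                     condition="LGN-/-", seed=SEED + 30))
    sio.write_tracks(tracks, OUT / "track_angles.csv", OUT / "track_frames.csv")
    truth["tracks"] = {"resolution_prob": 0.2, "reintegration_prob": 0.4,
                      "ground_truth": track_truth}

    (OUT / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    print(f"wrote synthetic study pack ({len(rows)} angles, "
          f"{len(sections)} sections, {len(low) + len(high)} mice, "
          f"{len(tracks)} tracks) to {OUT}")


if __name__ == "__main__":
    main()
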