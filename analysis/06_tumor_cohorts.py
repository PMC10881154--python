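#!/usr/bin/env python
"""Tumor-cohort summaries and the between-genotype comparison.

Per genotype: incidence, tumor counts, mean burden (tumor-free mice count
as zero), and largest tumor; then the fold differences between genotypes
and the normality-gated two-group burden test. Writes results/cohorts.json
and results/cohort_comparison.csv.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from spindlestats import io as sio
from spindlestats.cohort import burden, compare_groups, fold_change, summarize_cohort

OUT = Path("results")


def main() -> None:
    records = sio.read_tumors(OUT / "simulated" / "tumors.csv")
    genotypes = sorted({r.genotype for r in records})
    summaries = {}
    for gt in genotypes:
        grp = [r for r in records if r.genotype == gt]
        summaries[gt] = summarize_cohort(grp, "snout")
        print(f"{gt}: n={summaries[gt].n_mice}, incidence "
              f"{summaries[gt].incidence_pct:.1f}%, mean burden "
              f"{summaries[gt].mean_burden_mm3:.2f} mm3, largest "
              f"{summaries[gt].largest_tumor_mm3:.2f} mm3")
    (OUT / "cohorts.json").write_text(json.dumps(
        {gt: dataclasses.asdict(s) for gt, s in summaries.items()}, indent=2))

    rows = []
    if len(genotypes) == 2:
        a, b = genotypes
        burdens_a = [burden(r) for r in records if r.genotype == a]
        burdens_b = [burden(r) for r in records if r.genotype == b]
        cmp = compare_groups(burdens_a, burdens_b)
        fold = fold_change(summaries[b].mean_burden_mm3,
                           summaries[a].mean_burden_mm3) \
            if summaries[a].mean_burden_mm3 else float("nan")
        rows.append({"genotype_a": a, "genotype_b": b,
                     "burden_fold_b_over_a": fold,
                     "incidence_fold_b_over_a": fold_change(
                         summaries[b].incidence_pct, summaries[a].incidence_pct)
                     if summaries[a].incidence_pct else float("nan"),
                     "test": cmp.test_name, "p_value": cmp.p_value})
        print(f"burden fold ({b}/{a}): {fold:.1f}; "
              f"{cmp.test_name} p = {cmp.p_value:.3g}")
    pd.DataFrame(rows).to_csv(OUT / "cohort_comparison.csv", index=False)
    print(f"wrote {OUT/'cohorts.json'} and {OUT/'cohort_comparison.csv'}")


if __name__ == "__main__":
    main()
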