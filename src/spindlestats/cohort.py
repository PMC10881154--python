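"""Tumor-cohort summaries and between-group tests.

Each :class:`TumorRecord` holds one mouse's tumors at one body site (snout,
eyelid, or paw) with volumes in mm³.  Cohort summaries report incidence
(percentage of mice with at least one tumor), per-mouse tumor counts,
burden (summed volume per mouse; tumor-free mice contribute 0 to the
cohort mean, with an option to restrict to tumor-bearing mice), and the
largest individual tumor.  Between-group comparisons apply a Shapiro–Wilk
normality gate: Student's t test when both samples look normal at 0.05,
otherwise the two-tailed Mann–Whitney rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .randomization import mann_whitney, shapiro_wilk, students_t

__all__ = [
    "TumorRecord",
    "CohortSummary",
    "GroupComparison",
    "incidence",
    "burden",
    "cohort_burden",
    "fold_change",
    "summarize_cohort",
    "compare_groups",
]

SITES = ("snout", "eyelid", "paw")


@dataclass(frozen=True)
class TumorRecord:
    mouse_id: str
    genotype: str
    site: str
    volumes: tuple[float, ...] = ()
    eyelids_affected: int | None = None

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        vols = tuple(float(v) for v in self.volumes)
        object.__setattr__(self, "volumes", vols)
        if any(v < 0 for v in vols):
            raise ValueError(f"mouse {self.mouse_id}: negative tumor volume")
        if self.eyelids_affected is not None:
            if self.site != "eyelid":
                raise ValueError("eyelids_affected only applies to the eyelid site")
            if self.eyelids_affected not in (0, 1, 2):
                raise ValueError("eyelids_affected must be 0, 1 or 2")


@dataclass(frozen=True)
class CohortSummary:
    n_mice: int
    incidence_pct: float
    mean_tumor_count: float
    max_tumor_count: int
    mean_burden_mm3: float
    largest_tumor_mm3: float
    burden_includes_tumor_free: bool = True


@dataclass(frozen=True)
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    shapiro_p: tuple[float, float] | None = None


def incidence(records: Sequence[TumorRecord], site: str) -> float:
    """Percentage of mice with at least one tumor at the given site."""
    at_site = [r for r in records if r.site == site]
    if not at_site:
        raise ValueError(f"no mice recorded at site {site!r}")
    affected = sum(1 for r in at_site if len(r.volumes) >= 1)
    return 100.0 * affected / len(at_site)


def burden(record: TumorRecord) -> float:
    """Summed tumor volume of one mouse, mm³."""
    return float(sum(record.volumes))


def cohort_burden(
    records: Sequence[TumorRecord], include_tumor_free: bool = True
) -> float:
    """Mean per-mouse burden over the cohort.

    Tumor-free mice contribute 0 by default; pass
    ``include_tumor_free=False`` to average over tumor-bearing mice only.
    """
    if not records:
        raise ValueError("empty cohort")
    burdens = [burden(r) for r in records]
    if not include_tumor_free:
        burdens = [b for b, r in zip(burdens, records) if len(r.volumes) >= 1]
        if not burdens:
            return 0.0
    return float(np.mean(burdens))


def fold_change(value_a: float, value_b: float, rounding: str = "none") -> float:
    """Ratio value_a / value_b, optionally rounded to the nearest integer."""
    if value_b == 0:
        raise ValueError("zero denominator in fold change")
    ratio = value_a / value_b
    if rounding == "nearest_int":
        return float(round(ratio))
    if rounding != "none":
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return ratio


def summarize_cohort(
    records: Sequence[TumorRecord], site: str, include_tumor_free: bool = True
) -> CohortSummary:
    at_site = [r for r in records if r.site == site]
    if not at_site:
        raise ValueError(f"no mice recorded at site {site!r}")
    counts = [len(r.volumes) for r in at_site]
    all_volumes = [v for r in at_site for v in r.volumes]
    return CohortSummary(
        n_mice=len(at_site),
        incidence_pct=incidence(at_site, site),
        mean_tumor_count=float(np.mean(counts)),
        max_tumor_count=int(max(counts)),
        mean_burden_mm3=cohort_burden(at_site, include_tumor_free),
        largest_tumor_mm3=float(max(all_volumes)) if all_volumes else 0.0,
        burden_includes_tumor_free=include_tumor_free,
    )


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    force: str | None = None,
) -> GroupComparison:
    """Two-group comparison with a Shapiro–Wilk normality gate.

    Both samples are tested for normality at 0.05; if both pass, the
    unpaired two-tailed Student's t test is used, otherwise the two-tailed
    Mann–Whitney test.  Samples smaller than 3 cannot be gated and fall
    through to the rank test.  ``force`` ("t" or "rank") bypasses the gate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("compare_groups requires non-empty samples")
    shapiro_p: tuple[float, float] | None = None
    if force is None:
        if a.size >= 3 and b.size >= 3:
            pa = shapiro_wilk(a)[1]
            pb = shapiro_wilk(b)[1]
            shapiro_p = (pa, pb)
            use_t = pa > 0.05 and pb > 0.05
        else:
            use_t = False
    elif force in ("t", "rank"):
        use_t = force == "t"
    else:
        raise ValueError(f"unknown force mode {force!r}")
    if use_t:
        stat, p = students_t(a, b)
        name = "t"
    else:
        stat, p = mann_whitney(a, b)
        name = "mann-whitney"
    return GroupComparison(test_name=name, statistic=stat, p_value=p, shapiro_p=shapiro_p)
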