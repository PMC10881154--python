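"""Tissue morphometry from per-section count annotations.

Metrics follow the conventions used for sectioned epidermis: cell densities
are cells per µm of basement membrane, tissue folding is basement-membrane
arc length over straight-line tissue span (1 = perfectly flat), marker
fractions are percentages of a layer total, and rare events (TUNEL+ cells,
proliferative KRT5− spinous cells) are events per µm of basement membrane
pooled per animal before division.  The unit of replication for
condition-level statistics is the animal: per-animal values are computed by
pooling sections, then averaged per condition.

``SectionCounts.counts`` maps ``(layer, marker_class)`` to an integer count.
Layers are ``basal``, ``spinous``, ``granular_cornified``; the marker class
``"total"`` holds the layer's denominator for marker fractions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "SectionCounts",
    "MorphometrySummary",
    "cell_density",
    "tissue_folding",
    "marker_fraction",
    "rare_event_frequency",
    "summarize_section",
    "pool_sections",
    "summarize_animals",
    "condition_means",
]

LAYERS = ("basal", "spinous", "granular_cornified")
#: marker classes counted per µm of basement membrane rather than per layer total
RARE_EVENT_CLASSES = ("Ki67+KRT10+KRT5-", "TUNEL+")


@dataclass(frozen=True)
class SectionCounts:
    section_id: str
    condition: str
    mouse_id: str
    bm_length: float
    tissue_span: float
    counts: Mapping[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bm_length <= 0 or self.tissue_span <= 0:
            raise ValueError(
                f"section {self.section_id}: lengths must be positive"
            )
        for (layer, marker), c in self.counts.items():
            if c < 0:
                raise ValueError(
                    f"section {self.section_id}: negative count for {layer}/{marker}"
                )
            total = self.counts.get((layer, "total"))
            if marker != "total" and total is not None and c > total:
                raise ValueError(
                    f"section {self.section_id}: {layer}/{marker} count {c} "
                    f"exceeds layer total {total}"
                )


@dataclass(frozen=True)
class MorphometrySummary:
    """Per-animal (or per-section) morphometry metrics."""

    basal_density: float
    spinous_density: float
    folding: float
    krt10_basal_fraction: float
    ki67_basal_fraction: float
    phh3_basal_fraction: float
    rare_event_frequency_by_class: dict[str, float] = field(default_factory=dict)


def cell_density(count: int, bm_length: float) -> float:
    """Cells per µm of basement membrane."""
    if bm_length <= 0:
        raise ValueError("bm_length must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / bm_length


def tissue_folding(bm_length: float, tissue_span: float) -> float:
    """Basement-membrane arc length over straight-line tissue span (flat = 1)."""
    if bm_length <= 0 or tissue_span <= 0:
        raise ValueError("lengths must be positive")
    return bm_length / tissue_span


def marker_fraction(positive_count: int, layer_total: int) -> float:
    """Percentage of marker-positive cells in a layer."""
    if layer_total <= 0:
        raise ValueError("layer_total must be positive")
    if not (0 <= positive_count <= layer_total):
        raise ValueError(
            f"positive count {positive_count} inconsistent with total {layer_total}"
        )
    return 100.0 * positive_count / layer_total


def rare_event_frequency(event_count: int, bm_length: float) -> float:
    """Events per µm of basement membrane.

    Per-animal frequencies must pool counts and lengths across sections
    before dividing (see :func:`pool_sections`), never average per-section
    ratios.
    """
    if bm_length <= 0:
        raise ValueError("bm_length must be positive")
    if event_count < 0:
        raise ValueError("event_count must be non-negative")
    return event_count / bm_length


def pool_sections(sections: Iterable[SectionCounts]) -> SectionCounts:
    """Pool sections of one animal: counts and lengths sum."""
    sections = list(sections)
    if not sections:
        raise ValueError("no sections to pool")
    ids = {s.mouse_id for s in sections}
    if len(ids) > 1:
        raise ValueError(f"cannot pool sections from different mice: {ids}")
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for s in sections:
        for key, c in s.counts.items():
            counts[key] += c
    return SectionCounts(
        section_id="+".join(s.section_id for s in sections),
        condition=sections[0].condition,
        mouse_id=sections[0].mouse_id,
        bm_length=sum(s.bm_length for s in sections),
        tissue_span=sum(s.tissue_span for s in sections),
        counts=dict(counts),
    )


def _get(counts: Mapping[tuple[str, str], int], layer: str, marker: str) -> int:
    return int(counts.get((layer, marker), 0))


def summarize_section(section: SectionCounts) -> MorphometrySummary:
    """All morphometry metrics for one section (or one pooled animal)."""
    c = section.counts
    basal_total = _get(c, "basal", "total")
    rare = {}
    for layer in LAYERS:
        for cls in RARE_EVENT_CLASSES:
            if (layer, cls) in c:
                rare[f"{layer}:{cls}"] = rare_event_frequency(
                    _get(c, layer, cls), section.bm_length
                )

    def frac(layer: str, marker: str) -> float:
        total = _get(c, layer, "total")
        if total == 0:
            return 0.0
        return marker_fraction(_get(c, layer, marker), total)

    return MorphometrySummary(
        basal_density=cell_density(basal_total, section.bm_length),
        spinous_density=cell_density(_get(c, "spinous", "total"), section.bm_length),
        folding=tissue_folding(section.bm_length, section.tissue_span),
        krt10_basal_fraction=frac("basal", "KRT10+"),
        ki67_basal_fraction=frac("basal", "Ki67+"),
        phh3_basal_fraction=frac("basal", "pHH3+"),
        rare_event_frequency_by_class=rare,
    )


def summarize_animals(
    sections: Iterable[SectionCounts],
) -> dict[tuple[str, str], MorphometrySummary]:
    """Per-animal summaries keyed by (condition, mouse_id), sections pooled."""
    by_animal: dict[tuple[str, str], list[SectionCounts]] = defaultdict(list)
    for s in sections:
        by_animal[(s.condition, s.mouse_id)].append(s)
    return {
        key: summarize_section(pool_sections(group))
        for key, group in sorted(by_animal.items())
    }


def condition_means(
    animal_summaries: Mapping[tuple[str, str], MorphometrySummary],
) -> dict[str, MorphometrySummary]:
    """Condition-level summary as the mean of per-animal values."""
    by_cond: dict[str, list[MorphometrySummary]] = defaultdict(list)
    for (cond, _mouse), summ in animal_summaries.items():
        by_cond[cond].append(summ)
    out = {}
    for cond, summs in sorted(by_cond.items()):
        rare_keys = sorted({k for s in summs for k in s.rare_event_frequency_by_class})
        out[cond] = MorphometrySummary(
            basal_density=float(np.mean([s.basal_density for s in summs])),
            spinous_density=float(np.mean([s.spinous_density for s in summs])),
            folding=float(np.mean([s.folding for s in summs])),
            krt10_basal_fraction=float(
                np.mean([s.krt10_basal_fraction for s in summs])
            ),
            ki67_basal_fraction=float(np.mean([s.ki67_basal_fraction for s in summs])),
            phh3_basal_fraction=float(np.mean([s.phh3_basal_fraction for s in summs])),
            rare_event_frequency_by_class={
                k: float(
                    np.mean([s.rare_event_frequency_by_class.get(k, 0.0) for s in summs])
                )
                for k in rare_keys
            },
        )
    return out
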