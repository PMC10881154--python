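"""Synthetic annotation data with known ground truth.

Every input the pipeline consumes can be generated here: angle samples from
planar-biased mixtures, folded basement-membrane traces with a controllable
folding ratio, per-section marker counts, zero-inflated tumor cohorts, and
live-imaging division tracks with stochastic resolution and reintegration.
All generators are deterministic under a fixed seed and return their ground
truth alongside the data, so every downstream estimator can be checked for
parameter recovery.

Angle mixtures use folded (half-)normal components rather than circular
distributions: the measurement domain is a folded quarter-circle [0°, 90°],
and half-normal CDFs give closed-form bin probabilities for oracles — for
example a pure planar component with σ = 10° puts 2Φ(3) − 1 ≈ 99.73% of
angles in the parallel bin.  Counts are Poisson, marker labels Bernoulli;
no spatial correlation between neighbouring cells is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .angle_geometry import (
    AngleSample,
    BasementMembraneTrace,
    DivisionTrack,
    LIVE_PLANAR_THRESHOLD_DEG,
)
from .morphometry import SectionCounts
from .cohort import TumorRecord

__all__ = [
    "AngleSimSpec",
    "TissueSimSpec",
    "CohortSimSpec",
    "TrackSimSpec",
    "simulate_angles",
    "simulate_tissue",
    "simulate_cohort",
    "simulate_tracks",
    "binned_angle_sample",
    "PAPER_LIKE_SCENARIO",
]


def _fold_to_quarter(x: np.ndarray) -> np.ndarray:
    """Fold arbitrary angles into [0, 90] by reflection."""
    x = np.abs(x) % 180.0
    return np.where(x > 90.0, 180.0 - x, x)


@dataclass(frozen=True)
class AngleSimSpec:
    """Mixture of a planar half-normal, a uniform, and an optional
    perpendicular component reflected at 90°."""

    n: int
    p_planar: float = 0.0
    planar_sd: float = 10.0
    p_uniform: float = 1.0
    p_perp: float = 0.0
    perp_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = (self.p_planar, self.p_uniform, self.p_perp)
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("mixture weights must be >= 0 and sum to 1")
        if self.planar_sd <= 0 or self.perp_sd <= 0:
            raise ValueError("component SDs must be positive")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def simulate_angles(
    spec: AngleSimSpec, condition: str = "synthetic"
) -> tuple[AngleSample, np.ndarray]:
    """Draw an angle sample; returns (sample, per-angle component labels).

    Components: ``planar`` = |N(0, planar_sd)|, ``uniform`` = U(0, 90),
    ``perp`` = 90 − |N(0, perp_sd)|, all folded into [0, 90].
    """
    rng = np.random.Generator(np.random.Philox(key=spec.seed))
    comp = rng.choice(
        3, size=spec.n, p=[spec.p_planar, spec.p_uniform, spec.p_perp]
    )
    angles = np.empty(spec.n)
    planar = comp == 0
    angles[planar] = _fold_to_quarter(rng.normal(0.0, spec.planar_sd, planar.sum()))
    unif = comp == 1
    angles[unif] = rng.uniform(0.0, 90.0, unif.sum())
    perp = comp == 2
    angles[perp] = _fold_to_quarter(90.0 - np.abs(rng.normal(0.0, spec.perp_sd, perp.sum())))
    labels = np.array(["planar", "uniform", "perp"])[comp]
    return AngleSample(condition=condition, angles=tuple(angles)), labels


def binned_angle_sample(
    pct_parallel: float,
    pct_oblique: float,
    pct_perpendicular: float,
    n: int,
    seed: int = 0,
    condition: str = "scenario",
) -> AngleSample:
    """Angle sample with exact orientation-bin counts, uniform within bins.

    Bin counts are the rounded targets (largest-remainder correction keeps
    the total at n), which lets a scenario reproduce printed bin
    percentages exactly at the printed sample size.
    """
    pcts = np.array([pct_parallel, pct_oblique, pct_perpendicular], dtype=float)
    # printed figure percentages may sum to 99 or 101 after integer rounding
    if abs(pcts.sum() - 100.0) > 2.0:
        raise ValueError("bin percentages must sum to ~100")
    raw = pcts / pcts.sum() * n
    counts = np.floor(raw).astype(int)
    for _ in range(n - counts.sum()):
        counts[int(np.argmax(raw - counts))] += 1
    rng = np.random.Generator(np.random.Philox(key=seed))
    lo = np.array([0.0, 30.0, 60.0])
    hi = np.array([30.0, 60.0, 90.0])
    parts = []
    for k in range(3):
        u = rng.random(counts[k])
        a = lo[k] + (hi[k] - lo[k]) * u
        # keep oblique draws off the closed 30°/60° boundaries
        if k == 1:
            a = np.clip(a, np.nextafter(30.0, 90.0), np.nextafter(60.0, 0.0))
        parts.append(a)
    angles = np.concatenate(parts)
    rng.shuffle(angles)
    return AngleSample(condition=condition, angles=tuple(angles))


#: Four-condition scenario mirroring the published fixed-tissue bin
#: percentages and sample sizes (wild type; LGN-null; PTEN-null; double null).
PAPER_LIKE_SCENARIO: tuple[tuple[str, tuple[float, float, float], int], ...] = (
    ("LGN+/+", (80.0, 13.0, 7.0), 45),
    ("LGN-/-", (53.0, 20.0, 27.0), 45),
    ("14d PTEN LGN+/+", (65.0, 20.0, 14.0), 49),
    ("14d PTEN LGN-/-", (34.0, 38.0, 27.0), 44),
)


@dataclass(frozen=True)
class TissueSimSpec:
    """Sinusoidally folded tissue with Poisson cell counts.

    Default densities and folding match the homeostatic snout epidermis
    magnitudes (basal ≈ 0.16 cells/µm, spinous ≈ 0.19 cells/µm, mild
    folding); marker fractions are percentages of each layer total.
    """

    span_um: float = 2000.0
    folding_target: float = 1.2
    basal_density: float = 0.16
    spinous_density: float = 0.19
    marker_fractions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "basal": {"KRT10+": 0.46, "Ki67+": 0.27, "pHH3+": 0.02},
        }
    )
    rare_event_rates: Mapping[str, float] = field(
        default_factory=lambda: {"spinous:Ki67+KRT10+KRT5-": 0.0002}
    )
    n_sections: int = 3
    n_mice: int = 3
    #: SD of the optional per-mouse Gaussian random effect on density rates
    #: (multiplicative, mean 1); 0 disables animal-level heterogeneity.
    mouse_rate_sd: float = 0.0
    condition: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folding_target < 1.0:
            raise ValueError("folding_target must be >= 1 (arc length >= span)")
        if self.span_um <= 0:
            raise ValueError("span_um must be positive")
        if self.basal_density < 0 or self.spinous_density < 0:
            raise ValueError("densities must be >= 0")
        if self.mouse_rate_sd < 0:
            raise ValueError("mouse_rate_sd must be >= 0")


def _sinusoid_trace(
    span: float, folding: float, n_points: int = 400, n_waves: int = 5
) -> BasementMembraneTrace:
    """Sinusoid whose amplitude is solved so (arc length / span) = folding."""
    x = np.linspace(0.0, span, n_points)
    omega = 2.0 * np.pi * n_waves / span

    def ratio(amp: float) -> float:
        y = amp * np.sin(omega * x)
        return float(np.sum(np.hypot(np.diff(x), np.diff(y)))) / span

    if folding == 1.0:
        amp = 0.0
        y = np.zeros_like(x)
    else:
        hi = span / n_waves
        while ratio(hi) < folding:
            hi *= 2.0
        amp = brentq(lambda a: ratio(a) - folding, 0.0, hi, xtol=1e-10)
        y = amp * np.sin(omega * x)
    return BasementMembraneTrace(points=tuple(zip(x.tolist(), y.tolist())))


def simulate_tissue(
    spec: TissueSimSpec,
) -> tuple[list[SectionCounts], BasementMembraneTrace]:
    """Per-section count tables plus the folded basement-membrane trace."""
    rng = np.random.Generator(np.random.Philox(key=spec.seed))
    trace = _sinusoid_trace(spec.span_um, spec.folding_target)
    from .angle_geometry import polyline_arc_length

    bm_length = polyline_arc_length(trace.points)
    sections = []
    for m in range(spec.n_mice):
        rate_mult = 1.0
        if spec.mouse_rate_sd > 0:
            rate_mult = max(0.0, float(rng.normal(1.0, spec.mouse_rate_sd)))
        for s in range(spec.n_sections):
            counts: dict[tuple[str, str], int] = {}
            basal_total = int(rng.poisson(rate_mult * spec.basal_density * bm_length))
            spinous_total = int(rng.poisson(rate_mult * spec.spinous_density * bm_length))
            counts[("basal", "total")] = basal_total
            counts[("spinous", "total")] = spinous_total
            for layer, fracs in spec.marker_fractions.items():
                total = counts.get((layer, "total"), 0)
                for marker, p in fracs.items():
                    counts[(layer, marker)] = int(rng.binomial(total, p))
            for key, rate in spec.rare_event_rates.items():
                layer, cls = key.split(":", 1)
                counts[(layer, cls)] = int(rng.poisson(rate * bm_length))
            sections.append(
                SectionCounts(
                    section_id=f"m{m}s{s}",
                    condition=spec.condition,
                    mouse_id=f"mouse{m}",
                    bm_length=bm_length,
                    tissue_span=spec.span_um,
                    counts=counts,
                )
            )
    return sections, trace


@dataclass(frozen=True)
class CohortSimSpec:
    """Zero-inflated tumor cohort: Bernoulli incidence, zero-truncated
    Poisson tumor count given affected, iid log-normal volumes (mm³)."""

    n_mice: int = 20
    incidence_prob: float = 0.35
    count_mean: float = 2.0  # zero-truncated Poisson rate λ
    volume_mu: float = 1.0  # log-scale mean of mm³ volumes
    volume_sigma: float = 1.0
    genotype: str = "synthetic"
    site: str = "snout"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.incidence_prob <= 1.0):
            raise ValueError("incidence_prob must be in [0, 1]")
        if self.volume_sigma <= 0 or self.count_mean <= 0:
            raise ValueError("count_mean and volume_sigma must be positive")


def _zt_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson by rejection; mean is λ / (1 − e^{−λ})."""
    out = np.zeros(size, dtype=int)
    todo = np.arange(size)
    while todo.size:
        draw = rng.poisson(lam, todo.size)
        ok = draw > 0
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def simulate_cohort(spec: CohortSimSpec) -> list[TumorRecord]:
    rng = np.random.Generator(np.random.Philox(key=spec.seed))
    affected = rng.random(spec.n_mice) < spec.incidence_prob
    counts = np.zeros(spec.n_mice, dtype=int)
    counts[affected] = _zt_poisson(rng, spec.count_mean, int(affected.sum()))
    records = []
    for i in range(spec.n_mice):
        vols = tuple(
            float(v)
            for v in rng.lognormal(spec.volume_mu, spec.volume_sigma, counts[i])
        )
        records.append(
            TumorRecord(
                mouse_id=f"mouse{i}",
                genotype=spec.genotype,
                site=spec.site,
                volumes=vols,
            )
        )
    return records


@dataclass(frozen=True)
class TrackSimSpec:
    """Live-imaging division tracks at 5-min frames.

    Non-planar divisions (t0 above the live planar threshold) resolve to
    planar by +60 min with ``resolution_prob``; their suprabasal daughter
    reintegrates into the basal layer after ``reintegration_delay`` frames
    with ``reintegration_prob``.
    """

    n_tracks: int = 40
    t0_spec: AngleSimSpec = field(
        default_factory=lambda: AngleSimSpec(n=1, p_planar=0.8, p_uniform=0.2)
    )
    resolution_prob: float = 0.2
    reintegration_prob: float = 0.4
    reintegration_delay: int = 36  # frames (3 h)
    track_length: int = 120  # frames (10 h)
    condition: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.resolution_prob, self.reintegration_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")


def simulate_tracks(
    spec: TrackSimSpec,
) -> tuple[list[DivisionTrack], dict[str, dict[str, bool]]]:
    """Division tracks plus per-track ground truth flags.

    Ground truth maps division_id to {"nonplanar", "resolved",
    "reintegrated"} booleans.
    """
    rng = np.random.Generator(np.random.Philox(key=spec.seed))
    t0_sample, _ = simulate_angles(
        AngleSimSpec(
            n=spec.n_tracks,
            p_planar=spec.t0_spec.p_planar,
            planar_sd=spec.t0_spec.planar_sd,
            p_uniform=spec.t0_spec.p_uniform,
            p_perp=spec.t0_spec.p_perp,
            perp_sd=spec.t0_spec.perp_sd,
            seed=spec.seed,
        )
    )
    thr = LIVE_PLANAR_THRESHOLD_DEG
    tracks: list[DivisionTrack] = []
    truth: dict[str, dict[str, bool]] = {}
    for i, t0 in enumerate(t0_sample.angles):
        did = f"div{i}"
        nonplanar = t0 > thr
        if nonplanar:
            resolved = bool(rng.random() < spec.resolution_prob)
            t60 = float(rng.uniform(0.0, thr)) if resolved else float(
                rng.uniform(np.nextafter(thr, 90.0), 90.0)
            )
            reint = bool(rng.random() < spec.reintegration_prob)
            supra = ["suprabasal"] * (spec.track_length + 1)
            if reint:
                for f in range(spec.reintegration_delay, spec.track_length + 1):
                    supra[f] = "basal"
            layers = {
                "a": tuple(["basal"] * (spec.track_length + 1)),
                "b": tuple(supra),
            }
        else:
            resolved = False
            reint = False
            t60 = float(rng.uniform(0.0, thr))
            layers = {
                "a": tuple(["basal"] * (spec.track_length + 1)),
                "b": tuple(["basal"] * (spec.track_length + 1)),
            }
        tracks.append(
            DivisionTrack(
                division_id=did,
                angle_t0=float(t0),
                angle_t60=t60,
                daughter_layers=layers,
                condition=spec.condition,
            )
        )
        truth[did] = {
            "nonplanar": nonplanar,
            "resolved": resolved,
            "reintegrated": reint and nonplanar,
        }
    return tracks, truth
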