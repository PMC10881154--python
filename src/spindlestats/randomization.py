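"""Monte-Carlo randomization statistics for angle distributions.

Two bespoke procedures are implemented here:

* the **randomization score** — the experimental angle sample is compared
  with a large number of uniform null samples drawn on the angle domain
  (default 100,000 samples on [0°, 90°], each of the experimental sample's
  own size) using the two-sample Kolmogorov–Smirnov test; the score at a
  significance level α is the percentage of those null comparisons whose
  p-value exceeds α.  A score near 100% means the sample is statistically
  indistinguishable from uniform ("fully randomized"); a score near 0 means
  the sample is reliably distinguished from uniform at that level.

* the **Gaussian-simulation outlier test** — a reference group's mean and
  SD define a Gaussian; ``k`` values are drawn from it ``n_sim`` times and
  the reported probability is the fraction of simulations in which at least
  one draw exceeds a given frequency threshold.  The closed form
  ``1 − Φ((t − µ)/σ)^k`` is reported alongside the Monte-Carlo estimate.

Standard auxiliary tests (Shapiro–Wilk, Mann–Whitney, Student's t, one-way
ANOVA) are exposed as thin wrappers over scipy so the normality-gated test
choice used elsewhere has a single home.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.stats import distributions

__all__ = [
    "RandomizationConfig",
    "RandomizationResult",
    "OutlierTestResult",
    "ks_two_sample",
    "randomization_score",
    "gaussian_outlier_probability",
    "flag_outlier_animals",
    "shapiro_wilk",
    "mann_whitney",
    "students_t",
    "one_way_anova",
]

KSMode = Literal["asymp", "exact"]


@dataclass(frozen=True)
class RandomizationConfig:
    """Configuration of the randomization-score Monte Carlo.

    ``null_size`` of None means "same size as the experimental sample".
    ``integer_null`` draws integer angles on [lower, upper] instead of
    continuous uniforms (ties then perturb KS p-values; continuous is the
    default because the measured quantity is continuous).
    """

    n_reps: int = 100_000
    alpha_levels: tuple[float, ...] = (0.05, 0.01)
    lower: float = 0.0
    upper: float = 90.0
    null_size: int | None = None
    seed: int = 0
    ks_mode: KSMode = "asymp"
    integer_null: bool = False

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not all(0.0 < a < 1.0 for a in self.alpha_levels):
            raise ValueError("alpha levels must be in (0, 1)")
        if not self.lower < self.upper:
            raise ValueError("lower must be < upper")


@dataclass(frozen=True)
class RandomizationResult:
    """Randomization score with full provenance of the Monte Carlo."""

    score_pct: dict[float, float]
    n_reps: int
    null_size: int
    seed: int
    ks_mode: str
    integer_null: bool
    p_value_quantiles: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class OutlierTestResult:
    """Gaussian-simulation outlier-test outcome."""

    probability: float
    analytic_probability: float
    k_draws: int
    n_sim: int
    threshold: float
    ref_mean: float
    ref_sd: float
    seed: int


def ks_two_sample(
    a: Sequence[float], b: Sequence[float], mode: KSMode | Literal["auto"] = "auto"
) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test.

    Returns (D, p).  ``mode="auto"`` lets scipy pick the exact null
    distribution when both samples are small and tie-free, otherwise the
    asymptotic formula; "exact"/"asymp" force the choice.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_two_sample requires non-empty samples")
    res = stats.ks_2samp(a, b, method=mode)
    return float(res.statistic), float(res.pvalue)


def _ks_d_one_vs_many(sample: np.ndarray, nulls: np.ndarray) -> np.ndarray:
    """Vectorized two-sample KS D between one sample and each row of ``nulls``.

    Pools each row with the sample, walks the pooled order with a signed
    step (+1/m for sample points, −1/n for null points) and takes the max
    |cumulative step| at the end of each tie block — the classic ECDF-gap
    scan, batched.
    """
    m = sample.size
    reps, n = nulls.shape
    vals = np.concatenate([np.broadcast_to(sample, (reps, m)), nulls], axis=1)
    step = np.concatenate([np.full(m, 1.0 / m), np.full(n, -1.0 / n)])
    order = np.argsort(vals, axis=1, kind="stable")
    svals = np.take_along_axis(vals, order, axis=1)
    cs = np.cumsum(step[order], axis=1)
    # ECDF differences are only meaningful after a full block of tied values
    block_end = np.ones_like(svals, dtype=bool)
    block_end[:, :-1] = svals[:, :-1] != svals[:, 1:]
    return np.max(np.abs(cs) * block_end, axis=1)


def _asymp_sf(d: np.ndarray, m: int, n: int) -> np.ndarray:
    # matches scipy.stats.ks_2samp(method="asymp")
    en = m * n / (m + n)
    return distributions.kstwo.sf(d, int(np.round(en)))


def randomization_score(
    sample: "Sequence[float] | object", cfg: RandomizationConfig
) -> RandomizationResult:
    """Randomization score of an angle sample against uniform null samples.

    Draws ``cfg.n_reps`` independent null samples uniform on
    [cfg.lower, cfg.upper] (size = sample size unless overridden), computes
    the two-sample KS p-value of the experimental sample against each, and
    reports, per α level, the percentage of p-values strictly greater than
    α.  Bit-reproducible for a fixed seed: the null stream is a single
    counter-based Philox generator filled row-major, so rep *i* sees the
    same draws whatever ``n_reps`` is.
    """
    angles = np.asarray(getattr(sample, "angles", sample), dtype=float)
    if angles.size == 0:
        raise ValueError("empty sample")
    if np.any(angles < cfg.lower) or np.any(angles > cfg.upper):
        raise ValueError("sample values outside the null domain")
    null_size = cfg.null_size if cfg.null_size is not None else angles.size
    rng = np.random.Generator(np.random.Philox(key=cfg.seed))
    s = np.sort(angles)

    pvals = np.empty(cfg.n_reps)
    batch = 20_000  # bounds the (batch, m+n) work arrays
    done = 0
    while done < cfg.n_reps:
        b = min(batch, cfg.n_reps - done)
        if cfg.integer_null:
            nulls = rng.integers(
                int(cfg.lower), int(cfg.upper), size=(b, null_size), endpoint=True
            ).astype(float)
        else:
            nulls = cfg.lower + (cfg.upper - cfg.lower) * rng.random((b, null_size))
        if cfg.ks_mode == "asymp":
            d = _ks_d_one_vs_many(s, nulls)
            pvals[done : done + b] = _asymp_sf(d, angles.size, null_size)
        else:
            for i in range(b):
                pvals[done + i] = stats.ks_2samp(s, nulls[i], method="exact").pvalue
        done += b

    score = {
        float(a): float(100.0 * np.count_nonzero(pvals > a) / cfg.n_reps)
        for a in cfg.alpha_levels
    }
    qs = np.percentile(pvals, [1, 5, 25, 50, 75, 95, 99])
    quantiles = {
        f"p{q:02d}": float(v) for q, v in zip((1, 5, 25, 50, 75, 95, 99), qs)
    }
    return RandomizationResult(
        score_pct=score,
        n_reps=cfg.n_reps,
        null_size=int(null_size),
        seed=cfg.seed,
        ks_mode=cfg.ks_mode,
        integer_null=cfg.integer_null,
        p_value_quantiles=quantiles,
    )


def gaussian_outlier_probability(
    ref_mean: float,
    ref_sd: float,
    threshold: float,
    k_draws: int = 6,
    n_sim: int = 10_000,
    seed: int = 0,
) -> OutlierTestResult:
    """Probability that at least one of ``k_draws`` Gaussian draws exceeds a threshold.

    Simulates ``n_sim`` rounds of ``k_draws`` values from N(ref_mean,
    ref_sd²) and reports the fraction of rounds with any value strictly
    above ``threshold``, together with the closed form 1 − Φ((t − µ)/σ)^k.
    """
    if ref_sd < 0:
        raise ValueError("ref_sd must be >= 0")
    if n_sim < 1 or k_draws < 1:
        raise ValueError("n_sim and k_draws must be >= 1")
    if ref_sd == 0:
        analytic = 1.0 if ref_mean > threshold else 0.0
        mc = analytic
    else:
        z = (threshold - ref_mean) / ref_sd
        analytic = float(1.0 - stats.norm.cdf(z) ** k_draws)
        rng = np.random.Generator(np.random.Philox(key=seed))
        draws = rng.normal(ref_mean, ref_sd, size=(n_sim, k_draws))
        mc = float(np.mean(np.any(draws > threshold, axis=1)))
    return OutlierTestResult(
        probability=mc,
        analytic_probability=analytic,
        k_draws=k_draws,
        n_sim=n_sim,
        threshold=threshold,
        ref_mean=float(ref_mean),
        ref_sd=float(ref_sd),
        seed=seed,
    )


def flag_outlier_animals(
    frequencies: Sequence[float],
    reference: Sequence[float],
    threshold: float,
    n_sim: int = 10_000,
    seed: int = 0,
) -> tuple[list[bool], OutlierTestResult]:
    """Flag tested animals above a frequency threshold, with an outlier probability.

    The reference genotype's per-animal frequencies define the Gaussian
    (sample mean and SD, ddof=1); the outlier probability uses k equal to
    the number of tested animals.  Raises when the reference has fewer than
    two animals (its SD is then undefined).
    """
    ref = np.asarray(reference, dtype=float)
    freq = np.asarray(frequencies, dtype=float)
    if ref.size < 2:
        raise ValueError("reference group needs >= 2 animals to define an SD")
    result = gaussian_outlier_probability(
        ref_mean=float(np.mean(ref)),
        ref_sd=float(np.std(ref, ddof=1)),
        threshold=threshold,
        k_draws=freq.size,
        n_sim=n_sim,
        seed=seed,
    )
    return [bool(f > threshold) for f in freq], result


# -- thin wrappers over established routines ---------------------------------

def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    r = stats.shapiro(np.asarray(x, dtype=float))
    return float(r.statistic), float(r.pvalue)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    r = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(r.statistic), float(r.pvalue)


def students_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    r = stats.ttest_ind(a, b)
    return float(r.statistic), float(r.pvalue)


def one_way_anova(*groups: Sequence[float]) -> tuple[float, float]:
    r = stats.f_oneway(*groups)
    return float(r.statistic), float(r.pvalue)
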