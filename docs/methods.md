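# Methods

## Angle measurement and binning

Annotations arrive as calibrated 2-D coordinates in µm (y increasing
apically); no pixel units appear anywhere. A division's angle is the acute
angle between the spindle pole-to-pole axis and a basal reference
direction, folded into [0°, 90°]; it is invariant to pole order, reference
sign, and rigid motions of the whole annotation. The reference is either
supplied explicitly per division or derived from a traced basement-membrane
polyline as the direction of the segment nearest (perpendicular distance)
to the midpoint of the pole axis. Both options exist because sectioned
tissue curves: a local tangent is the faithful reading of "measured against
the basal layer", while a global per-field direction is supported for flat
fields. Ties between equidistant segments break toward the earlier segment
so the result is deterministic.

Fixed-tissue bins are parallel θ ≤ 30°, oblique 30° < θ < 60°,
perpendicular θ ≥ 60° — closed on the parallel and perpendicular sides.
Bin percentages are computed unrounded (rounding only at report
rendering); medians and quartiles use numpy's linear-interpolation
convention, which differs from median-unbiased alternatives by well under
1° at n ≈ 45.

Live-imaging classification uses a stricter planar criterion of 20°, the
threshold under which nearly all wild-type live divisions fall; it is a
parameter (`planar_threshold`) rather than a constant because "resolution"
of an oblique division has no canonical numeric criterion. A non-planar
division (t0 > threshold) is *resolved* if its +60 min angle is at or
below threshold, *persistent* if not, *censored* if the division was lost.
A suprabasal daughter is *reintegrated* if its layer label becomes basal
within the window (default 6 h at 5-min frames) and stays basal to the end
of the track; tracks outlasting the window without a transition are
*retained*, shorter ones *censored*.

## Randomization score

The experimental sample (size m) is compared with `n_reps` (default
100,000) independent null samples, each of size `null_size` (default: m
itself, with an override for a fixed common size) drawn uniformly on
[0°, 90°]. For each comparison the two-sample KS p-value is computed; the
score at level α is the percentage of p-values **strictly** greater than α
(ties at exactly α count as not larger). Scores are reported at
α = 0.05 and α = 0.01; since {p > 0.05} ⊆ {p > 0.01}, the α = 0.01 score
is always ≥ the α = 0.05 score.

Numerical choices:

- **Null draws are continuous.** Integer-valued nulls create ties that
  perturb KS p-values; an `integer_null` flag exists for sensitivity
  checks but the measured quantity is continuous.
- **KS p-value mode is explicit and recorded.** The default is the
  asymptotic two-sample formula (`kstwo.sf(D, round(mn/(m+n)))`, matching
  `scipy.stats.ks_2samp(method="asymp")`), computed over a vectorized
  ECDF-gap scan so a full 100,000-repetition run takes seconds. An exact
  mode loops `scipy.stats.ks_2samp(method="exact")`. Scores under the two
  modes can differ by a few percentage points at n ≈ 45, so every result
  records its mode and tests pin it.
- **Reproducibility.** Null draws come from a single counter-based Philox
  stream filled row-major over (n_reps × null_size), so repetition *i*
  sees the same draws regardless of n_reps: growing the repetition count
  extends the Monte Carlo rather than reshuffling it, and a fixed seed is
  bit-reproducible.

An independently written straight-loop implementation (legacy generator,
per-repetition scipy calls) was used as the Monte-Carlo oracle for the
mean score of size-45 uniform samples; its frozen mean/SD anchor the
discrimination test.

## Gaussian-simulation outlier test

The reference group's per-animal frequencies give a sample mean and SD
(ddof = 1); k values (k = number of tested animals, default 6) are drawn
from that Gaussian n_sim = 10,000 times, and the probability reported is
the fraction of rounds in which at least one draw strictly exceeds the
threshold. The closed form 1 − Φ((t − µ)/σ)^k is reported alongside and
the Monte-Carlo estimate agrees with it to within four binomial standard
errors. The threshold is a **mandatory explicit parameter**: published
descriptions of this test state two values differing tenfold (0.0007
vs 0.007 events/µm), so no default is hard-coded. σ = 0 degenerates to an
indicator (probability 1 if µ > t, else 0).

## Morphometry

Densities are counts per µm of basement-membrane arc length; folding is
arc length over straight-line span (flat = 1); marker fractions are
percentages of a layer total; rare events are counts per µm. The unit of
replication is the animal: per-animal values pool counts and lengths
across sections *before* dividing (a weighted pooling — never the mean of
per-section ratios), and condition-level values are means of per-animal
values. Whether published per-condition bars are animal means or
pooled-cell proportions is ambiguous; animal means were chosen and are
recorded in the output metadata. "Proliferative spinous cell" is
operationalized as Ki67+ KRT10+ KRT5−.

## Tumor cohorts

Burden is the per-mouse summed volume; the cohort mean includes tumor-free
mice as zeros (an option restricts to tumor-bearing mice, and the choice is
recorded in the summary). The zero-inclusive reading is the only one under
which a low-incidence cohort can have a sub-mm³ mean burden. Two-group
comparisons gate on Shapiro–Wilk at 0.05 in each sample: both normal →
unpaired two-tailed Student's t; otherwise two-tailed Mann–Whitney; samples
of fewer than 3 cannot be gated and fall through to the rank test. Volume
measurement itself is out of scope — volumes are inputs.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not
tissue mechanics or images:

- **Angles**: mixtures of a planar half-normal |N(0, σ_planar)|, a uniform
  U(0, 90), and an optional perpendicular 90 − |N(0, σ_perp)|, folded into
  [0, 90]. Half-normal components give closed-form bin probabilities
  (e.g. 2Φ(30/σ) − 1 for the parallel bin). A scenario helper draws exact
  bin counts uniformly within bins, so a four-condition pack can reproduce
  published bin percentages (80/13/7, 53/20/27, 65/20/14, 34/38/27) at the
  published sizes (45, 45, 49, 44); printed percentages may sum to 99
  after integer rounding and are renormalized. Downstream, this pack
  yields the expected score ordering: the wild-type-like condition lowest,
  the double-knockout-like condition highest (≈ 99% at α = 0.01).
- **Tissue**: the membrane is a five-wave sinusoid whose amplitude is
  solved (Brent root-finding on numerically integrated arc length) so that
  arc length / span equals the folding target to < 1%. Cell totals are
  Poisson at density × arc length, markers binomial at stated fractions,
  rare events Poisson at rate × arc length. Defaults match homeostatic
  magnitudes (basal 0.16, spinous 0.19 cells/µm; KRT10+ basal 46%).
- **Cohorts**: per mouse, affected ~ Bernoulli(incidence); if affected,
  count ~ zero-truncated Poisson (mean λ/(1 − e^{−λ})); volumes iid
  log-normal. Moments are closed-form oracles for the burden estimators.
- **Tracks**: t0 angles from an angle mixture; non-planar tracks resolve
  by +60 min with a set probability; the suprabasal daughter reintegrates
  after a set delay with a set probability. Ground-truth flags accompany
  every track.

What passing on synthetic data does *not* show: robustness to annotation
noise in pole placement, curvature mis-tracing, observer variation in
layer calls, or spatial correlation between neighbouring cells — none of
which the generators model.

## Problem sizes and runtime choices

The discrimination suite uses 50 seeds × 10,000 repetitions (the full
100,000-repetition configuration is exercised by the acceptance script and
completes in seconds per condition via the vectorized KS path). Parameter
recovery uses n = 1000 angle samples (3-percentage-point band), ≥ 300
generated cells per animal for morphometry (the 5%-relative-error check is
run at a generated size large enough that the band is ≥ 4 Poisson SEs),
and 10,000 tracks (3-SE band).

## Known limitations

- 2-D only: no correction for section obliquity; angles are taken in the
  section or reslice plane as annotated.
- The asymptotic KS p-value is conservative at n ≈ 45, which nudges
  scores upward relative to the exact mode; both modes are available and
  recorded, neither is claimed to reproduce unpublished raw-data scores.
- The reintegration classifier requires contiguous per-frame layer labels;
  gaps must be resolved upstream.
- Condition-level morphometry assumes animals are exchangeable within a
  condition; per-mouse random effects are available in the generator but
  off by default.
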