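"""Synthetic-data generators: determinism, closed-form oracles, recovery."""

import numpy as np
import pytest
from scipy import stats

from spindlestats.angle_geometry import (
    bin_angle,
    classify_reintegration,
    polyline_arc_length,
    t0_t60_resolution,
)
from spindlestats.morphometry import summarize_animals, tissue_folding
from spindlestats.synth import (
    AngleSimSpec,
    CohortSimSpec,
    TissueSimSpec,
    TrackSimSpec,
    binned_angle_sample,
    simulate_angles,
    simulate_cohort,
    simulate_tissue,
    simulate_tracks,
)


class TestSimulateAngles:
    def test_uniform_component_equal_bins(self):
        sample, _ = simulate_angles(AngleSimSpec(n=100_000, p_planar=0, p_uniform=1, seed=1))
        classes = np.array([bin_angle(a) for a in sample.angles])
        for cls in ("parallel", "oblique", "perpendicular"):
            assert np.mean(classes == cls) == pytest.approx(1 / 3, abs=0.01)

    def test_planar_component_half_normal_cdf(self):
        """Pure planar σ=10°: parallel fraction is 2Φ(3) − 1 ≈ 0.9973."""
        sample, _ = simulate_angles(
            AngleSimSpec(n=100_000, p_planar=1.0, p_uniform=0.0, planar_sd=10, seed=2)
        )
        frac = np.mean([a <= 30 for a in sample.angles])
        assert frac == pytest.approx(2 * stats.norm.cdf(3) - 1, abs=0.01)

    def test_mixture_arithmetic(self):
        spec = AngleSimSpec(n=100_000, p_planar=0.8, p_uniform=0.2, planar_sd=10, seed=3)
        sample, labels = simulate_angles(spec)
        expect = 0.8 * (2 * stats.norm.cdf(3) - 1) + 0.2 / 3
        frac = np.mean([a <= 30 for a in sample.angles])
        assert frac == pytest.approx(expect, abs=0.01)
        assert set(labels) == {"planar", "uniform"}

    def test_deterministic_under_seed(self):
        spec = AngleSimSpec(n=50, p_planar=0.5, p_uniform=0.5, seed=9)
        s1, l1 = simulate_angles(spec)
        s2, l2 = simulate_angles(spec)
        assert s1.angles == s2.angles
        assert (l1 == l2).all()

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            AngleSimSpec(n=10, p_planar=0.5, p_uniform=0.2)

    def test_mixture_bin_recovery_within_3_points(self):
        """Known mixture weights recovered from bin fractions at n = 1000."""
        spec = AngleSimSpec(n=1000, p_planar=0.6, p_uniform=0.3, p_perp=0.1,
                            planar_sd=8, perp_sd=8, seed=4)
        sample, _ = simulate_angles(spec)
        classes = np.array([bin_angle(a) for a in sample.angles])
        phi = 2 * stats.norm.cdf(30 / 8) - 1  # component mass inside its own bin
        expect_parallel = 0.6 * phi + 0.3 / 3
        expect_perp = 0.1 * phi + 0.3 / 3
        assert 100 * np.mean(classes == "parallel") == pytest.approx(
            100 * expect_parallel, abs=3.0)
        assert 100 * np.mean(classes == "perpendicular") == pytest.approx(
            100 * expect_perp, abs=3.0)


class TestBinnedSample:
    def test_exact_bin_counts_at_printed_percentages(self):
        sample = binned_angle_sample(80, 13, 7, n=45, seed=5)
        classes = [bin_angle(a) for a in sample.angles]
        assert classes.count("parallel") == 36
        assert classes.count("oblique") == 6
        assert classes.count("perpendicular") == 3

    def test_total_preserved_when_percentages_sum_to_99(self):
        sample = binned_angle_sample(34, 38, 27, n=44, seed=6)
        assert sample.n == 44


class TestSimulateTissue:
    def test_flat_trace_when_folding_one(self):
        sections, trace = simulate_tissue(TissueSimSpec(folding_target=1.0, seed=7))
        assert polyline_arc_length(trace.points) == pytest.approx(2000.0)

    def test_folding_target_recovered_from_trace(self):
        _, trace = simulate_tissue(TissueSimSpec(folding_target=1.3, seed=7))
        bm = polyline_arc_length(trace.points)
        assert tissue_folding(bm, 2000.0) == pytest.approx(1.3, abs=0.01)

    def test_poisson_count_rate(self):
        spec = TissueSimSpec(folding_target=1.0, basal_density=0.16,
                             span_um=2000.0, n_sections=50, n_mice=4, seed=8)
        sections, _ = simulate_tissue(spec)
        totals = np.array([s.counts[("basal", "total")] for s in sections])
        lam = 0.16 * 2000
        se = np.sqrt(lam / len(totals))
        assert abs(totals.mean() - lam) <= 4 * se

    def test_unattainable_folding_rejected(self):
        with pytest.raises(ValueError):
            TissueSimSpec(folding_target=0.9)

    def test_mouse_random_effect_shared_within_mouse(self):
        """With a strong per-mouse rate effect, sections of one mouse stay
        correlated: between-mouse spread of pooled density exceeds the
        homogeneous case."""
        base = dict(folding_target=1.0, basal_density=0.2, span_um=2000.0,
                    n_sections=6, n_mice=8, seed=40)
        homo, _ = simulate_tissue(TissueSimSpec(**base))
        hetero, _ = simulate_tissue(TissueSimSpec(**base, mouse_rate_sd=0.3))

        def mouse_means(sections):
            means = {}
            for s in sections:
                means.setdefault(s.mouse_id, []).append(s.counts[("basal", "total")])
            return np.array([np.mean(v) for v in means.values()])

        assert mouse_means(hetero).std() > 3 * mouse_means(homo).std()

    def test_parameter_recovery_through_morphometry(self):
        """Density, folding and marker fractions recovered within 5% relative
        error at ≥ 300 cells per animal."""
        spec = TissueSimSpec(span_um=2000.0, folding_target=1.25,
                             basal_density=0.2, spinous_density=0.3,
                             marker_fractions={"basal": {"KRT10+": 0.46}},
                             n_sections=4, n_mice=3, seed=10)
        sections, _ = simulate_tissue(spec)
        animals = summarize_animals(sections)
        for summ in animals.values():
            assert summ.basal_density == pytest.approx(0.2, rel=0.05)
            assert summ.spinous_density == pytest.approx(0.3, rel=0.05)
            assert summ.folding == pytest.approx(1.25, rel=0.01)
            assert summ.krt10_basal_fraction == pytest.approx(46.0, rel=0.05)


class TestSimulateCohort:
    def test_zero_incidence(self):
        records = simulate_cohort(CohortSimSpec(n_mice=50, incidence_prob=0.0, seed=11))
        assert all(len(r.volumes) == 0 for r in records)

    def test_zero_truncated_poisson_mean(self):
        spec = CohortSimSpec(n_mice=5000, incidence_prob=1.0, count_mean=2.0, seed=12)
        records = simulate_cohort(spec)
        counts = np.array([len(r.volumes) for r in records])
        assert counts.min() >= 1
        expect = 2.0 / (1 - np.exp(-2.0))
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expect) <= 3 * se


class TestSimulateTracks:
    def test_zero_resolution_prob_all_persistent(self):
        tracks, truth = simulate_tracks(
            TrackSimSpec(n_tracks=300, resolution_prob=0.0, seed=14)
        )
        for t in tracks:
            if truth[t.division_id]["nonplanar"]:
                assert t0_t60_resolution(t) == "persistent"

    def test_all_planar_spec_yields_no_reintegration_candidates(self):
        spec = TrackSimSpec(
            n_tracks=100,
            t0_spec=AngleSimSpec(n=1, p_planar=1.0, p_uniform=0.0, planar_sd=3),
            seed=15,
        )
        tracks, truth = simulate_tracks(spec)
        eligible = [
            t for t in tracks
            if any(v and v[0] == "suprabasal" for v in t.daughter_layers.values())
        ]
        # σ=3° planar component leaves essentially no angles above 20°
        assert len(eligible) == sum(truth[t.division_id]["nonplanar"] for t in tracks)

    def test_resolution_and_reintegration_probabilities_recovered(self):
        """Classifier recovers the programmed probabilities within 3 SE
        on 10,000 simulated tracks."""
        spec = TrackSimSpec(
            n_tracks=10_000,
            t0_spec=AngleSimSpec(n=1, p_planar=0.3, p_uniform=0.7),
            resolution_prob=0.25, reintegration_prob=0.4, seed=16,
        )
        tracks, truth = simulate_tracks(spec)
        nonplanar = [t for t in tracks if truth[t.division_id]["nonplanar"]]
        res = np.array([t0_t60_resolution(t) == "resolved" for t in nonplanar])
        se = np.sqrt(0.25 * 0.75 / res.size)
        assert abs(res.mean() - 0.25) <= 3 * se
        reint = np.array(
            [classify_reintegration(t) == "reintegrated" for t in nonplanar]
        )
        se = np.sqrt(0.4 * 0.6 / reint.size)
        assert abs(reint.mean() - 0.4) <= 3 * se
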