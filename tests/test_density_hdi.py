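"""HDI extraction, bandwidth/consensus rules, and the bounded-support KDE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pertpool import (
    HdiInterval,
    ThreePointElicitation,
    classify_consensus,
    count_modes,
    estimate_kde,
    fit_pert,
    hdi_bandwidth,
    hdi_from_density,
    hdi_from_samples,
    pool_opinions,
    sample_pert,
)


def brute_force_hdi(samples, mass):
    """O(m^2) oracle: enumerate every ceil(mass*m)-length sorted window."""
    import math

    x = np.sort(np.asarray(samples, float))
    m = x.size
    w = math.ceil(mass * m)
    best = None
    for i in range(m - w + 1):
        width = x[i + w - 1] - x[i]
        if best is None or width < best[0]:
            best = (width, x[i], x[i + w - 1])
    return best[1], best[2]


class TestHdiFromSamples:
    def test_point_cluster_dominates(self):
        samples = [50.0] * 30 + [0.0]
        h = hdi_from_samples(samples, mass=0.8)
        assert (h.lower, h.upper) == (50.0, 50.0)
        assert hdi_bandwidth(h) == 0.0

    def test_equally_spaced_ties_break_leftmost(self):
        h = hdi_from_samples(np.arange(101.0), mass=0.8)
        assert (h.lower, h.upper) == (0.0, 80.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            hdi_from_samples([1.0] * 9)

    @settings(deadline=None, derandomize=True, max_examples=80)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=10, max_size=200),
        st.sampled_from([0.5, 0.8, 0.9]),
    )
    def test_matches_brute_force_oracle(self, samples, mass):
        h = hdi_from_samples(samples, mass=mass)
        assert (h.lower, h.upper) == brute_force_hdi(samples, mass)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=20, max_size=200))
    def test_coverage_and_median_containment(self, samples):
        import math

        h = hdi_from_samples(samples, mass=0.8)
        x = np.asarray(samples)
        covered = np.sum((x >= h.lower) & (x <= h.upper))
        assert covered >= math.ceil(0.8 * x.size)
        assert float(np.median(x)) in h

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=10, max_size=150))
    def test_bandwidth_nondecreasing_in_mass(self, samples):
        h8 = hdi_from_samples(samples, mass=0.8)
        h9 = hdi_from_samples(samples, mass=0.9)
        assert h9.bandwidth >= h8.bandwidth


class TestBandwidthAndConsensus:
    @pytest.mark.parametrize(
        "lower, upper, expected",
        [(69.7, 99.8, 30.1), (61.2, 99.8, 38.6), (15.5, 99.0, 83.5), (42.0, 42.0, 0.0)],
    )
    def test_bandwidth_is_upper_minus_lower(self, lower, upper, expected):
        h = HdiInterval(lower, upper)
        assert hdi_bandwidth(h) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "bandwidth, label",
        [(42.3, "strong"), (45.1, "strong"), (50.0, "strong"), (50.0001, "weak"), (83.5, "weak")],
    )
    def test_threshold_at_50_is_inclusive(self, bandwidth, label):
        assert classify_consensus(bandwidth) == label

    def test_negative_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            classify_consensus(-1.0)


class TestKde:
    def test_uniform_samples_give_flat_density(self):
        rng = np.random.default_rng(0)
        curve = estimate_kde(rng.uniform(0, 100, 100_000))
        interior = (curve.grid > 5) & (curve.grid < 95)
        np.testing.assert_allclose(curve.density[interior], 0.01, rtol=0.10)
        assert curve.integral() == pytest.approx(1.0, abs=1e-3)

    def test_mass_conserved_despite_boundary_reflection(self):
        # mass piled against the 0 boundary must reflect, not leak
        d = fit_pert(ThreePointElicitation(0, 2, 15))
        curve = estimate_kde(sample_pert(d, 50_000, seed=3))
        assert curve.integral() == pytest.approx(1.0, abs=1e-3)
        assert (curve.density >= 0).all()

    def test_single_pert_pool_recovers_the_mode(self):
        d = fit_pert(ThreePointElicitation(30, 50, 70))
        # fixed smoothing wide enough to average out Monte-Carlo jitter at the peak
        curve = estimate_kde(sample_pert(d, 50_000, seed=5), kde_bandwidth=3.0)
        step = curve.grid[1] - curve.grid[0]
        argmax = curve.grid[np.argmax(curve.density)]
        assert abs(argmax - 50.0) <= 2 * step

    def test_two_expert_clusters_give_two_modes(self):
        panel = [
            ThreePointElicitation(10, 20, 30),
            ThreePointElicitation(15, 22, 35),
            ThreePointElicitation(65, 75, 85),
            ThreePointElicitation(70, 80, 95),
        ]
        p = pool_opinions(panel, samples_per_expert=10_000, seed=6)
        assert count_modes(estimate_kde(p.samples)) == 2

    def test_identical_samples_rejected(self):
        with pytest.raises(ValueError, match="point mass"):
            estimate_kde([42.0] * 100)


class TestDensityThresholdDiagnostic:
    def test_bimodal_pool_yields_two_intervals(self):
        panel = [ThreePointElicitation(5, 15, 25), ThreePointElicitation(70, 85, 95)]
        p = pool_opinions(panel, samples_per_expert=20_000, seed=8)
        curve = estimate_kde(p.samples)
        intervals = hdi_from_density(curve.grid, curve.density, mass=0.8)
        assert len(intervals) == 2
        # the union must carry at least the target mass
        total = sum(
            np.trapezoid(
                curve.density[(curve.grid >= lo) & (curve.grid <= hi)],
                curve.grid[(curve.grid >= lo) & (curve.grid <= hi)],
            )
            for lo, hi in intervals
        )
        assert total >= 0.8 - 0.01
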