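"""PERT fitting: closed-form shapes/moments, unit mass, sampling contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from pertpool import (
    ElicitationError,
    ThreePointElicitation,
    fit_pert,
    pert_cdf,
    pert_mean,
    pert_pdf,
    sample_pert,
)


def valid_triplets(min_width=0.0):
    """Strategy for (low, mode, high) with low <= mode <= high in [0, 100]."""
    return (
        st.tuples(
            st.floats(0, 100, allow_nan=False),
            st.floats(0, 100, allow_nan=False),
            st.floats(0, 100, allow_nan=False),
        )
        .map(sorted)
        .filter(lambda t: t[2] - t[0] >= min_width)
    )


class TestValidation:
    @pytest.mark.parametrize(
        "low, mode, high, field",
        [
            (60, 50, 80, "low"),  # low > mode
            (40, 90, 80, "mode"),  # mode > high
            (-1, 50, 80, "low"),  # off-scale
            (40, 50, 101, "high"),
        ],
    )
    def test_invalid_triplets_rejected_naming_the_field(self, low, mode, high, field):
        with pytest.raises(ElicitationError, match=field):
            ThreePointElicitation(low, mode, high)

    def test_nan_rejected(self):
        with pytest.raises(ElicitationError):
            ThreePointElicitation(40, float("nan"), 80)

    def test_negative_shape_lambda_rejected(self, worked_example):
        with pytest.raises(ElicitationError):
            fit_pert(worked_example, shape_lambda=-1)


class TestFit:
    def test_worked_example_shapes_and_mean(self, worked_example):
        """(40, 50, 80): alpha = 1 + 4*10/40 = 2, beta = 1 + 4*30/40 = 4."""
        d = fit_pert(worked_example)
        assert d.alpha == pytest.approx(2.0)
        assert d.beta_ == pytest.approx(4.0)
        assert pert_mean(d) == pytest.approx((40 + 4 * 50 + 80) / 6)
        # mean cross-checked by numerical integration of x * pdf(x)
        num_mean, _ = quad(lambda x: x * pert_pdf(d, x), 40, 80)
        assert num_mean == pytest.approx(pert_mean(d), abs=1e-8)

    def test_symmetric_triplet_gives_equal_shapes(self):
        d = fit_pert(ThreePointElicitation(0, 50, 100))
        assert d.alpha == pytest.approx(3.0)
        assert d.beta_ == pytest.approx(3.0)
        assert pert_mean(d) == pytest.approx(50.0)
        assert pert_cdf(d, 50) == pytest.approx(0.5)

    def test_point_elicitation_is_degenerate(self):
        d = fit_pert(ThreePointElicitation(30, 30, 30))
        assert d.degenerate
        assert pert_mean(d) == 30.0
        assert pert_cdf(d, 29.999) == 0.0
        assert pert_cdf(d, 30) == 1.0
        with pytest.raises(ElicitationError):
            pert_pdf(d, 30)

    @pytest.mark.parametrize(
        "triplet, which",
        [((20, 20, 60), "alpha"), ((20, 60, 60), "beta_")],
    )
    def test_edge_mode_gives_unit_shape(self, triplet, which):
        """mode == low forces alpha = 1 exactly; mode == high forces beta = 1."""
        d = fit_pert(ThreePointElicitation(*triplet))
        assert getattr(d, which) == 1.0


class TestDensity:
    def test_pdf_zero_outside_support_and_mode_is_argmax(self, worked_example):
        d = fit_pert(worked_example)
        assert pert_pdf(d, 30) == 0.0
        assert pert_pdf(d, 90) == 0.0
        grid = np.linspace(40, 80, 4001)
        assert grid[np.argmax(pert_pdf(d, grid))] == pytest.approx(50, abs=0.02)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(valid_triplets(min_width=1.0))
    def test_unit_mass_property(self, triplet):
        d = fit_pert(ThreePointElicitation(*triplet))
        mass, _ = quad(lambda x: pert_pdf(d, x), d.low, d.high, limit=200)
        assert mass == pytest.approx(1.0, abs=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(valid_triplets(min_width=5.0), st.floats(-10, 10))
    def test_location_equivariance(self, triplet, c):
        low, mode, high = triplet
        if not (0 <= low + c and high + c <= 100):
            c = 0.0
        d0 = fit_pert(ThreePointElicitation(low, mode, high))
        d1 = fit_pert(ThreePointElicitation(low + c, mode + c, high + c))
        assert pert_mean(d1) == pytest.approx(pert_mean(d0) + c, abs=1e-9)
        x = (low + high) / 2
        assert pert_cdf(d1, x + c) == pytest.approx(pert_cdf(d0, x), abs=1e-12)
        s0 = sample_pert(d0, 100, seed=5)
        s1 = sample_pert(d1, 100, seed=5)
        np.testing.assert_allclose(s1, s0 + c, atol=1e-9)


class TestSampling:
    def test_degenerate_sampling_repeats_the_point(self):
        d = fit_pert(ThreePointElicitation(30, 30, 30))
        np.testing.assert_array_equal(sample_pert(d, 5, seed=0), [30] * 5)

    def test_seed_determinism_and_support(self, worked_example):
        d = fit_pert(worked_example)
        a = sample_pert(d, 1000, seed=42)
        b = sample_pert(d, 1000, seed=42)
        np.testing.assert_array_equal(a, b)
        assert a.min() >= 40 and a.max() <= 80

    def test_sample_mean_matches_closed_form(self, worked_example):
        d = fit_pert(worked_example)
        s = sample_pert(d, 50_000, seed=7)
        tol = 3 * s.std(ddof=1) / np.sqrt(s.size)
        assert abs(s.mean() - 53.333333) < tol

    def test_nonpositive_n_rejected(self, worked_example):
        with pytest.raises(ElicitationError):
            sample_pert(fit_pert(worked_example), 0, seed=1)

    @pytest.mark.parametrize("triplet", [(40, 50, 80), (0, 5, 95), (10, 70, 75)])
    def test_cdf_matches_empirical_within_dkw(self, triplet):
        """Empirical CDF of 50k draws within the 99.9% DKW band of pert_cdf."""
        n = 50_000
        d = fit_pert(ThreePointElicitation(*triplet))
        s = np.sort(sample_pert(d, n, seed=11))
        eps = np.sqrt(np.log(2 / 0.001) / (2 * n))
        ecdf = np.arange(1, n + 1) / n
        assert np.max(np.abs(ecdf - pert_cdf(d, s))) < eps
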