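"""ABC machinery: priors, kernels, weights, acceptance, full samplers.

The sampler-level tests use cheap synthetic distance functions so the
algorithmic properties (population constraint satisfaction, weight
normalization, prior recovery, determinism) are separated from the Psp
simulators, which have their own tests.
"""

import math

import numpy as np
import pytest
from scipy import stats

from pspabc.smc import (
    AcceptanceFloorError,
    Particle,
    Population,
    Prior,
    ToleranceSchedule,
    abc_rejection,
    abc_smc,
    accept,
    default_prior,
    default_tolerances,
    kernel_density,
    kernel_scales,
    particle_weight,
    perturb,
    sample_prior,
)


def make_population(thetas, weights=None):
    thetas = np.atleast_2d(thetas)
    n = len(thetas)
    weights = np.full(n, 1.0 / n) if weights is None else np.asarray(weights)
    particles = tuple(
        Particle(np.asarray(th, dtype=float), w, np.zeros(5))
        for th, w in zip(thetas, weights)
    )
    return Population(particles, 1, np.full(5, np.inf), n)


class TestPrior:
    def test_draws_stay_in_bounds_with_uniform_mean(self):
        prior = default_prior()
        rng = np.random.default_rng(0)
        draws = np.array([sample_prior(prior, rng) for _ in range(100_000)])
        assert np.all(draws >= prior.lower) and np.all(draws <= prior.upper)
        k2 = draws[:, 1]
        se = k2.std(ddof=1) / math.sqrt(len(k2))
        assert abs(k2.mean() - 50.0) <= 3 * se

    def test_narrow_prior_concentrates(self):
        prior = Prior(np.full(10, 0.5), np.full(10, 0.5 + 1e-12))
        rng = np.random.default_rng(1)
        np.testing.assert_allclose(sample_prior(prior, rng), 0.5, rtol=1e-9)

    def test_density_inside_and_outside(self):
        prior = Prior([0.0, 0.0], [2.0, 5.0])
        assert prior.density(np.array([1.0, 1.0])) == pytest.approx(0.1)
        assert prior.density(np.array([3.0, 1.0])) == 0.0

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            Prior([0.0], [0.0])
        with pytest.raises(ValueError):
            Prior([-1.0], [1.0])


class TestToleranceSchedule:
    def test_default_schedule_shape_and_monotonicity(self):
        tol = default_tolerances()
        assert tol.epsilons.shape == (8, 5)
        assert np.all(np.diff(tol.epsilons, axis=0) <= 0)

    def test_increasing_rows_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            ToleranceSchedule([[1.0] * 5, [2.0] * 5])

    def test_wrong_width_rejected(self):
        with pytest.raises(ValueError, match="5 components"):
            ToleranceSchedule([[1.0, 2.0]])


class TestKernelScales:
    def test_half_range_rule(self):
        thetas = np.zeros((3, 10))
        thetas[:, 2] = [0.2, 0.4, 0.6]
        sigma = kernel_scales(make_population(thetas), default_prior())
        assert sigma[2] == pytest.approx(0.2)

    def test_single_particle_floored(self):
        prior = default_prior()
        sigma = kernel_scales(make_population(np.full((1, 10), 0.3)), prior)
        np.testing.assert_allclose(sigma, 1e-6 * prior.width)

    def test_scales_shrink_with_nested_ranges(self):
        wide = make_population(np.linspace(0, 1, 5)[:, None] * np.ones(10))
        narrow = make_population((0.4 + 0.2 * np.linspace(0, 1, 5))[:, None] * np.ones(10))
        prior = default_prior()
        assert np.all(kernel_scales(narrow, prior) <= kernel_scales(wide, prior))


class TestPerturb:
    def test_zero_scale_is_identity(self):
        theta = np.linspace(0, 1, 10)
        out = perturb(theta, np.zeros(10), np.random.default_rng(0))
        np.testing.assert_array_equal(out, theta)

    def test_step_distribution_is_uniform(self):
        rng = np.random.default_rng(2)
        sigma = np.array([0.3])
        steps = np.array(
            [perturb(np.array([1.0]), sigma, rng)[0] - 1.0 for _ in range(100_000)]
        )
        assert stats.kstest(steps, stats.uniform(loc=-0.3, scale=0.6).cdf).pvalue > 0.01

    def test_box_density(self):
        sigma = np.array([0.5, 1.0])
        center = np.zeros(2)
        assert kernel_density(np.array([0.4, -0.9]), center, sigma) == pytest.approx(0.5)
        assert kernel_density(np.array([0.6, 0.0]), center, sigma) == 0.0


class TestParticleWeight:
    def test_first_population_unit_weight(self):
        assert particle_weight(np.zeros(10), None, None, default_prior()) == 1.0

    def test_single_parent_closed_form(self):
        prior = Prior(np.zeros(2), np.ones(2))
        prev = Population(
            (Particle(np.array([0.5, 0.5]), 1.0, np.zeros(5)),), 1, np.ones(5), 1
        )
        sigma = np.array([0.1, 0.2])
        theta = np.array([0.55, 0.45])
        w = particle_weight(theta, prev, sigma, prior)
        assert w == pytest.approx(1.0 / (1.0 / (0.2 * 0.4)))

    def test_orphan_proposal_rejected(self):
        prior = Prior(np.zeros(2), np.ones(2))
        prev = Population(
            (Particle(np.array([0.5, 0.5]), 1.0, np.zeros(5)),), 1, np.ones(5), 1
        )
        with pytest.raises(ValueError, match="support"):
            particle_weight(np.array([0.9, 0.9]), prev, np.array([0.1, 0.1]), prior)


class TestAccept:
    def test_boundary_is_accepted(self):
        eps = np.array([10, 3.0, 20.0, 20.0, 0.7])
        assert accept(eps.copy(), eps)

    def test_any_component_above_rejects(self):
        eps = np.array([10, 3.0, 20.0, 20.0, 0.7])
        d = eps.copy()
        d[3] += 1e-9
        assert not accept(d, eps)

    def test_zero_distance_accepted(self):
        assert accept(np.zeros(5), np.full(5, 1e-12) + 1e-13)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            accept(np.zeros(4), np.zeros(5))


def quadratic_distance(theta, rng):
    """Cheap deterministic surrogate: distance grows with the gap to a
    known optimum, mapped onto all five components."""
    target = default_prior().upper * 0.3
    gap = float(np.linalg.norm((theta - target) / default_prior().width))
    return np.array([100 * gap, 13 * gap, 100 * gap, 100 * gap, 1.5 * gap])


class TestSamplers:
    def test_populations_satisfy_their_tolerances(self):
        tol = ToleranceSchedule(
            np.array([[60.0, 8.0, 60.0, 60.0, 0.9], [30.0, 4.0, 30.0, 30.0, 0.45]])
        )
        pops = abc_smc(quadratic_distance, default_prior(), tol, n_particles=50, seed=3)
        assert len(pops) == 2
        for pop, eps in zip(pops, tol.epsilons):
            assert len(pop.particles) == 50
            assert np.all(pop.distances <= eps)
            assert pop.weights.sum() == pytest.approx(1.0)
            assert np.all(pop.weights >= 0)

    def test_same_seed_reproduces_exactly(self):
        tol = ToleranceSchedule(np.array([[60.0, 8.0, 60.0, 60.0, 0.9]]))
        a = abc_smc(quadratic_distance, default_prior(), tol, n_particles=20, seed=5)
        b = abc_smc(quadratic_distance, default_prior(), tol, n_particles=20, seed=5)
        np.testing.assert_array_equal(a[0].thetas, b[0].thetas)
        np.testing.assert_array_equal(a[0].weights, b[0].weights)

    def test_all_accepting_tolerances_recover_prior_mean(self):
        huge = ToleranceSchedule(np.full((2, 5), 1e9))
        pops = abc_smc(quadratic_distance, default_prior(), huge, n_particles=400, seed=7)
        final = pops[-1]
        for i, half_width in enumerate(default_prior().upper / 2):
            mean = float(final.weights @ final.thetas[:, i])
            se = 2 * half_width / math.sqrt(12 * 400)  # uniform SD / sqrt(N)
            assert abs(mean - half_width) <= 4 * se, f"k{i+1}"

    def test_rejection_equals_single_population_smc(self):
        eps = np.array([60.0, 8.0, 60.0, 60.0, 0.9])
        rej = abc_rejection(quadratic_distance, default_prior(), eps, n_particles=30, seed=9)
        smc = abc_smc(
            quadratic_distance, default_prior(), ToleranceSchedule(eps[None, :]),
            n_particles=30, seed=9,
        )[0]
        np.testing.assert_array_equal(rej.thetas, smc.thetas)
        assert np.all(rej.weights == rej.weights[0])  # uniform after normalization

    def test_huge_tolerance_accepts_everything(self):
        pop = abc_rejection(
            quadratic_distance, default_prior(), np.full(5, 1e9), n_particles=50, seed=1
        )
        assert pop.acceptance_rate == 1.0

    def test_impossible_tolerance_aborts_with_diagnostic(self):
        def far(theta, rng):
            return np.full(5, 1e6)

        with pytest.raises(AcceptanceFloorError, match="d1"):
            abc_smc(
                far, default_prior(), ToleranceSchedule(np.ones((1, 5))),
                n_particles=5, seed=0, min_attempts_before_floor=200,
            )

    def test_weighted_quantiles_bracket_the_support(self):
        pops = abc_smc(
            quadratic_distance, default_prior(),
            ToleranceSchedule(np.full((1, 5), 1e9)), n_particles=200, seed=13,
        )
        lo, hi = pops[0].weighted_quantile([0.05, 0.95], 1)
        assert 0.0 < lo < 50.0 < hi < 100.0
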