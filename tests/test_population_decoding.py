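import numpy as np
import pytest

from mtfano.core import TuningCurveFit
from mtfano.population_decoding import (CorrelationKernel, FFTuningSpec,
                                        build_covariance, corr_kernel_value,
                                        cumulative_tuning,
                                        heterogeneous_population,
                                        homogeneous_population, kernel_hwhm,
                                        linear_fisher, mean_cr_bound,
                                        neurons_to_threshold, time_to_threshold)

CURVE = TuningCurveFit(2.0, 28.0, 3.0, 0.0)
THETAS = [0.0, 5.0, 10.0]


class TestCorrelationKernel:
    def test_anchor_values(self):
        k = CorrelationKernel(0.1, 1.0)
        assert corr_kernel_value(0.0, k) == pytest.approx(0.1)
        assert corr_kernel_value(180.0, k) == pytest.approx(0.0, abs=1e-15)
        assert corr_kernel_value(-180.0, k) == pytest.approx(0.0, abs=1e-15)

    def test_even_and_periodic(self):
        k = CorrelationKernel(0.1, 1.0)
        d = np.array([13.0, 64.0, 120.0])
        assert np.allclose(k(d), k(-d))
        assert np.allclose(k(d), k(d + 360.0))

    def test_half_width_at_half_max_64_degrees(self):
        assert round(kernel_hwhm(CorrelationKernel(0.1, 1.0))) == 64

    def test_values_within_bounds(self):
        k = CorrelationKernel(0.1, 1.0)
        d = np.linspace(-180, 180, 721)
        assert np.all(k(d) >= -1e-15) and np.all(k(d) <= 0.1 + 1e-15)


class TestFFTuningSpec:
    GRID = np.arange(0.0, 360.0, 15.0)

    def test_mean_ff_exactly_one(self):
        for sign in ("positive", "flat", "negative"):
            spec = FFTuningSpec(sign, 0.3)
            ff = spec.ff(self.GRID, pref_deg=45.0, grid_deg=self.GRID)
            assert np.mean(ff) == pytest.approx(1.0, abs=1e-10)

    def test_positive_and_negative_are_mirror_images(self):
        pos = FFTuningSpec("positive", 0.3).ff(self.GRID, 0.0, self.GRID)
        neg = FFTuningSpec("negative", 0.3).ff(self.GRID, 0.0, self.GRID)
        assert np.allclose(pos - 1.0, -(neg - 1.0))

    def test_positive_dips_at_preferred(self):
        spec = FFTuningSpec("positive", 0.3)
        ff = spec.ff(np.array([0.0, 90.0]), 0.0, self.GRID)
        assert ff[0] < ff[1]

    def test_excessive_amplitude_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            FFTuningSpec("positive", 3.0).ff(self.GRID, 0.0, self.GRID)


class TestCovariance:
    def test_diagonal_when_uncorrelated(self):
        pop = homogeneous_population(CURVE, 6, corr=CorrelationKernel(0.0, 1.0))
        s0, _ = build_covariance(pop, 0.0)
        assert np.allclose(s0, np.diag(np.diag(s0)))

    def test_assembly_matches_hand_formula(self):
        pop = homogeneous_population(CURVE, 6, ff_spec=FFTuningSpec("positive", 0.3),
                                     corr=CorrelationKernel(0.1, 1.0), epsilon=2.0)
        theta = 12.0
        s0, se = build_covariance(pop, theta)
        f = np.array([c(theta) for c in pop.tuning_set])
        ff = np.array([pop.ff_spec.ff(theta, c.pref_direction, pop.direction_grid)
                       for c in pop.tuning_set]).ravel()
        var = ff * f
        assert np.allclose(np.diag(s0), var)
        prefs = pop.pref_directions
        for i in range(6):
            for j in range(i + 1, 6):
                c_ij = pop.corr(prefs[i] - prefs[j])
                assert s0[i, j] == pytest.approx(c_ij * np.sqrt(var[i] * var[j]))
        # rank-one information-limiting term, f' checked by finite differences
        h = 1e-5
        fp = np.array([(c(theta + h) - c(theta - h)) / (2 * h)
                       for c in pop.tuning_set])
        assert np.allclose(se - s0, 2.0 * np.outer(fp, fp), atol=1e-8)

    def test_two_neuron_hand_case(self):
        # variances 4 and 9 with correlation 0.05: off-diagonal 0.3
        c = 0.05 * np.sqrt(4.0 * 9.0)
        assert c == pytest.approx(0.3)
        # and with eps=1, f' = (2, -1): rank-one update [[4,-2],[-2,1]]
        fp = np.array([2.0, -1.0])
        assert np.allclose(np.outer(fp, fp), [[4.0, -2.0], [-2.0, 1.0]])


class TestLinearFisher:
    def test_additivity_for_independent_population(self):
        pop = homogeneous_population(CURVE, 40, corr=CorrelationKernel(0.0, 1.0))
        res = linear_fisher(pop, 7.0)
        s0, _ = build_covariance(pop, 7.0)
        fp = np.array([c.derivative(7.0) for c in pop.tuning_set])
        assert res.J0 == pytest.approx(np.sum(fp ** 2 / np.diag(s0)), rel=1e-9)

    def test_rank_one_update_identity(self):
        for seed in range(5):
            r = np.random.default_rng(seed)
            pool = [TuningCurveFit(r.uniform(1, 4), r.uniform(10, 40),
                                   r.uniform(1, 4), 0.0) for _ in range(10)]
            pop = heterogeneous_population(pool, 30, seed=seed,
                                           ff_spec=FFTuningSpec("positive", 0.2),
                                           corr=CorrelationKernel(0.1, 1.0),
                                           epsilon=4.0)
            s0, se = build_covariance(pop, 3.0)
            fp = np.array([c.derivative(3.0) for c in pop.tuning_set])
            j0 = fp @ np.linalg.solve(s0, fp)
            j_direct = fp @ np.linalg.solve(se, fp)
            j_formula = j0 / (1.0 + 4.0 * j0)
            assert abs(j_direct - j_formula) / j_formula < 1e-6

    def test_hand_values_for_bound(self):
        # J0=1, eps=4: J_eps = 0.2, bound sqrt(5)
        assert 1.0 / (1.0 + 4.0 * 1.0) == pytest.approx(0.2)
        res = linear_fisher(homogeneous_population(CURVE, 50, epsilon=4.0), 5.0)
        assert res.cr_bound_deg == pytest.approx(np.sqrt(1.0 / res.J0 + 4.0))
        assert res.J_eps <= res.J0
        assert res.J_eps < 1.0 / 4.0

    def test_bound_approaches_floor_for_large_population(self):
        strong = TuningCurveFit(4.0, 56.0, 3.0, 0.0)
        pop = homogeneous_population(strong, 2000,
                                     corr=CorrelationKernel(0.0, 1.0), epsilon=4.0)
        b = linear_fisher(pop, 4.0).cr_bound_deg
        assert b > 2.0
        assert (b - 2.0) / 2.0 < 0.01


class TestThresholdSearches:
    def _family(self, sign):
        def make(n):
            return homogeneous_population(
                CURVE, n, ff_spec=FFTuningSpec(sign, 0.3),
                corr=CorrelationKernel(0.1, 1.0), epsilon=4.0)
        return make

    def test_bound_monotone_and_crossing(self):
        mn, curve = neurons_to_threshold(self._family("positive"), 3.0,
                                         [25, 50, 100, 200], theta_grid=THETAS)
        assert np.all(np.diff(curve[:, 1]) <= 1e-9)
        assert mn in (50, 100, 200)

    def test_unreachable_below_floor(self):
        mn, _ = neurons_to_threshold(self._family("positive"), 1.9,
                                     [25, 50], theta_grid=THETAS)
        assert mn is None

    def test_independent_closed_form_case(self):
        # independent homogeneous population: minimal N solves 1/(j1*N) <= th^2 - eps
        def fam(n):
            return homogeneous_population(CURVE, n,
                                          corr=CorrelationKernel(0.0, 1.0),
                                          epsilon=4.0)
        j1 = linear_fisher(fam(100), 0.0).J0 / 100.0
        target = 1.0 / (j1 * (3.0 ** 2 - 4.0))
        grid = sorted({25, 50, 100, 200, 400, int(np.ceil(target))})
        mn, _ = neurons_to_threshold(fam, 3.0, grid, theta_grid=[0.0])
        assert mn == int(np.ceil(target))

    def test_time_to_threshold(self):
        rate = TuningCurveFit(2.0 / 250, 28.0 / 250, 3.0, 0.0)

        def fam(t):
            c = cumulative_tuning(rate, 56.0, t)
            if c is None:
                return None
            return homogeneous_population(c, 200,
                                          ff_spec=FFTuningSpec("positive", 0.3),
                                          corr=CorrelationKernel(0.1, 1.0),
                                          epsilon=4.0)
        mt, curve = time_to_threshold(fam, 3.0, np.arange(0.0, 260.0, 25.0),
                                      theta_grid=THETAS)
        assert np.isinf(curve[curve[:, 0] <= 56.0, 1]).all()   # no signal before latency
        finite = curve[np.isfinite(curve[:, 1])]
        assert np.all(np.diff(finite[:, 1]) <= 1e-9)
        assert mt is not None and mt > 56.0

    def test_amplitude_scaling_law(self):
        # doubling tuning amplitudes at eps=0 doubles J0, shrinks bound by sqrt(2)
        pop1 = homogeneous_population(CURVE, 50, corr=CorrelationKernel(0.1, 1.0))
        double = TuningCurveFit(4.0, 56.0, 3.0, 0.0)
        pop2 = homogeneous_population(double, 50, corr=CorrelationKernel(0.1, 1.0))
        r1, r2 = linear_fisher(pop1, 5.0), linear_fisher(pop2, 5.0)
        assert r2.J0 == pytest.approx(2.0 * r1.J0, rel=1e-6)
        assert r2.cr_bound_deg == pytest.approx(r1.cr_bound_deg / np.sqrt(2), rel=1e-6)


class TestHeterogeneous:
    def test_pool_of_one_equals_homogeneous(self):
        het = heterogeneous_population([CURVE], 12, seed=0)
        hom = homogeneous_population(CURVE, 12)
        assert np.allclose(het.pref_directions, hom.pref_directions)
        assert all(a.amplitude_A == b.amplitude_A
                   for a, b in zip(het.tuning_set, hom.tuning_set))

    def test_without_replacement_is_permutation(self):
        pool = [TuningCurveFit(1.0 + i, 10.0 + i, 2.0, 0.0) for i in range(6)]
        pop = heterogeneous_population(pool, 6, seed=3,
                                       sample_with_replacement=False)
        assert sorted(c.baseline_b for c in pop.tuning_set) == \
            sorted(c.baseline_b for c in pool)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            heterogeneous_population([], 5, seed=0)
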