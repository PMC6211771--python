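import itertools

import numpy as np
import pandas as pd
import pytest

from mtfano.core import BinnedSpikeTensor, CountMatrix, GainModelParams, TuningCurveFit
from mtfano.response_stats import (count_in_window, direction_stats,
                                   estimate_latency, ff_expanding_windows,
                                   fit_tuning_curve, mean_matched_ffti,
                                   tuning_indices)
from mtfano.synthetic_data import SyntheticConfig, generate_temporal_trains


class TestCountInWindow:
    def test_half_open_interval(self):
        spikes = [[[np.array([10.0, 100.0, 249.0]), np.array([250.0, 100.0])]]]
        cm = count_in_window((spikes, [0.0]), (0.0, 250.0))
        # 250.0 is excluded: [0, 250)
        assert cm.counts[0, 0, 0] == 3
        assert cm.counts[0, 0, 1] == 1

    def test_poisson_rate_recovery(self, rng):
        rate = 0.04  # events per ms -> expect 10 per 250 ms
        spikes = [[[np.sort(rng.uniform(0, 250, rng.poisson(10)))
                    for _ in range(500)]]]
        cm = count_in_window((spikes, [0.0]), (0.0, 250.0))
        m = cm.counts.mean()
        se = cm.counts.std() / np.sqrt(cm.counts.size)
        assert m == pytest.approx(10.0, abs=3 * se + 1e-9)

    def test_window_validation(self):
        with pytest.raises(ValueError, match="window"):
            count_in_window(([], [0.0]), (100.0, 50.0))


class TestDirectionStats:
    def test_identical_counts_zero_ff(self):
        cm = CountMatrix(np.full((1, 3, 5), 7.0), np.array([-90.0, 0.0, 90.0]))
        ds = direction_stats(cm, pref=0.0)[0]
        assert np.all(ds.var == 0.0)
        assert np.all(ds.ff == 0.0)

    def test_hand_arithmetic(self):
        counts = np.array([[[4.0, 6.0], [10.0, 10.0], [4.0, 6.0]]])
        cm = CountMatrix(counts, np.array([-90.0, 0.0, 90.0]))
        ds = direction_stats(cm, pref=0.0)[0]
        assert ds.mean[0] == 5.0 and ds.var[0] == 2.0
        assert ds.ff[0] == pytest.approx(0.4)

    def test_unbiased_variance_matches_two_pass(self, rng):
        counts = rng.poisson(9.0, (1, 5, 30)).astype(float)
        cm = CountMatrix(counts, np.arange(5) * 15.0)
        ds = direction_stats(cm, pref=0.0)[0]
        for d in range(5):
            x = counts[0, d]
            two_pass = np.sum((x - x.mean()) ** 2) / (x.size - 1)
            assert abs(ds.var[d] - two_pass) <= 1e-12 * max(two_pass, 1.0)

    def test_gain_model_poisson_ff_near_one(self, poisson_like_counts):
        stats = direction_stats(poisson_like_counts, pref=0.0)
        ffs = np.concatenate([ds.ff for ds in stats])
        # FF estimator SE ~ sqrt(2/(n-1)) for n=400 trials
        assert np.all(np.abs(ffs - 1.0) < 3.5 * np.sqrt(2.0 / 399))

    def test_orth_is_average_of_both_sides(self):
        counts = np.zeros((1, 3, 4))
        counts[0, 0] = [1, 1, 1, 1]   # -90
        counts[0, 1] = [9, 9, 9, 9]   # 0 (pref)
        counts[0, 2] = [3, 3, 3, 3]   # +90
        cm = CountMatrix(counts, np.array([-90.0, 0.0, 90.0]))
        ds = direction_stats(cm, pref=0.0)[0]
        assert ds.r_orth == pytest.approx(2.0)


class TestTuningIndices:
    def _stats(self, ff_pref, ff_orth, r_pref=10.0, r_orth=5.0):
        from mtfano.response_stats import DirectionStats
        return DirectionStats(
            directions=np.array([-90.0, 0.0, 90.0]),
            mean=np.array([r_orth, r_pref, r_orth]),
            var=np.array([ff_orth * r_orth, ff_pref * r_pref, ff_orth * r_orth]),
            ff=np.array([ff_orth, ff_pref, ff_orth]),
            pref_direction=0.0)

    def test_symmetric_ff_gives_zero_ffti(self):
        ti = tuning_indices(self._stats(0.8, 0.8))
        assert ti.FFTI == pytest.approx(0.0)

    def test_ffti_hand_value(self):
        ti = tuning_indices(self._stats(ff_pref=0.5, ff_orth=1.0))
        assert ti.FFTI == pytest.approx(0.5 / 1.5)
        assert ti.delta_FF == pytest.approx(0.5)

    def test_di_boundary(self):
        ti = tuning_indices(self._stats(0.5, 1.0, r_pref=10.0, r_orth=0.0))
        assert ti.DI == pytest.approx(1.0)

    def test_undefined_ff_orth_excludes_neuron(self):
        ds = self._stats(0.5, np.nan)
        ti = tuning_indices(ds)
        assert np.isnan(ti.FFTI)
        assert "FF_orth was not defined" in ti.excluded_reason

    def test_indices_bounded_on_gain_model_data(self, poisson_like_counts):
        for ds in direction_stats(poisson_like_counts, pref=0.0):
            ti = tuning_indices(ds)
            for v in (ti.DI, ti.VTI, ti.FFTI):
                assert -1.0 <= v <= 1.0


class TestTuningFit:
    def test_noiseless_von_mises_recovery(self):
        truth = TuningCurveFit(10.0, 60.0, 2.0, 30.0)
        theta = np.arange(-180.0, 180.0, 15.0)
        fit = fit_tuning_curve(theta, truth(theta), shape="von_mises")
        assert fit.baseline_b == pytest.approx(10.0, abs=1e-4)
        assert fit.amplitude_A == pytest.approx(60.0, abs=1e-4)
        assert fit.width == pytest.approx(2.0, abs=1e-4)
        assert fit.pref_direction == pytest.approx(30.0, abs=1e-3)
        assert fit.rss < 1e-8

    def test_gaussian_width_is_sd(self):
        truth = TuningCurveFit(3.0, 20.0, 35.0, 0.0, shape="gaussian")
        theta = np.arange(-90.0, 91.0, 15.0)
        fit = fit_tuning_curve(theta, truth(theta), shape="gaussian")
        assert fit.width == pytest.approx(35.0, abs=1e-3)

    def test_flat_counts_give_zero_amplitude(self):
        theta = np.arange(-90.0, 91.0, 15.0)
        fit = fit_tuning_curve(theta, np.full(theta.size, 8.0))
        assert fit.amplitude_A == pytest.approx(0.0, abs=1e-3)

    def test_too_few_directions(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_tuning_curve([0.0, 90.0, 180.0], [1.0, 2.0, 1.0])


class TestLatency:
    def test_noiseless_step(self):
        psth = np.zeros(300)
        psth[50 + 28:] = 50.0   # onset at bin 50 (100 ms), step 56 ms later
        assert estimate_latency(psth, 2.0, 100.0) == pytest.approx(56.0, abs=2.0)

    def test_constant_rate_flagged(self):
        assert estimate_latency(np.full(300, 10.0), 2.0, 100.0) is None

    def test_noisy_recovery_rate(self, rng):
        # latency 94 ms with realistic PSTH noise: within +-2 bins in >=95/100
        hits = 0
        for _ in range(100):
            baseline, driven, n_trials = 5.0, 70.0, 100
            rate = np.full(400, baseline)
            rate[100 + 47:] = driven     # onset bin 100 (200 ms), latency 94 ms
            counts = rng.poisson(rate * 0.002, (n_trials, 400))
            psth = counts.mean(axis=0) / 0.002
            lat = estimate_latency(psth, 2.0, 200.0)
            if lat is not None and abs(lat - 94.0) <= 4.0:
                hits += 1
        assert hits >= 95


class TestExpandingWindows:
    def _trains(self, var_g, tau, n_trials=400, seed=0):
        cfg = SyntheticConfig(
            n_neurons=2, n_trials=n_trials, direction_grid=[0.0],
            gain_params=GainModelParams(1.0, var_g),
            tuning=TuningCurveFit(25.0, 0.0, 2.0, 0.0),
            tau_gain_ms=tau, trial_duration_ms=500.0, seed=seed)
        return generate_temporal_trains(cfg)

    def test_poisson_flat_ff(self):
        df = ff_expanding_windows(self._trains(0.0, 0.0), [50.0, 100.0, 250.0, 500.0])
        pop = df.groupby("duration_ms")["population_mean"].first()
        assert np.all(np.abs(pop - 1.0) < 0.15)

    def test_slow_gain_ff_grows_with_window(self):
        df = ff_expanding_windows(self._trains(0.15, 200.0, seed=3),
                                  [20.0, 100.0, 500.0])
        pop = df.groupby("duration_ms")["population_mean"].first().to_numpy()
        assert pop[0] < pop[1] < pop[2]

    def test_response_alignment_shift_identity(self):
        trains = self._trains(0.0, 0.0, n_trials=5, seed=1)
        a = ff_expanding_windows(trains, [100.0, 200.0])
        b = ff_expanding_windows(trains, [100.0, 200.0],
                                 alignment="response_onset", latencies_ms=[0.0, 0.0])
        assert np.allclose(a["ff"], b["ff"], equal_nan=True)


class TestMeanMatching:
    def _state(self, rng, ff_level, n=20):
        rows = []
        for d in (-90.0, 0.0, 90.0):
            means = rng.uniform(5, 20, n)
            ffs = rng.normal(ff_level, 0.05, n)
            for m, f in zip(means, ffs):
                rows.append({"direction_deg": d, "mean": m, "ff": f})
        return pd.DataFrame(rows)

    def test_identical_states_no_discard(self, rng):
        a = self._state(rng, 1.0)
        res = mean_matched_ffti(a, a.copy(), n_resamples=20, seed=0)
        assert np.allclose(res.ffti_a, res.raw_ffti_a)
        assert np.allclose(res.ffti_b, res.raw_ffti_b)

    def test_disjoint_distributions_error(self):
        rows_a = [{"direction_deg": d, "mean": m, "ff": 1.0}
                  for d in (-90.0, 0.0, 90.0) for m in (1.0, 2.0)]
        rows_b = [{"direction_deg": d, "mean": m, "ff": 1.0}
                  for d in (-90.0, 0.0, 90.0) for m in (100.0, 101.0)]
        with pytest.raises(ValueError, match="direction"):
            mean_matched_ffti(pd.DataFrame(rows_a), pd.DataFrame(rows_b),
                              n_resamples=5, seed=0)

    def test_four_neuron_toy_matches_enumeration(self):
        # At the preferred direction state A has 3 neurons in the low bin and
        # 1 in the high bin, state B the mirror image.  Exactly one of A's
        # low-bin neurons is kept (uniformly) alongside its high-bin neuron,
        # and symmetrically for B, so each state's matched mean FF takes 3
        # equally likely values that we can enumerate by hand.
        ff_a_low, ff_a_high = [0.2, 0.4, 0.9], [1.5]
        ff_b_low, ff_b_high = [0.6], [1.0, 1.2, 2.0]
        rows_a = [{"direction_deg": 0.0, "mean": 1.0, "ff": f} for f in ff_a_low]
        rows_a += [{"direction_deg": 0.0, "mean": 10.0, "ff": f} for f in ff_a_high]
        rows_b = [{"direction_deg": 0.0, "mean": 1.2, "ff": f} for f in ff_b_low]
        rows_b += [{"direction_deg": 0.0, "mean": 9.8, "ff": f} for f in ff_b_high]
        for d in (-90.0, 90.0):   # orthogonal directions match trivially
            rows_a.append({"direction_deg": d, "mean": 5.0, "ff": 1.0})
            rows_b.append({"direction_deg": d, "mean": 5.0, "ff": 1.0})
        res = mean_matched_ffti(pd.DataFrame(rows_a), pd.DataFrame(rows_b),
                                n_bins=2, n_resamples=6000, seed=0)
        # enumerate: matched FF_pref(A) in {(x+1.5)/2 : x in ff_a_low}, p=1/3
        support_a = sorted((x + 1.5) / 2 for x in ff_a_low)
        ffti_support = sorted((1.0 - fp) / (1.0 + fp) for fp in support_a)
        observed = sorted(set(np.round(res.ffti_a, 12)))
        assert np.allclose(observed, ffti_support)
        # each branch uniformly likely (3-sigma binomial band)
        for val in ffti_support:
            frac = np.mean(np.isclose(res.ffti_a, val))
            assert frac == pytest.approx(1 / 3, abs=3 * np.sqrt((1 / 3) * (2 / 3) / 6000))

    def test_preserves_sign_of_ffti_difference(self, rng):
        # equal count distributions, different FF tunings
        a, b = [], []
        for d in (-90.0, 0.0, 90.0):
            means = rng.uniform(5, 20, 25)
            for m in means:
                a.append({"direction_deg": d, "mean": m,
                          "ff": 0.6 if d == 0.0 else 1.0})
                b.append({"direction_deg": d, "mean": m,
                          "ff": 1.3 if d == 0.0 else 1.2})
        res = mean_matched_ffti(pd.DataFrame(a), pd.DataFrame(b),
                                n_resamples=200, seed=1)
        assert res.ffti_a.mean() > res.ffti_b.mean()
        assert res.raw_ffti_a > res.raw_ffti_b
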