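"""F1 projection, blank-referenced d', bootstrap, window sweep, STA."""

import numpy as np
import pytest

from conftest import make_trial_set, poisson_spike_trains
from lgnsnr.snr import (
    CountingWindow,
    InsufficientDataError,
    Trial,
    TrialSet,
    bootstrap_se,
    dprime_f1,
    f1_projection,
    spike_triggered_average,
    window_sweep,
)


def modulated_rate(r0, depth, freq, duration=1.0, dt=0.001):
    t = np.arange(0.0, duration, dt)
    return r0 * (1.0 + depth * np.sin(2 * np.pi * freq * t))


WINDOW = CountingWindow(0.0, 1.0)


class TestF1Projection:
    def test_empty_train(self):
        assert f1_projection(np.array([]), WINDOW, 5.0) == 0j

    def test_single_spike_phase(self):
        z = f1_projection(np.array([0.25]), WINDOW, 1.0)
        assert z == pytest.approx(np.exp(-1j * np.pi / 2))
        assert abs(z) == pytest.approx(1.0)

    def test_spikes_outside_window_ignored(self):
        z = f1_projection(np.array([-0.5, 1.0, 2.3]), WINDOW, 5.0)
        assert z == 0j

    def test_homogeneous_poisson_mean_magnitude(self):
        # Package side: |F1| of simulated 50 Hz Poisson trains at 5 Hz.
        # Oracle side: for a homogeneous Poisson train over an integer
        # number of cycles the spike phases are i.i.d. uniform, so |F1|
        # is the modulus of a 2-D random walk -- simulate that directly.
        n_trials = 10**4
        rng = np.random.default_rng(7)
        trains = poisson_spike_trains(np.full(1000, 50.0), 0.001, n_trials, rng)
        mags = np.array([abs(f1_projection(t, WINDOW, 5.0)) for t in trains])

        rng_o = np.random.default_rng(8)
        counts = rng_o.poisson(50.0, n_trials)
        oracle = np.array(
            [
                abs(np.sum(np.exp(1j * rng_o.uniform(0, 2 * np.pi, c))))
                for c in counts
            ]
        )
        se = np.sqrt(mags.var() / n_trials + oracle.var() / n_trials)
        assert abs(mags.mean() - oracle.mean()) < 2.576 * se


class TestDprimeF1:
    def test_identical_sets_give_zero(self):
        rng = np.random.default_rng(3)
        trains = poisson_spike_trains(np.full(1000, 30.0), 0.001, 20, rng)
        ts = make_trial_set(trains, trains, frequency_hz=5.0)
        est = dprime_f1(ts, "stim", WINDOW)
        assert est.dprime == 0.0
        assert est.n_stim == est.n_blank == 20

    def test_insufficient_trials(self):
        rng = np.random.default_rng(4)
        trains = poisson_spike_trains(np.full(100, 30.0), 0.001, 3, rng)
        ts = make_trial_set(trains[:1], trains[1:], frequency_hz=5.0, duration=0.1)
        with pytest.raises(InsufficientDataError):
            dprime_f1(ts, "stim", CountingWindow(0.0, 0.1))

    def test_deeper_modulation_increases_dprime(self):
        # ordering oracle: over 100 replicate simulations, doubling the
        # modulation depth raises the estimated d'
        rng = np.random.default_rng(11)
        wins = 0
        n_rep = 100
        for _ in range(n_rep):
            blank = poisson_spike_trains(np.full(1000, 20.0), 0.001, 40, rng)
            d_by_depth = []
            for depth in (0.25, 0.5):
                stim = poisson_spike_trains(
                    modulated_rate(20.0, depth, 5.0), 0.001, 40, rng
                )
                ts = make_trial_set(stim, blank, frequency_hz=5.0)
                d_by_depth.append(dprime_f1(ts, "stim", WINDOW).dprime)
            wins += d_by_depth[1] > d_by_depth[0]
        assert wins > 0.7 * n_rep

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        stim = poisson_spike_trains(modulated_rate(25.0, 0.6, 4.0), 0.001, 30, rng)
        blank = poisson_spike_trains(np.full(1000, 25.0), 0.001, 30, rng)
        ts = make_trial_set(stim, blank, frequency_hz=4.0)
        d0 = dprime_f1(ts, "stim", WINDOW).dprime

        shift = 0.35
        ts_shifted = make_trial_set(
            [s + shift for s in stim], [b + shift for b in blank], frequency_hz=4.0
        )
        d1 = dprime_f1(
            ts_shifted, "stim", CountingWindow(shift, 1.0 + shift)
        ).dprime
        assert d1 == pytest.approx(d0, rel=1e-9)

    def test_trial_order_irrelevant(self):
        rng = np.random.default_rng(6)
        stim = poisson_spike_trains(modulated_rate(25.0, 0.6, 4.0), 0.001, 30, rng)
        blank = poisson_spike_trains(np.full(1000, 25.0), 0.001, 30, rng)
        d0 = dprime_f1(make_trial_set(stim, blank, 4.0), "stim", WINDOW).dprime
        perm = np.random.default_rng(0).permutation(len(stim))
        d1 = dprime_f1(
            make_trial_set([stim[i] for i in perm], blank[::-1], 4.0), "stim", WINDOW
        ).dprime
        assert d1 == pytest.approx(d0, rel=1e-12)

    def test_vanishing_modulation_gives_zero_mean_dprime(self):
        # with no signal, the estimator is unbiased around 0
        rng = np.random.default_rng(12)
        ds = []
        for _ in range(100):
            stim = poisson_spike_trains(np.full(500, 20.0), 0.002, 30, rng)
            blank = poisson_spike_trains(np.full(500, 20.0), 0.002, 30, rng)
            ds.append(dprime_f1(make_trial_set(stim, blank, 5.0), "stim", WINDOW).dprime)
        ds = np.asarray(ds)
        assert abs(ds.mean()) < 2 * ds.std(ddof=1) / np.sqrt(len(ds))


class TestBootstrap:
    def _trial_set(self, rng, n=40):
        stim = poisson_spike_trains(modulated_rate(20.0, 0.5, 5.0), 0.001, n, rng)
        blank = poisson_spike_trains(np.full(1000, 20.0), 0.001, n, rng)
        return make_trial_set(stim, blank, 5.0)

    def test_no_resampling_variance(self):
        train = np.array([0.1, 0.3, 0.5])
        trials = [Trial(i, "stim", train) for i in range(5)] + [
            Trial(5 + i, "blank", np.array([0.2])) for i in range(5)
        ]
        ts = TrialSet(
            trials=trials,
            conditions=make_trial_set([train], [train], 5.0).conditions,
            stim_on=0.0,
            stim_off=1.0,
        )
        assert bootstrap_se(ts, "stim", WINDOW, n_boot=100, seed=0) == 0.0

    def test_seed_determinism(self):
        ts = self._trial_set(np.random.default_rng(9))
        a = bootstrap_se(ts, "stim", WINDOW, n_boot=500, seed=42)
        b = bootstrap_se(ts, "stim", WINDOW, n_boot=500, seed=42)
        c = bootstrap_se(ts, "stim", WINDOW, n_boot=500, seed=43)
        assert a == b
        assert a != c

    def test_se_shrinks_with_trial_count(self):
        rng = np.random.default_rng(10)
        med = {}
        for n in (50, 500):
            ses = [
                bootstrap_se(self._trial_set(rng, n), "stim", WINDOW, 300, seed=i)
                for i in range(20)
            ]
            med[n] = np.median(ses)
        assert med[500] < med[50]

    def test_invalid_resample_count(self):
        ts = self._trial_set(np.random.default_rng(9))
        with pytest.raises(ValueError):
            bootstrap_se(ts, "stim", WINDOW, n_boot=1, seed=0)

    def test_se_calibrated_against_empirical_sd(self):
        # the bootstrap SE should track the true sampling SD of d'
        # across independent datasets from the same generative model
        rng = np.random.default_rng(13)
        ds = [
            dprime_f1(self._trial_set(rng, 50), "stim", WINDOW).dprime
            for _ in range(200)
        ]
        empirical_sd = np.std(ds, ddof=1)
        ses = [
            bootstrap_se(self._trial_set(rng, 50), "stim", WINDOW, 2000, seed=i)
            for i in range(10)
        ]
        assert abs(np.median(ses) - empirical_sd) < 0.25 * empirical_sd


class TestWindowSweep:
    def _trial_set(self, rng):
        rate = np.concatenate([modulated_rate(20.0, 0.5, 5.0), np.full(300, 20.0)])
        stim = poisson_spike_trains(rate, 0.001, 60, rng)
        blank = poisson_spike_trains(np.full(1300, 20.0), 0.001, 60, rng)
        return make_trial_set(stim, blank, 5.0)

    def test_zero_offsets_reproduce_dprime_f1(self):
        ts = self._trial_set(np.random.default_rng(14))
        res = window_sweep(ts, "stim", np.array([0.0]), np.array([0.0]))
        expected = dprime_f1(ts, "stim", CountingWindow(0.0, 1.0)).dprime
        assert res.dprime[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_default_grid_and_level_set(self):
        ts = self._trial_set(np.random.default_rng(15))
        res = window_sweep(ts, "stim", criterion=1.27)
        assert res.dprime.shape == (11, 11)
        assert not np.any(np.isnan(res.dprime))
        assert res.at_criterion.dtype == bool
        assert np.array_equal(res.at_criterion, res.dprime >= 1.27)

    def test_5x5_sweep_complete(self):
        ts = self._trial_set(np.random.default_rng(16))
        offs = np.arange(0.0, 0.201, 0.05)
        res = window_sweep(ts, "stim", offs, offs)
        assert res.dprime.shape == (5, 5)
        assert np.all(np.isfinite(res.dprime))

    def test_infeasible_cells_are_nan_not_errors(self):
        rng = np.random.default_rng(17)
        stim = poisson_spike_trains(np.full(100, 40.0), 0.001, 10, rng)
        ts = make_trial_set(stim, stim, 10.0, duration=0.1)
        res = window_sweep(ts, "stim", np.array([0.0, 0.15]), np.array([0.0]))
        assert np.isfinite(res.dprime[0, 0])
        assert np.isnan(res.dprime[1, 0])


class TestSTA:
    def _lnp_run(self, n_frames, seed=0):
        # generic 1-D LNP cell: gamma-filtered noise, rectified, Poisson
        rng = np.random.default_rng(seed)
        dt = 0.01
        frames = rng.standard_normal(n_frames)
        t = np.arange(0.0, 0.2, dt)
        kern = (t / 0.03) ** 2 * np.exp(-t / 0.03)
        kern /= kern.sum()
        drive = np.convolve(frames, kern)[:n_frames]
        rate = np.maximum(20.0 + 80.0 * drive, 0.0)
        counts = rng.poisson(rate * dt)
        return frames, counts, kern

    def test_null_sta_is_flat(self):
        rng = np.random.default_rng(18)
        frames = rng.standard_normal((20000, 3))
        counts = rng.poisson(0.5, 20000)
        sta = spike_triggered_average(frames, counts, n_lags=10)
        se = 1.0 / np.sqrt(counts.sum())
        assert np.all(np.abs(sta) < 3.5 * se)

    def test_recovers_generative_kernel(self):
        frames, counts, kern = self._lnp_run(10**5, seed=19)
        sta = spike_triggered_average(frames, counts, n_lags=len(kern))
        r = np.corrcoef(sta[:, 0], kern)[0, 1]
        assert r > 0.9

    def test_no_spikes_is_an_error(self):
        frames = np.zeros((100, 2))
        with pytest.raises(ValueError, match="no spikes"):
            spike_triggered_average(frames, np.zeros(100), n_lags=5)
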