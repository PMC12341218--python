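"""Tests of trace quantification, curve fits and event-train statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import synpool as sp
from synpool.observables import FitError


def _trace(pre, post, stim=10.0):
    pre, post = np.asarray(pre, float), np.asarray(post, float)
    t = np.concatenate([np.linspace(0, 9, pre.size), stim + np.arange(post.size)])
    return sp.CaTrace(times=t, values=np.concatenate([pre, post]), stim_time=stim)


class TestCaPeak:
    def test_top5_mean_minus_baseline(self):
        trace = _trace([100] * 4, [200, 300, 280, 260, 240, 150, 120])
        assert sp.ca_peak(trace) == pytest.approx(156.0, abs=1e-12)

    def test_flat_trace_gives_zero(self):
        assert sp.ca_peak(_trace([7.5] * 3, [7.5] * 6)) == 0.0

    def test_exactly_five_post_samples(self):
        trace = _trace([10.0], [20, 30, 40, 50, 60])
        assert sp.ca_peak(trace) == pytest.approx(40.0 - 10.0)

    def test_too_few_post_samples_rejected(self):
        with pytest.raises(ValueError, match="post-stimulus"):
            sp.ca_peak(_trace([10.0] * 3, [20, 30, 40, 50]))

    def test_missing_baseline_rejected(self):
        t = np.arange(5.0)
        with pytest.raises(ValueError, match="pre-stimulus"):
            sp.ca_peak(sp.CaTrace(times=t + 100, values=t, stim_time=10.0))

    def test_invariant_under_constant_shift(self):
        base = _trace([100, 102, 98], [200, 300, 280, 260, 240, 150])
        shifted = sp.CaTrace(times=base.times, values=base.values + 55.5, stim_time=base.stim_time)
        assert sp.ca_peak(shifted) == pytest.approx(sp.ca_peak(base), abs=1e-10)


class TestNormalize:
    @pytest.mark.parametrize(
        "peak,ref,expected", [(50, 200, 25.0), (200, 200, 100.0), (11.8, 200, 5.9)]
    )
    def test_percent_of_reference(self, peak, ref, expected):
        assert sp.normalize_to_reference(peak, ref) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            sp.normalize_to_reference(10.0, 0.0)


class TestBoltzmannFit:
    CURVE = {"r_min": 0.0, "r_max": 100.0, "ec50_um": 1.2, "slope": 0.4}
    CONCS = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 50.0)

    def test_noiseless_roundtrip(self):
        data = sp.synth_dose_response(self.CURVE, self.CONCS, reps=1, noise=sp.NoiseModel(), seed=0)
        fit = sp.fit_boltzmann(data)
        assert fit.ec50 == pytest.approx(1.2, rel=1e-6)
        assert fit.r_min == pytest.approx(0.0, abs=1e-4)
        assert fit.r_max == pytest.approx(100.0, rel=1e-6)
        assert fit.slope == pytest.approx(0.4, rel=1e-6)
        assert fit.converged and fit.rss < 1e-12

    def test_unit_rescaling_rescales_asymptotes_only(self):
        data = sp.synth_dose_response(self.CURVE, self.CONCS, reps=1, noise=sp.NoiseModel(), seed=0)
        scaled = sp.DoseResponseData(data.concentrations_um, 3.0 * data.responses + 7.0)
        fit = sp.fit_boltzmann(scaled)
        assert fit.ec50 == pytest.approx(1.2, rel=1e-6)
        assert fit.slope == pytest.approx(0.4, rel=1e-6)
        assert fit.r_max == pytest.approx(307.0, rel=1e-6)

    def test_constant_response_flagged(self):
        data = sp.DoseResponseData(np.array(self.CONCS), np.full(len(self.CONCS), 42.0))
        with pytest.raises(FitError, match="do not vary"):
            sp.fit_boltzmann(data)

    def test_too_few_concentrations_rejected(self):
        data = sp.DoseResponseData(np.array([0.1, 1.0, 10.0]), np.array([0.0, 50.0, 100.0]))
        with pytest.raises(ValueError, match="4 distinct"):
            sp.fit_boltzmann(data)

    def test_noisy_recovery_is_accurate(self):
        errs = []
        for seed in range(5):
            data = sp.synth_dose_response(
                self.CURVE, self.CONCS, reps=5, noise=sp.NoiseModel(multiplicative_sd=0.10), seed=seed
            )
            errs.append(abs(sp.fit_boltzmann(data).ec50 - 1.2) / 1.2)
        assert np.median(errs) < 0.15


class TestExpDecayFit:
    def _trace(self, tau=20.0, amp=300.0, off=50.0, noise_sd=0.0, seed=0):
        t = np.arange(0.0, 120.0, 1.0)
        f = amp * np.exp(-t / tau) + off
        if noise_sd:
            f = f + np.random.default_rng(seed).normal(0, noise_sd, t.size)
        return sp.PHluorinTrace(times=t, fluorescence=f)

    def test_noiseless_roundtrip(self):
        fit = sp.fit_exp_decay(self._trace(), (0.0, 120.0))
        assert fit.tau == pytest.approx(20.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(300.0, rel=1e-6)
        assert fit.offset == pytest.approx(50.0, rel=1e-5)

    def test_noisy_tau_recovery(self):
        errs = [
            abs(sp.fit_exp_decay(self._trace(noise_sd=15.0, seed=s), (0.0, 120.0)).tau - 20.0) / 20.0
            for s in range(5)
        ]
        assert np.median(errs) < 0.10

    def test_rising_trace_flagged(self):
        t = np.arange(0.0, 50.0, 1.0)
        rising = sp.PHluorinTrace(times=t, fluorescence=10.0 + t)
        with pytest.raises(FitError, match="does not decay"):
            sp.fit_exp_decay(rising, (0.0, 50.0))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 4 samples"):
            sp.fit_exp_decay(self._trace(), (0.0, 2.5))


class TestModelObservables:
    def test_equilibrium_mepsc_rate(self, paper_rates, equilibrium):
        traj = sp.simulate(sp.RateSchedule.constant(paper_rates), equilibrium, [0.0, 60.0])
        rate = sp.mepsc_rate(traj, n_pool=100)
        np.testing.assert_allclose(rate.flux, 0.78371, atol=1e-5)

    def test_rate_linear_in_pool_size(self, lpa_trajectory):
        r1 = sp.mepsc_rate(lpa_trajectory, 100.0)
        r2 = sp.mepsc_rate(lpa_trajectory, 200.0)
        np.testing.assert_allclose(r2.flux, 2.0 * r1.flux, rtol=1e-12)

    def test_nonpositive_pool_rejected(self, lpa_trajectory):
        with pytest.raises(ValueError, match="n_pool"):
            sp.mepsc_rate(lpa_trajectory, 0.0)

    def test_phluorin_signal_tracks_fused_fraction(self, paper_rates, equilibrium):
        traj = sp.simulate(sp.RateSchedule.constant(paper_rates), equilibrium, [0.0, 30.0])
        trace = sp.phluorin_signal(traj, gain=1000.0, baseline_f=100.0)
        np.testing.assert_allclose(trace.fluorescence, 100.0 + 1000.0 * 0.004693, atol=1e-3)

    def test_zero_gain_gives_flat_baseline(self, lpa_trajectory):
        trace = sp.phluorin_signal(lpa_trajectory, gain=0.0, baseline_f=42.0)
        assert np.all(trace.fluorescence == 42.0)


class TestEventStatistics:
    def test_uniform_events_single_bin(self):
        train = sp.EventTrain(times=np.linspace(0.5, 59.5, 30), duration=60.0)
        fs = sp.bin_events(train, [0.0, 60.0])
        assert fs.rate_hz[0] == pytest.approx(0.5)

    def test_empty_train_zero_rates(self):
        train = sp.EventTrain(times=np.empty(0), duration=60.0)
        assert np.all(sp.bin_events(train, [0, 20, 40, 60]).rate_hz == 0)

    @given(st.integers(0, 200), st.integers(1, 8))
    def test_count_conservation(self, n, nbins):
        rng = np.random.default_rng(n * 13 + nbins)
        times = np.sort(rng.uniform(0, 100, n))
        train = sp.EventTrain(times=times, duration=100.0)
        edges = np.linspace(0, 100, nbins + 1)
        fs = sp.bin_events(train, edges)
        assert np.sum(fs.rate_hz * np.diff(edges)) == pytest.approx(n)

    def test_frequency_ratio_halves(self):
        times = np.sort(np.concatenate([np.linspace(0, 59, 30), 60 + np.linspace(0, 59, 15)]))
        train = sp.EventTrain(times=times, duration=120.0)
        assert sp.frequency_ratio(train, (0.0, 60.0), (60.0, 120.0)) == pytest.approx(0.5)

    def test_identical_windows_give_unity(self):
        train = sp.EventTrain(times=np.linspace(1, 59, 20), duration=60.0)
        assert sp.frequency_ratio(train, (0.0, 60.0), (0.0, 60.0)) == 1.0

    def test_empty_pre_window_rejected(self):
        train = sp.EventTrain(times=np.array([50.0]), duration=60.0)
        with pytest.raises(ValueError, match="pre-window"):
            sp.frequency_ratio(train, (0.0, 10.0), (40.0, 60.0))

    def test_ecdf_steps(self):
        train = sp.EventTrain(
            times=np.array([1.0, 2.0, 3.0]),
            duration=10.0,
            amplitudes=np.array([10.0, 20.0, 30.0]),
        )
        ecdf = sp.cumulative_amplitudes(train)
        assert ecdf(20.0) == pytest.approx(2 / 3)
        assert ecdf(30.0) == 1.0
        assert ecdf(9.99) == 0.0

    def test_ecdf_pools_across_trains(self):
        t1 = sp.EventTrain(np.array([1.0]), 10.0, np.array([10.0]))
        t2 = sp.EventTrain(np.array([1.0]), 10.0, np.array([30.0]))
        assert sp.cumulative_amplitudes([t1, t2])(10.0) == pytest.approx(0.5)

    def test_ecdf_requires_amplitudes(self):
        with pytest.raises(ValueError, match="amplitudes"):
            sp.cumulative_amplitudes(sp.EventTrain(np.array([1.0]), 10.0))
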