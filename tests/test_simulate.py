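"""Simulator unit tests: filters, onsets, drives, dynamics invariants."""

import numpy as np
import pytest

import refractiv as rf
from refractiv.simulate import sigmoid


class TestFilters:
    def test_coupling_values(self, spec):
        # default: unit first tap, exponential decay over the 5-ms support
        assert rf.coupling_filter(1, spec) == 1.0
        assert rf.coupling_filter(2, spec) == pytest.approx(np.exp(-0.2))
        assert rf.coupling_filter(5, spec) == pytest.approx(np.exp(-0.8))
        # zero beyond the 5-ms support
        assert rf.coupling_filter(6, spec) == 0.0
        assert rf.coupling_filter(10, spec) == 0.0

    def test_coupling_literal_lag_origin(self):
        spec = rf.NetworkSpec(coupling_lag_origin=0)
        assert rf.coupling_filter(1, spec) == pytest.approx(0.81873, abs=1e-5)
        assert rf.coupling_filter(6, spec) == 0.0

    def test_coupling_no_decay_limit(self):
        spec = rf.NetworkSpec(coupling_alpha=0.0)
        assert rf.coupling_filter(1, spec) == 1.0

    def test_refractory_values(self, spec):
        for lag in (1, 2, 3):
            assert rf.refractory_filter(lag, spec) == -100.0
        assert rf.refractory_filter(4, spec) == pytest.approx(
            -30 * np.exp(-4.0))
        assert rf.refractory_filter(10, spec) == pytest.approx(
            -30 * np.exp(-7.0))

    @pytest.mark.parametrize("lag", [0, 11, -1])
    def test_domain_errors(self, spec, lag):
        with pytest.raises(ValueError):
            rf.coupling_filter(lag, spec)
        with pytest.raises(ValueError):
            rf.refractory_filter(lag, spec)


class TestOnsets:
    def test_degenerate_clipping_gives_regular_grid(self, rng):
        sched = rf.sample_onsets(50, 50, 50, 400, rng)
        assert list(sched.onset_times) == [50, 100, 150, 200, 250, 300, 350]

    def test_zero_horizon_empty(self, rng):
        assert len(rf.sample_onsets(50, 10, 200, 0, rng)) == 0

    def test_intervals_within_clip_bounds(self, rng):
        sched = rf.sample_onsets(50, 10, 200, 200_000, rng)
        iv = np.diff(sched.onset_times)
        assert iv.min() >= 10 and iv.max() <= 200

    def test_mean_interval_matches_clipped_poisson_oracle(self, rng):
        # Monte-Carlo oracle: expected clipped-Poisson interval
        draws = np.clip(np.random.default_rng(0).poisson(50, 100_000), 10, 200)
        expected = draws.mean()
        sched = rf.sample_onsets(50, 10, 200, 10**6, rng)
        observed = np.diff(sched.onset_times).mean()
        assert observed == pytest.approx(expected, abs=2.0)

    def test_invalid_ordering_rejected(self, rng):
        with pytest.raises(ValueError):
            rf.sample_onsets(5, 10, 200, 1000, rng)


class TestDriveTrace:
    def _protocol(self, **kw):
        from refractiv.simulate import DriveProtocol, PulseSpec

        return DriveProtocol(**kw)

    def test_stimulus_pulse_covers_closed_interval(self):
        # gamma_S held on bins [t_S, t_S + 2]: three active bins
        from refractiv.simulate import DriveProtocol, PulseSpec, OnsetSchedule

        proto = DriveProtocol(
            stimulus=PulseSpec(amplitude=6.0, duration_ms=2),
            stimulated_ids=(0,),
        )
        sched = {"stimulus": OnsetSchedule([100]),
                 "excitatory": OnsetSchedule([]),
                 "inhibitory": OnsetSchedule([])}
        U = rf.drive_trace(proto, sched, 200, 1)
        assert U[0, 99] == 0
        assert U[0, 100] == U[0, 101] == U[0, 102] == 6.0
        assert U[0, 103] == 0

    def test_zero_amplitudes_zero_trace(self):
        from refractiv.simulate import DriveProtocol, OnsetSchedule

        proto = DriveProtocol()
        sched = {k: OnsetSchedule([10]) for k in
                 ("stimulus", "excitatory", "inhibitory")}
        U = rf.drive_trace(proto, sched, 50, 2)
        assert not U.any()

    def test_overlapping_confounders_add(self):
        from refractiv.simulate import DriveProtocol, PulseSpec, OnsetSchedule

        proto = DriveProtocol(
            excitatory=PulseSpec(amplitude=2.0, duration_ms=10),
            inhibitory=PulseSpec(amplitude=-5.0, duration_ms=10),
        )
        sched = {"stimulus": OnsetSchedule([]),
                 "excitatory": OnsetSchedule([20]),
                 "inhibitory": OnsetSchedule([25])}
        U = rf.drive_trace(proto, sched, 60, 1)
        assert U[0, 22] == 2.0
        assert U[0, 27] == -3.0  # overlap region
        assert U[0, 32] == -5.0

    def test_stimulus_gain_scales_only_stimulated(self):
        from refractiv.simulate import DriveProtocol, PulseSpec, OnsetSchedule

        proto = DriveProtocol(
            stimulus=PulseSpec(amplitude=4.0, duration_ms=2),
            stimulated_ids=(0, 2),
            stimulus_gain=np.array([1.0, 1.0, 0.25]),
        )
        sched = {"stimulus": OnsetSchedule([10]),
                 "excitatory": OnsetSchedule([]),
                 "inhibitory": OnsetSchedule([])}
        U = rf.drive_trace(proto, sched, 30, 3)
        assert U[0, 11] == 4.0
        assert U[1, 11] == 0.0
        assert U[2, 11] == 1.0


class TestSimulate:
    def test_raster_is_binary_and_shaped(self, spec, rng):
        r = rf.simulate(spec, np.zeros((1, 1)), None, 5000, rng)
        assert r.spikes.shape == (1, 5000)
        assert set(np.unique(r.spikes)) <= {0, 1}

    def test_determinism_and_seed_sensitivity(self, spec):
        W = np.zeros((1, 1))
        a = rf.simulate(spec, W, None, 20_000, np.random.default_rng(5))
        b = rf.simulate(spec, W, None, 20_000, np.random.default_rng(5))
        c = rf.simulate(spec, W, None, 20_000, np.random.default_rng(6))
        assert np.array_equal(a.spikes, b.spikes)
        assert (a.spikes != c.spikes).sum() > 0

    def test_absolute_refractoriness(self, baseline_raster):
        isi = np.diff(baseline_raster.spike_times(0))
        assert isi.min() >= 4  # no spikes at lags 1-3 after a spike

    def test_baseline_rate_matches_renewal_oracle(self, baseline_raster):
        # hazard-based renewal oracle: mean ISI = sum of survival, with
        # per-lag hazards sigmoid(-b + r(lag)); beyond H the hazard is flat
        spec = rf.NetworkSpec()
        hazards = [0.0, 0.0, 0.0] + [
            1 / (1 + np.exp(-(-5 + rf.refractory_filter(l, spec))))
            for l in range(4, 11)
        ]
        p = 1 / (1 + np.exp(5.0))
        surv, mean_isi, s = 1.0, 0.0, 1.0
        for h in hazards:
            mean_isi += s
            s *= 1 - h
        mean_isi += s / p  # geometric tail at flat hazard
        expected = 1.0 / mean_isi
        n_sp = baseline_raster.spikes.sum()
        observed = n_sp / baseline_raster.n_steps
        se = np.sqrt(n_sp) / baseline_raster.n_steps
        assert abs(observed - expected) < 3 * se

    def test_strong_coupling_transmission_probability(self, rng):
        # isolated presyn spike -> postsyn spike prob one step later is
        # sigmoid(W * c(1) - b); Monte-Carlo over many events
        spec = rf.NetworkSpec(n_neurons=2)
        W = np.zeros((2, 2))
        W[1, 0] = 7.0
        r = rf.simulate(spec, W, None, 400_000, rng)
        pre = r.spike_times(0)
        # isolated: no other presyn spike within the coupling support
        iso = pre[1:-1][(np.diff(pre)[:-1] > 6) & (np.diff(pre)[1:] > 6)]
        iso = iso[iso < r.n_steps - 2]
        hits = r.spikes[1, iso + 1].mean()
        expected = 1 / (1 + np.exp(-(7 * rf.coupling_filter(1, spec) - 5)))
        se = np.sqrt(expected * (1 - expected) / iso.size)
        assert abs(hits - expected) < 4 * se

    def test_dimension_mismatch_raises(self, spec, rng):
        with pytest.raises(ValueError):
            rf.simulate(spec, np.zeros((2, 2)), None, 100, rng)
        with pytest.raises(ValueError):
            rf.simulate(rf.NetworkSpec(n_neurons=2), np.full((2, 2), np.nan),
                        None, 100, rng)

    def test_time_translation_equivariance(self):
        # shifting all drive pulses by k shifts aligned statistics by k
        from refractiv.simulate import DriveProtocol, PulseSpec, OnsetSchedule
        from refractiv.trials import WindowSpec, extract_trials

        spec = rf.NetworkSpec(n_neurons=2)
        W = np.zeros((2, 2))
        W[1, 0] = 7.0
        onsets = np.arange(100, 40_000, 50)
        k = 13
        results = []
        for shift in (0, k):
            proto = DriveProtocol(
                stimulus=PulseSpec(amplitude=6.0, duration_ms=2),
                stimulated_ids=(0,),
            )
            sched = {"stimulus": OnsetSchedule(onsets + shift),
                     "excitatory": OnsetSchedule([]),
                     "inhibitory": OnsetSchedule([])}
            U = rf.drive_trace(proto, sched, 41_000, 2)
            r = rf.simulate(spec, W, U, 41_000, np.random.default_rng(3),
                            burn_in=0)
            tt = extract_trials(r, OnsetSchedule(onsets + shift),
                                WindowSpec(), 0, 1)
            results.append((tt.X.mean(), tt.Y.mean()))
        # same seed, shifted drive: aligned hit/response rates agree closely
        assert results[0][0] == pytest.approx(results[1][0], abs=0.05)
        assert results[0][1] == pytest.approx(results[1][1], abs=0.05)


class TestSpikeRasterIO:
    def test_events_round_trip(self, tiny_raster):
        ev = tiny_raster.to_events()
        assert list(ev.columns) == ["time_ms", "neuron_id"]
        back = rf.SpikeRaster.from_events(ev, n_neurons=2, n_steps=40)
        assert np.array_equal(back.spikes, tiny_raster.spikes)

    def test_rejects_nonbinary(self):
        with pytest.raises(ValueError):
            rf.SpikeRaster(np.array([[0, 2]]))


def test_sigmoid_matches_scipy_expit():
    from scipy.special import expit

    x = np.linspace(-800, 800, 101)
    assert np.allclose(sigmoid(x), expit(x))
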