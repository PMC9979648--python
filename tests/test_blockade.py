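import numpy as np
import pytest

from peptidepore import simulate as sim
from peptidepore.blockade import (BlockadeConfig, BlockadeEvent,
                                  detect_blockades, blockade_conductance,
                                  event_frequency, bootstrap_means,
                                  subsample_bootstrap, compare_conditions)
from peptidepore.trace_io import CurrentTrace


def _event(amplitude=46.0, duration=1.3, voltage=100.0):
    return BlockadeEvent(start=0, end=int(duration * 20),
                         duration_ms=duration, amplitude_pa=amplitude,
                         blocking_conductance_ns=amplitude / voltage,
                         voltage_mv=voltage)


class TestDetection:
    def test_flat_open_trace_has_no_blockades(self):
        cfg = sim.SimulationConfig(voltage=100, duration_s=10,
                                   blockade_rate_per_s=0.0, seed=1)
        trace, _ = sim.simulate_blockades(cfg, open_level=200.0)
        assert detect_blockades(trace, 200.0) == []

    def test_single_injected_blockade_recovered(self):
        """A 1.30 ms, 45 pA blockade at 100 mV is recovered with its
        duration within 0.2 ms and blocking conductance near 0.45 nS."""
        rate = 20000.0
        x = np.full(int(2 * rate), 200.0)
        start = int(rate)
        width = int(round(1.30e-3 * rate))
        x[start:start + width] -= 45.0
        x += np.random.default_rng(0).normal(0, 1.0, x.size)
        trace = CurrentTrace(samples=x, sampling_rate=rate, voltage=100.0)
        events = detect_blockades(trace, 200.0,
                                  BlockadeConfig(threshold_pa=20.0))
        assert len(events) == 1
        assert events[0].duration_ms == pytest.approx(1.30, abs=0.2)
        assert events[0].blocking_conductance_ns == pytest.approx(0.45,
                                                                  abs=0.03)

    def test_long_event_excluded_by_translocation_filter(self):
        rate = 20000.0
        x = np.full(int(2 * rate), 200.0)
        x[20000:20000 + int(5e-3 * rate)] -= 45.0  # 5 ms event
        trace = CurrentTrace(samples=x, sampling_rate=rate, voltage=100.0)
        assert detect_blockades(trace, 200.0) == []
        unfiltered = detect_blockades(
            trace, 200.0, BlockadeConfig(max_duration_ms=None))
        assert len(unfiltered) == 1
        assert unfiltered[0].duration_ms == pytest.approx(5.0, abs=0.1)

    def test_duration_filter_is_exact_set_difference(self):
        cfg = sim.SimulationConfig(voltage=100, duration_s=60,
                                   blockade_rate_per_s=2.0,
                                   blockade_logsd=1.0, seed=6)
        trace, _ = sim.simulate_blockades(cfg, open_level=200.0)
        filtered = detect_blockades(trace, 200.0,
                                    BlockadeConfig(max_duration_ms=3.0))
        unfiltered = detect_blockades(trace, 200.0,
                                      BlockadeConfig(max_duration_ms=None))
        long_events = [e for e in unfiltered if e.duration_ms >= 3.0]
        assert {(e.start, e.end) for e in filtered} == \
            {(e.start, e.end) for e in unfiltered} \
            - {(e.start, e.end) for e in long_events}

    def test_poisson_count_within_3_sigma_over_seeds(self):
        lam_t = 100.0  # 2/s * 50 s
        for seed in range(20):
            cfg = sim.SimulationConfig(voltage=100, duration_s=50,
                                       blockade_rate_per_s=2.0, seed=seed)
            trace, truth = sim.simulate_blockades(cfg, open_level=200.0)
            events = detect_blockades(trace, 200.0,
                                      BlockadeConfig(max_duration_ms=None))
            assert abs(len(events) - lam_t) <= 3 * np.sqrt(lam_t)
            assert len(events) == len(truth.blockades)

    def test_nonpositive_open_level_raises(self):
        trace = CurrentTrace(samples=np.zeros(100), sampling_rate=100.0,
                             voltage=100.0)
        with pytest.raises(ValueError):
            detect_blockades(trace, 0.0)


class TestBlockadeConductance:
    def test_amplitude_over_voltage(self):
        assert blockade_conductance(_event(46.0)) == pytest.approx(0.46)

    def test_zero_voltage_raises(self):
        ev = _event()
        ev.voltage_mv = 0.0
        with pytest.raises(ValueError):
            blockade_conductance(ev)

    def test_simulated_depth_recovered_within_2_se(self):
        depth = 0.46
        estimates = []
        for seed in range(10):
            cfg = sim.SimulationConfig(voltage=100, duration_s=60,
                                       blockade_rate_per_s=2.0,
                                       blockade_mean_depth=depth,
                                       blockade_depth_sd=0.0, seed=seed)
            trace, _ = sim.simulate_blockades(cfg, open_level=200.0)
            events = detect_blockades(trace, 200.0,
                                      BlockadeConfig(threshold_pa=25.0,
                                                     max_duration_ms=None))
            estimates.extend(blockade_conductance(e) for e in events)
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - depth) <= 2 * se + 5e-3


class TestEventFrequency:
    def test_simple_rate(self):
        table = event_frequency([[_event()] * 10], [20.0], [100.0])
        assert table.loc[0, "mean_rate_per_s"] == pytest.approx(0.5)

    def test_identical_recordings_have_zero_se(self):
        table = event_frequency([[_event()] * 4] * 3, [8.0] * 3,
                                [100.0] * 3)
        assert table.loc[0, "se_rate_per_s"] == pytest.approx(0.0)

    def test_zero_duration_raises(self):
        with pytest.raises(ValueError):
            event_frequency([[]], [0.0], [100.0])

    def test_concatenation_equals_duration_weighted_average(self):
        """The per-recording-rate estimator: a concatenated recording's
        rate equals the duration-weighted mean of the parts' rates."""
        events_a, dur_a = [_event()] * 3, 10.0
        events_b, dur_b = [_event()] * 9, 20.0
        concat_rate = (len(events_a) + len(events_b)) / (dur_a + dur_b)
        weighted = (len(events_a) / dur_a * dur_a
                    + len(events_b) / dur_b * dur_b) / (dur_a + dur_b)
        assert concat_rate == pytest.approx(weighted)

    def test_doubling_rates_recovered_in_order(self):
        voltages = (50.0, 100.0, 150.0, 200.0)
        per_rec, durations, volts, true_rates = [], [], [], {}
        for j, v in enumerate(voltages):
            lam = 0.5 * 2 ** j
            inj = []
            for r in range(3):
                cfg = sim.SimulationConfig(voltage=v, duration_s=40,
                                           blockade_rate_per_s=lam,
                                           seed=100 * j + r)
                trace, truth = sim.simulate_blockades(cfg,
                                                      open_level=2.0 * v)
                events = detect_blockades(
                    trace, 2.0 * v,
                    BlockadeConfig(threshold_pa=None, threshold_fraction=0.1,
                                   max_duration_ms=None, debounce_samples=2))
                per_rec.append(events)
                durations.append(trace.duration_s)
                volts.append(v)
                inj.append(len(truth.blockades) / trace.duration_s)
            true_rates[v] = np.mean(inj)
        table = event_frequency(per_rec, durations, volts)
        means = table["mean_rate_per_s"].to_numpy()
        assert np.all(np.diff(means) > 0)  # increases with voltage
        for v, mean, se in zip(table["voltage_mv"], means,
                               table["se_rate_per_s"]):
            assert abs(mean - true_rates[v]) <= 2 * max(se, 1e-9) + 0.05


class TestBootstrap:
    def test_constant_values_give_constant_replicates(self):
        res = bootstrap_means([3.0] * 10, B=256, seed=1)
        assert np.all(res.replicate_means == 3.0)

    def test_seed_determinism(self):
        vals = np.arange(10.0)
        a = bootstrap_means(vals, B=512, seed=9)
        b = bootstrap_means(vals, B=512, seed=9)
        np.testing.assert_array_equal(a.replicate_means, b.replicate_means)

    @pytest.mark.parametrize("B", [2 ** 10, 2 ** 16])
    def test_bootstrap_moments_match_analytics(self, B):
        """Grand mean -> sample mean and replicate SD ->
        s*sqrt((n-1)/n)/sqrt(30) as B grows."""
        rng = np.random.default_rng(12)
        vals = rng.lognormal(0.3, 0.5, 120)
        res = bootstrap_means(vals, sample_size=30, B=B, seed=2)
        s = vals.std(ddof=1)
        n = vals.size
        assert abs(res.grand_mean - vals.mean()) <= \
            3 * (s / np.sqrt(30)) / np.sqrt(B)
        predicted_sd = s * np.sqrt((n - 1) / n) / np.sqrt(30)
        tol = 0.05 if B == 2 ** 16 else 0.15
        assert res.replicate_sd == pytest.approx(predicted_sd, rel=tol)

    def test_empty_values_raise(self):
        with pytest.raises(ValueError):
            bootstrap_means([])

    def test_subsample_full_is_a_permutation(self):
        res = bootstrap_means(np.arange(8.0), B=64, seed=3)
        sub = subsample_bootstrap(res, n=64, seed=4)
        np.testing.assert_array_equal(np.sort(sub),
                                      np.sort(res.replicate_means))

    def test_subsample_members_and_determinism(self):
        res = bootstrap_means(np.arange(50.0), B=4096, seed=5)
        sub1 = subsample_bootstrap(res, n=300, seed=6)
        sub2 = subsample_bootstrap(res, n=300, seed=6)
        np.testing.assert_array_equal(sub1, sub2)
        assert len(sub1) == 300
        assert np.isin(sub1, res.replicate_means).all()

    def test_subsample_larger_than_b_raises(self):
        res = bootstrap_means(np.arange(5.0), B=64, seed=7)
        with pytest.raises(ValueError):
            subsample_bootstrap(res, n=65)


class TestCompareConditions:
    def test_identical_inputs_give_identical_centers(self):
        events = [_event(40.0 + i, 1.0 + 0.1 * i) for i in range(10)]
        out = compare_conditions(events, events, B=1024, seed=8)
        for dim in ("blocking_conductance_ns", "duration_ms"):
            assert out["control"][dim]["center"] == pytest.approx(
                out["analyte"][dim]["center"], rel=0.01)

    def test_center_ordering_recovered(self):
        """Analyte blockades at 0.59 nS sit above controls at 0.42 nS
        after bootstrapping."""
        rng = np.random.default_rng(9)
        control = [_event(a) for a in rng.normal(42.0, 4.0, 60)]
        analyte = [_event(a) for a in rng.normal(59.0, 4.0, 60)]
        out = compare_conditions(control, analyte, B=4096, seed=10)
        c = out["control"]["blocking_conductance_ns"]["center"]
        a = out["analyte"]["blocking_conductance_ns"]["center"]
        assert a > c
        assert c == pytest.approx(0.42, abs=0.02)
        assert a == pytest.approx(0.59, abs=0.02)

    def test_deeper_injected_blockades_give_larger_centers(self):
        centers = {}
        for depth in (0.42, 0.59):
            events = []
            for seed in range(4):
                cfg = sim.SimulationConfig(voltage=100, duration_s=30,
                                           blockade_rate_per_s=2.0,
                                           blockade_mean_depth=depth,
                                           seed=40 + seed)
                trace, _ = sim.simulate_blockades(cfg, open_level=200.0)
                events.extend(detect_blockades(
                    trace, 200.0, BlockadeConfig(threshold_pa=None,
                                                 threshold_fraction=0.1,
                                                 debounce_samples=2)))
            centers[depth] = bootstrap_means(
                [e.blocking_conductance_ns for e in events],
                B=4096, seed=11).grand_mean
        assert centers[0.59] > centers[0.42]

    def test_empty_condition_raises(self):
        with pytest.raises(ValueError):
            compare_conditions([], [_event()])
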