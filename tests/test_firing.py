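"""Normalized firing score, spike detection, and dose-response summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from neurocard import (SpikeSimConfig, SpikeTrain, StimulationProtocol,
                       Trace, detect_spikes, dose_response,
                       normalized_firing_score, simulate_spike_trace)


def make_protocol(ps=0.4, span_len=100.0):
    return StimulationProtocol(windows=[(0.0, ps * span_len)],
                               span=(0.0, span_len))


class TestProtocol:
    def test_fractions_sum_to_one(self):
        p = StimulationProtocol(windows=[(5, 10), (20, 30)], span=(0, 50))
        assert p.Ps == pytest.approx(0.3)
        assert p.Ps + p.Pns == pytest.approx(1.0)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StimulationProtocol(windows=[(0, 10), (5, 15)], span=(0, 20))

    def test_window_outside_span_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            StimulationProtocol(windows=[(0, 30)], span=(0, 20))

    def test_boundary_is_closed_open(self):
        p = StimulationProtocol(windows=[(10, 20)], span=(0, 30))
        assert p.contains(10.0) and not p.contains(20.0)

    def test_complement_swaps_epochs(self):
        p = StimulationProtocol(windows=[(10, 20), (25, 30)], span=(0, 40))
        c = p.complement()
        assert c.Ps == pytest.approx(p.Pns)
        for t in np.linspace(0.0, 39.99, 200):
            assert p.contains(t) != c.contains(t)


class TestScore:
    def test_all_spikes_stimulated_gives_plus_one(self):
        p = make_protocol()
        spikes = SpikeTrain.from_times(np.linspace(1, 39, 10), p)
        res = normalized_firing_score(spikes, p)
        assert res.score == 1.0
        assert res.status == "defined"

    def test_no_spikes_stimulated_gives_minus_one(self):
        p = make_protocol()
        spikes = SpikeTrain.from_times(np.linspace(41, 99, 10), p)
        assert normalized_firing_score(spikes, p).score == -1.0

    def test_endpoints_agree_between_conventions(self):
        p = make_protocol()
        inside = SpikeTrain.from_times(np.linspace(1, 39, 10), p)
        for conv in ("rate", "product"):
            assert normalized_firing_score(inside, p, conv).score == 1.0

    def test_rate_matched_firing_scores_zero(self):
        # equal rates inside and outside the stimulated epochs
        p = make_protocol(ps=0.25, span_len=100.0)
        times = np.arange(0.5, 100.0, 1.0)  # 1 Hz everywhere
        res = normalized_firing_score(SpikeTrain.from_times(times, p), p)
        assert res.score == pytest.approx(0.0, abs=0.02)

    def test_no_spikes_is_a_status_not_a_value(self):
        res = normalized_firing_score(SpikeTrain.from_times([], None),
                                      make_protocol())
        assert res.status == "undefined_no_spikes"
        assert res.score is None

    def test_degenerate_protocol_rejected(self):
        p = StimulationProtocol(windows=[(0, 100)], span=(0, 100))
        spikes = SpikeTrain.from_times([1.0, 2.0], p)
        with pytest.raises(ValueError, match="degenerate"):
            normalized_firing_score(spikes, p)

    @given(st.integers(0, 2**31 - 1))
    def test_bounds_and_antisymmetry(self, seed):
        """score in [-1, 1]; complementing the windows negates it exactly."""
        rng = np.random.default_rng(seed)
        edges = np.sort(rng.uniform(0, 100, 6))
        windows = [(edges[0], edges[1]), (edges[2], edges[3]),
                   (edges[4], edges[5])]
        windows = [(a, b) for a, b in windows if b - a > 1e-3]
        if not windows:
            return
        p = StimulationProtocol(windows=windows, span=(0.0, 100.0))
        if p.Ps <= 0 or p.Pns <= 0:
            return
        times = np.sort(rng.uniform(0, 100, rng.integers(1, 40)))
        s = normalized_firing_score(SpikeTrain.from_times(times, p), p)
        assert -1.0 <= s.score <= 1.0
        sc = normalized_firing_score(
            SpikeTrain.from_times(times, p.complement()), p.complement())
        assert sc.score == pytest.approx(-s.score, abs=1e-12)

    def test_invariant_to_time_rescaling(self):
        p = StimulationProtocol(windows=[(10, 30)], span=(0, 100))
        times = np.array([5.0, 12.0, 40.0, 90.0])
        s1 = normalized_firing_score(SpikeTrain.from_times(times, p), p)
        k = 3.7
        p2 = StimulationProtocol(windows=[(10 * k, 30 * k)],
                                 span=(0, 100 * k))
        s2 = normalized_firing_score(
            SpikeTrain.from_times(times * k, p2), p2)
        assert s1.score == pytest.approx(s2.score, abs=1e-12)


class TestDetectSpikes:
    def test_recovers_embedded_spikes(self):
        p = make_protocol(ps=0.3, span_len=60.0)
        cfg = SpikeSimConfig(duration=60, baseline_rate=0.8,
                             neuron_ratio=0.1, trace_noise_sd=0.05,
                             seed=7)
        trace, truth = simulate_spike_trace(cfg, p)
        det = detect_spikes(trace, protocol=p)
        tol = 2.0 / trace.sample_rate
        matched = sum(np.any(np.abs(det.spike_times - t) <= tol)
                      for t in truth.spike_times)
        assert matched / max(truth.n_spikes, 1) >= 0.95
        assert det.n_spikes <= truth.n_spikes + 1

    def test_refractory_merges_close_spikes(self):
        fs = 100.0
        x = np.zeros(1000)
        x[300:305] = 1.0
        x[310:315] = 1.0  # 0.1 s later, inside the refractory gap
        tr = Trace(values=x, sample_rate=fs)
        det = detect_spikes(tr, median_window=1.0, threshold_k=5.0,
                            refractory=0.2)
        assert det.n_spikes == 1

    def test_pure_noise_yields_no_spikes_at_k8(self, rng):
        fp = 0
        for i in range(20):
            tr = Trace(values=rng.normal(0, 1, 6000), sample_rate=100.0)
            fp += detect_spikes(tr, threshold_k=8.0).n_spikes > 0
        assert fp <= 1

    def test_nonfinite_samples_rejected(self):
        x = np.zeros(100)
        x[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            detect_spikes(Trace(values=x, sample_rate=10.0))


class TestDoseResponse:
    def test_all_zero_group_gets_p_one(self):
        table = dose_response({0.0: [0.0, 0.0, 0.0]})
        assert table.rows.loc[0, "p_value"] == 1.0

    def test_mirror_symmetric_group_has_zero_median(self):
        vals = [0.3, -0.3, 0.5, -0.5, 0.1, -0.1]
        table = dose_response({0.1: vals})
        assert table.rows.loc[0, "median_score"] == 0.0

    def test_undefined_scores_flag_group(self):
        table = dose_response({0.0: [None, None], 0.2: [0.5, 0.6, 0.4]})
        assert bool(table.rows.loc[0, "flagged"])
        assert not bool(table.rows.loc[1, "flagged"])
        # smallest two-sided signed-rank p at n=3 is 0.25
        assert table.rows.loc[1, "p_value"] == pytest.approx(0.25)

    def test_groups_ordered_by_ratio(self):
        table = dose_response({0.2: [0.1], 0.0: [0.0], 0.05: [0.05]})
        assert list(table.rows["ratio"]) == [0.0, 0.05, 0.2]


class TestSpikeSimulator:
    def test_identical_seed_identical_output(self):
        p = make_protocol(span_len=30.0)
        cfg = SpikeSimConfig(duration=30, seed=5)
        t1, s1 = simulate_spike_trace(cfg, p)
        t2, s2 = simulate_spike_trace(cfg, p)
        assert np.array_equal(t1.values, t2.values)
        assert np.array_equal(s1.spike_times, s2.spike_times)

    def test_zero_baseline_rate_gives_empty_train(self):
        p = make_protocol(span_len=30.0)
        cfg = SpikeSimConfig(duration=30, baseline_rate=0.0,
                             neuron_ratio=0.2, seed=1)
        _, train = simulate_spike_trace(cfg, p)
        assert train.n_spikes == 0

    def test_refractory_gap_enforced(self):
        p = make_protocol(span_len=120.0)
        cfg = SpikeSimConfig(duration=120, baseline_rate=5.0, seed=2)
        _, train = simulate_spike_trace(cfg, p)
        if train.n_spikes > 1:
            assert np.min(np.diff(train.spike_times)) >= \
                cfg.template_duration - 1e-9

    def test_multiplier_is_monotone_with_one_at_zero(self):
        cfg = SpikeSimConfig()
        ratios = [0.0, 1e-5, 0.01, 0.05, 0.2, 1.0]
        gains = [cfg.rate_multiplier(r) for r in ratios]
        assert gains[0] == 1.0
        assert all(g2 >= g1 for g1, g2 in zip(gains, gains[1:]))

    def test_homogeneous_counts_split_by_epoch_duration(self):
        # ratio 0 -> same rate everywhere: Ns/Nns ~ Ps/Pns
        p = StimulationProtocol(
            windows=[(20 * k, 20 * k + 8) for k in range(30)],
            span=(0, 600))
        ns = nns = 0
        for seed in range(20):
            cfg = SpikeSimConfig(duration=600, baseline_rate=1.0,
                                 neuron_ratio=0.0, seed=seed)
            _, train = simulate_spike_trace(cfg, p)
            ns += train.Ns
            nns += train.Nns
        ratio = (ns / p.Ps) / (nns / p.Pns)
        assert ratio == pytest.approx(1.0, rel=0.05)
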