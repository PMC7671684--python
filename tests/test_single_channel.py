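"""All-point histogram fits, threshold idealization, dead time, Po, conductance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import capsgate as cg
from capsgate.channel import Recording
from capsgate.errors import DegenerateFitError, ParameterError
from capsgate.simulate import render_dwells
from capsgate.single_channel import (
    EventList,
    _merge_dead_time,
    aggregate_po,
)


def square_wave_recording(dwell_ms=10.0, n_cycles=10, amp=8.0,
                          sampling_hz=10_000.0):
    """Noise-free alternating closed/open square wave."""
    n_per = int(dwell_ms * sampling_hz / 1e3)
    cyc = np.concatenate([np.zeros(n_per), np.full(n_per, amp)])
    return Recording(np.tile(cyc, n_cycles), filter_hz=None,
                     sampling_hz=sampling_hz)


class TestAmplitudeHistogram:
    def test_counts_conserve_samples(self, rng):
        x = rng.normal(0, 1, 5000)
        model = cg.TwoGaussianModel(x, n_bins=64)
        assert model.histogram.counts.sum() == 5000

    @pytest.mark.parametrize("seed", range(10))
    def test_fit_recovers_generating_levels(self, seed):
        rng = np.random.default_rng(seed)
        n = 40_000
        is_open = rng.random(n) < 0.5
        x = np.where(is_open, 8.0, 0.0) + rng.normal(0, 0.5, n)
        _, fit = cg.TwoGaussianModel(x).fit()
        assert fit.closed_mean == pytest.approx(0.0, abs=0.05)
        assert fit.open_mean == pytest.approx(8.0, abs=0.05)

    def test_noiseless_two_level_amplitude_exact(self):
        rec = square_wave_recording()
        _, fit = cg.amplitude_histogram_fit(rec)
        assert fit.amplitude_pA == pytest.approx(8.0, abs=1e-9)

    def test_all_closed_trace_is_degenerate(self, rng):
        rec = Recording(rng.normal(0, 0.5, 10_000), filter_hz=None)
        with pytest.raises(DegenerateFitError):
            cg.amplitude_histogram_fit(rec)

    def test_open_weight_tracks_po(self):
        rng = np.random.default_rng(11)
        n = 60_000
        is_open = rng.random(n) < 0.3
        x = np.where(is_open, 8.0, 0.0) + rng.normal(0, 0.6, n)
        _, fit = cg.TwoGaussianModel(x).fit()
        assert fit.open_weight == pytest.approx(0.3, abs=0.02)


class TestIdealization:
    def test_square_wave_exact_boundaries(self):
        rec = square_wave_recording(dwell_ms=10.0, n_cycles=10)
        _, fit = cg.amplitude_histogram_fit(rec)
        ev = cg.idealize_events(rec, fit, dead_time_ms=0.3)
        assert ev.n_events == 20
        assert np.allclose(ev.durations_ms, 10.0)
        assert cg.open_probability(ev) == pytest.approx(0.5, abs=1e-12)

    def test_sub_dead_time_opening_removed(self):
        # one 0.2 ms opening inside a long closed stretch
        fs = 10_000.0
        trace = np.zeros(1000)
        trace[500:502] = 8.0  # 0.2 ms at 10 kHz
        rec = Recording(trace, filter_hz=None, sampling_hz=fs)
        fit = cg.LevelFit(0.0, 8.0, 0.1, 0.1, (0.5, 0.5))
        ev = cg.idealize_events(rec, fit, dead_time_ms=0.3)
        assert ev.n_events == 1
        assert ev.levels[0] == 0
        assert ev.durations_ms[0] == pytest.approx(100.0)

    def test_markov_round_trip_recovers_transitions(self, wt_model):
        # all dwells > 1 ms by construction (rates 0.2/ms, resampled),
        # sigma = 5% of amplitude
        rng = np.random.default_rng(3)
        durations = rng.exponential(5.0, size=2000) + 1.0
        levels = np.arange(2000) % 2
        dwells = cg.DwellSequence(levels, durations, durations.sum())
        trace = render_dwells(dwells, 8.0)
        trace = trace + np.random.default_rng(4).normal(0, 0.4, trace.size)
        rec = Recording(trace, filter_hz=None)
        _, fit = cg.amplitude_histogram_fit(rec)
        ev = cg.idealize_events(rec, fit, dead_time_ms=0.3)
        truth = np.concatenate([[0.0], np.cumsum(durations)])[1:-1]
        found = np.cumsum(ev.durations_ms)[:-1]
        # each true transition matched within one sample period
        dt = rec.dt_ms
        matched = sum(np.min(np.abs(found - t)) <= dt + 1e-9 for t in truth)
        assert matched / truth.size >= 0.99

    def test_noiseless_round_trip_is_exact_within_one_sample(self):
        rng = np.random.default_rng(9)
        durations = rng.exponential(4.0, size=400) + 1.0
        levels = np.arange(400) % 2
        dwells = cg.DwellSequence(levels, durations, durations.sum())
        rec = Recording(render_dwells(dwells, 8.0), filter_hz=None)
        fit = cg.LevelFit(0.0, 8.0, 0.1, 0.1, (0.5, 0.5))
        ev = cg.idealize_events(rec, fit, dead_time_ms=0.0)
        truth = np.cumsum(durations)[:-1]
        found = np.cumsum(ev.durations_ms)[:-1]
        assert found.size == truth.size
        assert np.max(np.abs(found - truth)) <= rec.dt_ms + 1e-9

    def test_po_consistent_with_histogram_weight(self, wt_model):
        _, rec = cg.simulate_single_channel(
            wt_model, open_rate_per_ms=0.1, close_rate_per_ms=0.1,
            duration_ms=60_000, noise_sd_pA=0.8, seed=21)
        _, fit = cg.amplitude_histogram_fit(rec)
        ev = cg.idealize_events(rec, fit, 0.3)
        assert cg.open_probability(ev) == pytest.approx(fit.open_weight,
                                                        abs=0.02)

    def test_huge_dead_time_rejected(self):
        rec = square_wave_recording(n_cycles=1)
        fit = cg.LevelFit(0.0, 8.0, 0.1, 0.1, (0.5, 0.5))
        with pytest.raises(ParameterError):
            cg.idealize_events(rec, fit, dead_time_ms=rec.duration_ms)


class TestDeadTimeMerging:
    def test_interior_merge_absorbs_neighbours(self):
        durs = np.array([5.0, 0.1, 5.0])
        levs = np.array([0, 1, 0], dtype=np.int8)
        d, l = _merge_dead_time(durs, levs, 0.3)
        assert np.array_equal(l, [0])
        assert d[0] == pytest.approx(10.1)

    def test_merging_is_idempotent(self):
        rng = np.random.default_rng(17)
        durs = rng.exponential(0.8, 501)
        levs = (np.arange(501) % 2).astype(np.int8)
        d1, l1 = _merge_dead_time(durs, levs, 0.3)
        d2, l2 = _merge_dead_time(d1, l1, 0.3)
        assert np.array_equal(l1, l2)
        assert np.allclose(d1, d2)
        assert d1.min() >= 0.3 or d1.size == 1

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=10_000),
           st.floats(min_value=0.05, max_value=1.0))
    def test_merging_conserves_total_time_and_alternation(self, seed, dead):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 200))
        durs = rng.exponential(0.7, n)
        levs = (np.arange(n) % 2).astype(np.int8)
        d, l = _merge_dead_time(durs, levs, dead)
        assert d.sum() == pytest.approx(durs.sum(), rel=1e-12)
        assert np.all(np.diff(l) != 0)  # strict alternation survives

    def test_shortest_first_order_is_deterministic(self):
        # two short events; merging the shorter first changes which level wins
        durs = np.array([1.0, 0.2, 0.25, 5.0])
        levs = np.array([0, 1, 0, 1], dtype=np.int8)
        d, l = _merge_dead_time(durs, levs, 0.3)
        d2, l2 = _merge_dead_time(durs.copy(), levs.copy(), 0.3)
        assert np.array_equal(d, d2) and np.array_equal(l, l2)
        assert d.sum() == pytest.approx(durs.sum())


class TestPoAndConductance:
    def test_alternating_equal_dwells(self):
        ev = EventList(np.array([0.0, 10.0]), np.array([10.0, 10.0]),
                       np.array([0, 1]), 0.3, 20.0)
        assert cg.open_probability(ev) == 0.5

    def test_all_open(self):
        ev = EventList(np.array([0.0]), np.array([50.0]), np.array([1]),
                       0.3, 50.0)
        assert cg.open_probability(ev) == 1.0

    def test_empty_rejected(self):
        ev = EventList(np.array([]), np.array([]), np.array([]), 0.3, 0.0)
        with pytest.raises(ParameterError):
            cg.open_probability(ev)

    @pytest.mark.parametrize("i,v,e,expected", [
        (8.0, 80.0, 0.0, 100.0),
        (0.0, 80.0, 0.0, 0.0),
        (7.2, 80.0, 0.0, 90.0),  # ~10% smaller shortened-analog amplitude
    ])
    def test_conductance_arithmetic(self, i, v, e, expected):
        assert cg.conductance(i, v, e) == pytest.approx(expected)

    def test_conductance_at_reversal_rejected(self):
        with pytest.raises(ParameterError):
            cg.conductance(8.0, 0.0, 0.0)

    def test_aggregate_mean_vs_pooled(self):
        po, sem = aggregate_po([0.9, 0.94, 0.92])
        assert po == pytest.approx(0.92)
        assert sem > 0
        pooled, _ = aggregate_po([(90, 100), (47, 50)], method="pooled")
        assert pooled == pytest.approx(137 / 150)


class TestEventListIO:
    def test_tsv_round_trip(self, tmp_path):
        ev = EventList(np.array([0.0, 3.0]), np.array([3.0, 2.0]),
                       np.array([0, 1]), 0.3, 5.0)
        p = tmp_path / "events.tsv"
        ev.to_tsv(p)
        back = EventList.from_tsv(p)
        assert np.allclose(back.durations_ms, ev.durations_ms)
        assert np.array_equal(back.levels, ev.levels)

    def test_summary_json_fields(self):
        ev = EventList(np.array([0.0, 3.0]), np.array([3.0, 2.0]),
                       np.array([0, 1]), 0.3, 5.0)
        import json

        d = json.loads(ev.summary_json(voltage_mV=80.0, amplitude_pA=8.0))
        assert d["g_pS"] == pytest.approx(100.0)
        assert d["Po"] == pytest.approx(0.4)
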