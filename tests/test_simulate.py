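"""Generator contracts: determinism, event statistics, channel structure."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sprstress.simulate import (SimConfig, biexp_pulse, gen_ecg,
                                gen_event_schedule, gen_recording, gen_spr_pair)


def oracle_thinned_count(rate_per_min, duration_s, min_gap_s, rng):
    """Independent brute-force simulation of Poisson arrivals + gap thinning."""
    starts = np.sort(rng.uniform(0, duration_s, rng.poisson(rate_per_min * duration_s / 60)))
    kept, last = 0, -np.inf
    for s in starts:
        if s - last >= min_gap_s:
            kept += 1
            last = s
    return kept


class TestEventSchedule:
    def test_zero_rate_gives_empty_schedule(self):
        assert gen_event_schedule(0.0, 600.0, seed=1).events == []

    def test_same_seed_reproduces_schedule(self):
        a = gen_event_schedule(3.0, 600.0, seed=42)
        b = gen_event_schedule(3.0, 600.0, seed=42)
        assert a.events == b.events

    def test_mean_count_matches_monte_carlo_oracle(self):
        """Thinned-process mean count agrees with a brute-force oracle to 3 s.e."""
        n_rep, rate, dur, gap = 2000, 3.0, 600.0, 10.0
        counts = [len(gen_event_schedule(rate, dur, gap, seed=s).events)
                  for s in range(n_rep)]
        rng = np.random.default_rng(987654)
        oracle = [oracle_thinned_count(rate, dur, gap, rng) for _ in range(n_rep)]
        se = np.std(oracle) / np.sqrt(n_rep)
        assert abs(np.mean(counts) - np.mean(oracle)) < 3 * se * np.sqrt(2)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            gen_event_schedule(-1.0, 600.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(rate=st.floats(0.0, 10.0), seed=st.integers(0, 2**31 - 1),
           gap=st.floats(1.0, 30.0))
    def test_schedule_invariants(self, rate, seed, gap):
        sched = gen_event_schedule(rate, 300.0, gap, seed=seed)
        starts = [s for s, _, _ in sched.events]
        assert starts == sorted(starts)
        assert all(b - a >= gap for a, b in zip(starts, starts[1:]))
        assert all(s >= 0 and d > 0 and s + d <= 300.0 + 1e-9
                   for s, d, _ in sched.events)


class TestSprPair:
    def test_noiseless_artifact_free_channels_identical(self):
        cfg = SimConfig(duration_s=60, noise_sd=0.0, artifact_rate_per_min=0.0, seed=5)
        sched = gen_event_schedule(3.0, 60.0, seed=5)
        left, right, clean, artifacts = gen_spr_pair(sched, cfg)
        np.testing.assert_array_equal(left, right)
        np.testing.assert_array_equal(left, clean)
        assert artifacts == []

    def test_event_response_magnitude_matches_pulse_formula(self):
        cfg = SimConfig(duration_s=120, noise_sd=0.01, artifact_rate_per_min=0.0, seed=3)
        sched = gen_event_schedule(0.0, 120.0, seed=0)
        sched = dataclasses.replace(sched, events=[(100.0, 4.0, 2.0)])
        left, right, _, _ = gen_spr_pair(sched, cfg)
        t_expect = np.arange(0, 10, 1 / cfg.fs)
        peak = biexp_pulse(t_expect, 2.0, cfg.spr_rise_tau_s, cfg.spr_decay_tau_s).max()
        fs = int(cfg.fs)
        for sig in (left, right):
            pre_max = np.abs(sig[: 100 * fs]).max()
            post_max = sig[100 * fs: 110 * fs].max()
            assert post_max > 3 * pre_max
            assert post_max == pytest.approx(peak, abs=5 * cfg.noise_sd)

    def test_each_artifact_on_exactly_one_hand_and_disjoint(self):
        cfg = SimConfig(duration_s=300, artifact_rate_per_min=4.0, seed=11)
        sched = gen_event_schedule(1.0, 300.0, seed=11)
        _, _, _, artifacts = gen_spr_pair(sched, cfg)
        assert len(artifacts) > 0
        assert all(hand in ("left", "right") for _, _, hand in artifacts)
        ordered = sorted(artifacts)
        assert all(a[1] <= b[0] for a, b in zip(ordered, ordered[1:]))

    def test_full_scale_clipping_warns(self):
        cfg = SimConfig(duration_s=60, artifact_rate_per_min=0.0, seed=1)
        sched = gen_event_schedule(0.0, 60.0, seed=0)
        sched = dataclasses.replace(sched, events=[(10.0, 4.0, 50.0)])
        with pytest.warns(UserWarning, match="clipping"):
            left, right, _, _ = gen_spr_pair(sched, cfg)
        assert np.abs(left).max() <= 10.0 and np.abs(right).max() <= 10.0


class TestEcg:
    def test_constant_rate_beat_count_and_rr(self):
        cfg = SimConfig(duration_s=60, hr_base_bpm=60, hr_event_delta_bpm=0.0, seed=2)
        sched = gen_event_schedule(0.0, 60.0, seed=0)
        _, beats = gen_ecg(sched, cfg)
        assert 59 <= len(beats) <= 61
        np.testing.assert_allclose(np.diff(beats), 1.0, atol=1e-6)

    def test_beat_count_matches_rate_integral(self):
        cfg = SimConfig(duration_s=600, hr_base_bpm=75, hr_event_delta_bpm=0.0, seed=2)
        _, beats = gen_ecg(gen_event_schedule(0.0, 600.0, seed=0), cfg)
        assert abs(len(beats) - 750) <= 1

    def test_rr_shortens_during_event(self):
        cfg = SimConfig(duration_s=120, hr_event_delta_bpm=20.0, seed=4)
        sched = gen_event_schedule(0.0, 120.0, seed=0)
        sched = dataclasses.replace(sched, events=[(60.0, 10.0, 2.0)])
        _, beats = gen_ecg(sched, cfg)
        rr = np.diff(beats)
        mids = (beats[:-1] + beats[1:]) / 2
        during = rr[(mids >= 62) & (mids < 70)]
        before = rr[(mids >= 40) & (mids < 48)]
        assert during.mean() < before.mean()


class TestRecording:
    def test_traffic_has_more_events_than_no_traffic(self, short_cfg):
        t = gen_recording(short_cfg, "traffic")
        n = gen_recording(short_cfg, "no_traffic")
        assert len(t.events.events) > len(n.events.events)

    def test_array_lengths_and_sections(self, traffic_recording, short_cfg):
        n = round(short_cfg.fs * short_cfg.duration_s)
        for name in ("t", "spr_left", "spr_right", "ecg"):
            assert len(getattr(traffic_recording, name)) == n
        tags = [tag for _, _, tag in traffic_recording.sections]
        assert tags == ["highway", "city"]

    def test_same_seed_identical_recording(self, short_cfg):
        a = gen_recording(short_cfg, "traffic")
        b = gen_recording(short_cfg, "traffic")
        np.testing.assert_array_equal(a.spr_left, b.spr_left)
        np.testing.assert_array_equal(a.ecg, b.ecg)
        assert a.events.events == b.events.events
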