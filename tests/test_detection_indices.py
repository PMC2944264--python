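import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vfseq import (Episode, SiftConfig, SynthSpec, WindowPlan, mav, mav_a,
                   nmav, nmav_a, normalize_segment, preprocess_stage1,
                   preprocess_stage2, synth)
from vfseq.detection_indices import DegenerateSegmentError


class TestMav:
    def test_constant_one(self):
        assert mav(np.ones(100)) == 1.0

    def test_alternating(self):
        x = np.tile([1.0, -1.0], 50)
        assert mav(x) == 1.0

    def test_unit_sinusoid_two_over_pi(self):
        # mean |sin| over whole periods = 2/pi (dense-summation oracle)
        t = np.linspace(0, 4, 100000, endpoint=False)
        assert mav(np.sin(2 * np.pi * t)) == pytest.approx(2 / np.pi, abs=1e-3)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mav(np.array([]))


class TestNormalizeSegment:
    def test_example(self):
        np.testing.assert_allclose(normalize_segment([2.0, -4.0]), [0.5, -1.0])

    def test_already_normalized_unchanged(self):
        x = np.array([0.5, -1.0, 0.25])
        np.testing.assert_array_equal(normalize_segment(x), x)

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateSegmentError):
            normalize_segment(np.zeros(10))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_mav_of_normalized_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(50) * rng.uniform(1e-3, 1e3)
        v = mav(normalize_segment(x))
        assert 0 < v <= 1


class TestMavA:
    def test_window_count(self, sine_episode):
        res = mav_a(sine_episode)
        assert len(res.per_window) == sine_episode.le - 1 == 7

    def test_identical_windows_aggregate_equals_window(self, fs):
        # periodic in 1 s -> every 2-s window is identical
        t = np.arange(int(8 * fs)) / fs
        ep = Episode(samples=np.sin(2 * np.pi * 5 * t), fs=fs, le=8)
        res = mav_a(ep, preprocess=False)
        assert res.aggregate == pytest.approx(res.per_window[0], rel=1e-9)

    def test_le2_single_window(self, fs):
        t = np.arange(int(2 * fs)) / fs
        ep = Episode(samples=np.sin(2 * np.pi * 5 * t), fs=fs, le=2)
        res = mav_a(ep, preprocess=False)
        assert len(res.per_window) == 1
        assert res.aggregate == res.per_window[0]

    def test_fixture_separation(self, vf_episode, nsr_episode):
        assert mav_a(vf_episode[0]).aggregate > 0.27
        assert mav_a(nsr_episode[0]).aggregate < 0.27

    def test_degenerate_windows_skipped(self, fs):
        x = np.zeros(int(8 * fs))
        x[: int(2 * fs)] = np.sin(2 * np.pi * 5 * np.arange(int(2 * fs)) / fs)
        ep = Episode(samples=x, fs=fs, le=8)
        res = mav_a(ep, preprocess=False)
        # windows starting at 0s and 1s overlap the sine; the other 5 are zero
        assert res.skipped_windows == 5
        assert res.aggregate == pytest.approx(np.mean(res.per_window))

    def test_all_degenerate_unclassifiable(self, fs):
        ep = Episode(samples=np.zeros(int(8 * fs)), fs=fs, le=8)
        res = mav_a(ep, preprocess=False)
        assert res.aggregate is None and res.skipped_windows == 7

    @pytest.mark.parametrize("scale", [1e-3, 0.1, 10.0, 1e3])
    def test_scale_invariance(self, vf_episode, scale):
        ep, _ = vf_episode
        scaled = Episode(samples=ep.samples * scale, fs=ep.fs, le=ep.le)
        assert mav_a(scaled).aggregate == pytest.approx(
            mav_a(ep).aggregate, rel=1e-9)


class TestNmav:
    def test_pure_sinusoid_small(self, fs):
        t = np.arange(int(2 * fs)) / fs
        x = np.sin(2 * np.pi * 5 * t)
        assert nmav(x) < 0.05

    def test_monotone_ramp_is_one(self):
        x = np.linspace(-1, 1, 500)
        assert nmav(x) == pytest.approx(1.0)

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateSegmentError):
            nmav(np.zeros(500))

    def test_vf_below_vt(self):
        """The EMD residual is far smaller for VF-like than VT-like windows."""
        wins, losses = 0, 0
        for seed in range(12):
            vf_ep, _ = synth(SynthSpec(kind="vf", seed=seed))
            vt_ep, _ = synth(SynthSpec(kind="vt", seed=seed, rate=180.0))
            w_vf = preprocess_stage2(vf_ep.samples[:500], vf_ep.fs)
            w_vt = preprocess_stage2(vt_ep.samples[:500], vt_ep.fs)
            if nmav(w_vf) < nmav(w_vt):
                wins += 1
            else:
                losses += 1
        assert wins >= 11


class TestNmavA:
    def test_window_count_and_passthrough(self, fs):
        t = np.arange(int(2 * fs)) / fs
        ep = Episode(samples=np.sin(2 * np.pi * 5 * t), fs=fs, le=2)
        res = nmav_a(ep)
        assert len(res.per_window) == 1
        assert res.aggregate == res.per_window[0]

    def test_stationary_tone_windows_agree(self, sine_episode):
        # a strictly stationary VF-band tone: every window's NMAV sits
        # within 10% (absolute floor 0.01) of the aggregate
        res = nmav_a(sine_episode)
        assert len(res.per_window) == 7
        for v in res.per_window:
            assert abs(v - res.aggregate) <= max(0.1 * res.aggregate, 0.01)

    @pytest.mark.parametrize("scale", [1e-3, 1e3])
    def test_scale_invariance(self, vf_episode, scale):
        ep, _ = vf_episode
        scaled = Episode(samples=ep.samples * scale, fs=ep.fs, le=ep.le)
        assert nmav_a(scaled).aggregate == pytest.approx(
            nmav_a(ep).aggregate, rel=1e-6)


def damped_vf(seed: int, fs: float = 250.0):
    """8-s 5 Hz quasi-sinusoid whose amplitude drops 4x mid-episode."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(8 * fs)) / fs
    f = 5.0 + 0.5 * np.sin(2 * np.pi * 0.2 * t + rng.uniform(0, 2 * np.pi))
    phase = 2 * np.pi * np.cumsum(f) / fs
    amp = np.where(t < 4.0, 1.0, 0.25)
    x = amp * np.sin(phase) + 0.01 * rng.standard_normal(t.size)
    return Episode(samples=x, fs=fs, le=8)


def test_windowed_mav_beats_whole_frame_on_damped_signal(fs):
    """Per-window renormalisation rescues damped stretches: the windowed
    aggregate exceeds the whole-frame MAV of the same episode."""
    for seed in range(20):
        ep = damped_vf(seed)
        filtered = preprocess_stage1(ep.samples, ep.fs)
        whole = mav(normalize_segment(filtered))
        windowed = mav_a(ep).aggregate
        assert windowed > whole
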