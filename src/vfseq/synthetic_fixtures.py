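"""Seeded ECG-like waveform generators with programmed ground truth.

These fixtures exist so every stage of the detector can be exercised
without database downloads. Each kind emulates the morphological property
the detector exploits, not full electrophysiology:

* ``nsr`` — trains of narrow (60-100 ms) biphasic QRS complexes with small
  P and T bumps and a quiet baseline: low duty cycle, hence low MAV.
* ``vt`` — wide (>= 140 ms) monophasic, asymmetric complexes that rarely
  cross the baseline: high MAV, and envelope asymmetry that leaves a large
  EMD residual (high NMAV).
* ``vf`` — a narrowband 4-7 Hz quasi-sinusoid with slowly drifting
  amplitude and frequency, symmetric about baseline: high MAV and, being
  close to an intrinsic mode itself, a tiny EMD residual (low NMAV).
* ``pulse_train`` — bare Gaussian pulses for exercising the rate
  estimator.

Powerline, baseline-wander and white noise are added per spec. All
randomness flows from a single explicit seed; identical spec gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .records_io import Episode
from .sequential_classifier import RhythmLabel

__all__ = ["SynthSpec", "SynthTruth", "NoiseSpec", "synth", "standard_cohort"]

KINDS = ("nsr", "vt", "vf", "pulse_train")


@dataclass
class NoiseSpec:
    """Additive noise amplitudes in microvolts (peak for the deterministic
    components, standard deviation for white noise)."""

    powerline_uv: float = 10.0
    wander_uv: float = 25.0
    white_uv: float = 5.0
    powerline_hz: float = 60.0


@dataclass
class SynthSpec:
    """Recipe for one synthetic episode.

    ``peak_amplitude_uv`` is the exact final peak |amplitude| of the
    composite signal (the waveform is rescaled after noise is added, so
    the programmed peak is recovered by the amplitude stage exactly).
    The generator emits samples calibrated at 1 record unit per uV.
    """

    kind: str = "vf"
    fs: float = 250.0
    duration: float = 8.0
    rate: float = 160.0           # bpm; used by nsr/vt/pulse_train
    vf_band: tuple = (4.0, 7.0)   # Hz
    peak_amplitude_uv: float = 1000.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {KINDS}")
        if self.fs < 125:
            raise ValueError("fs must be >= 125 samples/s")
        if self.duration < 2:
            raise ValueError("duration must be >= 2 s")
        if self.kind in ("nsr", "vt", "pulse_train") and not (20 <= self.rate <= 300):
            raise ValueError(f"rate {self.rate} bpm outside plausible range")


@dataclass
class SynthTruth:
    label: Optional[RhythmLabel]
    beat_count: int
    rate_bpm: Optional[float]
    peak_amplitude_uv: float


def _gauss(t, center, sigma, amp):
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _beat_times(duration: float, rate: float):
    """Regularly spaced beat centers that fit wholly inside the episode."""
    period = 60.0 / rate
    t0 = period / 2.0
    margin = min(0.15, period / 4.0)
    times = np.arange(t0, duration, period)
    times = times[(times >= margin) & (times <= duration - margin)]
    return times, period


def _nsr_wave(t, rng, rate):
    times, period = _beat_times(t[-1] + (t[1] - t[0]), rate)
    x = np.zeros_like(t)
    for tc in times:
        jit = rng.normal(0.0, 0.004)
        x += _gauss(t, tc + jit, 0.012, 1.0)           # R
        x += _gauss(t, tc + jit + 0.030, 0.010, -0.22)  # S
        x += _gauss(t, tc + jit - 0.028, 0.011, -0.10)  # Q
        x += _gauss(t, tc + jit - 0.160, 0.025, 0.10)   # P
        x += _gauss(t, tc + jit + min(0.30, 0.45 * period), 0.050, 0.18)  # T
    return x, len(times)


def _vt_wave(t, rng, rate):
    """Wide asymmetric complexes: a steep depolarisation spike riding on a
    flat-topped plateau. The plateau keeps the signal off baseline (high
    MAV, asymmetric envelopes) while the spike spreads energy across many
    harmonics, so the first two IMFs capture little of the waveform."""
    times, period = _beat_times(t[-1] + (t[1] - t[0]), rate)
    x = np.zeros_like(t)
    width = max(0.15, 0.5 * period)  # complex width >= 140 ms
    for tc in times:
        jit = rng.normal(0.0, 0.003)
        plateau = np.clip(1.0 - (np.abs(t - tc - jit) / (width / 2)) ** 8, 0, 1)
        x += 0.7 * plateau
        x += _gauss(t, tc + jit - 0.3 * width, 0.012, 1.0)
    return x, len(times)


def _vf_wave(t, rng, band):
    f_lo, f_hi = band
    # smooth random frequency drift inside the band
    n_ctrl = 6
    ctrl = rng.uniform(f_lo, f_hi, n_ctrl)
    freq = np.interp(t, np.linspace(t[0], t[-1], n_ctrl), ctrl)
    phase = 2.0 * np.pi * np.cumsum(freq) * (t[1] - t[0])
    phase += rng.uniform(0.0, 2.0 * np.pi)
    am_f = rng.uniform(0.15, 0.4)
    am_ph = rng.uniform(0.0, 2.0 * np.pi)
    amp = 0.75 + 0.25 * np.sin(2.0 * np.pi * am_f * t + am_ph)
    return amp * np.sin(phase), 0


def _pulse_train(t, rng, rate):
    times, _ = _beat_times(t[-1] + (t[1] - t[0]), rate)
    x = np.zeros_like(t)
    for tc in times:
        x += _gauss(t, tc, 0.080 / 2.355, 1.0)  # 80 ms FWHM Gaussian
    return x, len(times)


def synth(spec: SynthSpec) -> tuple[Episode, SynthTruth]:
    """Generate one synthetic episode plus its programmed ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs

    if spec.kind == "nsr":
        clean, beats = _nsr_wave(t, rng, spec.rate)
        label = RhythmLabel.NON_VTVF
        rate = spec.rate
    elif spec.kind == "vt":
        clean, beats = _vt_wave(t, rng, spec.rate)
        # the label follows the achieved (discretised) episode rate: beat
        # placement quantises the nominal rate to beats*60/duration
        achieved = beats * 60.0 / spec.duration
        label = (RhythmLabel.VT_HI if achieved > 180.0 else RhythmLabel.VT_LO)
        rate = spec.rate
    elif spec.kind == "vf":
        clean, beats = _vf_wave(t, rng, spec.vf_band)
        label = (RhythmLabel.COARSE_VF if spec.peak_amplitude_uv > 200.0
                 else RhythmLabel.FINE_VF)
        rate = None
    else:  # pulse_train
        clean, beats = _pulse_train(t, rng, spec.rate)
        label = None
        rate = spec.rate

    peak = float(np.max(np.abs(clean)))
    x = clean / peak * spec.peak_amplitude_uv if peak > 0 else clean

    ns = spec.noise
    x = x + ns.powerline_uv * np.sin(2.0 * np.pi * ns.powerline_hz * t
                                     + rng.uniform(0, 2 * np.pi))
    x = x + ns.wander_uv * np.sin(2.0 * np.pi * rng.uniform(0.15, 0.4) * t
                                  + rng.uniform(0, 2 * np.pi))
    x = x + ns.white_uv * rng.standard_normal(n)

    # rescale the composite so the programmed peak is exact
    peak = float(np.max(np.abs(x)))
    if peak > 0:
        x = x * (spec.peak_amplitude_uv / peak)

    episode = Episode(samples=x, fs=spec.fs, le=int(round(spec.duration)),
                      start_time=0.0, truth_label=label, gain=1.0)
    truth = SynthTruth(label=label, beat_count=beats, rate_bpm=rate,
                       peak_amplitude_uv=spec.peak_amplitude_uv)
    return episode, truth


def standard_cohort(n_per_class: int = 200, seed: int = 0):
    """The reference synthetic cohort: equal thirds of NSR-like episodes at
    60-100 bpm, VT-like episodes at 150-220 bpm, and coarse-VF-like
    episodes at 250-600 uV peak amplitude, all at the default noise levels
    (SNR >= 20 dB). Returns a list of (Episode, SynthTruth).

    One decision per episode; per-episode seeds are derived from ``seed``
    so the cohort is fully reproducible.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_per_class):
        s = int(rng.integers(0, 2**31 - 1))
        cohort.append(synth(SynthSpec(kind="nsr", seed=s,
                                      rate=float(rng.uniform(60, 100)))))
    for i in range(n_per_class):
        s = int(rng.integers(0, 2**31 - 1))
        cohort.append(synth(SynthSpec(kind="vt", seed=s,
                                      rate=float(rng.uniform(150, 220)))))
    for i in range(n_per_class):
        s = int(rng.integers(0, 2**31 - 1))
        cohort.append(synth(SynthSpec(
            kind="vf", seed=s,
            peak_amplitude_uv=float(rng.uniform(250, 600)))))
    return cohort
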