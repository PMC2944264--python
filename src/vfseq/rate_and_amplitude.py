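"""Stage 3: derivative-based heart-rate estimation and VF amplitude.

The rate estimator exploits the steep slope of the QRS complex: the first
difference of the preprocessed episode is half-wave rectified, smoothed by
a short moving sum (alpha = fs/10 samples), and peaks are picked greedily —
take the global maximum C, fix the threshold T_h = beta * C, record the
peak, zero out gamma = fs/8 samples on both sides, and repeat until the
remaining maximum drops below T_h. The count N_p over an L_e-second episode
gives HR = N_p * 60 / L_e bpm.

VF amplitude is the peak absolute value of the *calibrated raw* episode in
microvolts (the coarse/fine VF border of 200 uV is a physical amplitude,
so it is measured before any normalisation or filtering).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .preprocessing import FilterChainConfig, preprocess_stage1

__all__ = ["RateConfig", "RateResult", "CalibrationRequiredError",
           "heart_rate", "vf_amplitude"]


class CalibrationRequiredError(ValueError):
    """Amplitude in microvolts requires a known gain."""


@dataclass
class RateConfig:
    """Peak-picker parameters.

    beta scales the fixed detection threshold; alpha_divisor and
    gamma_divisor set the smoothing length (fs/10) and the masking
    half-width (fs/8); the VT rate border defaults to 180 bpm (the strict
    AHA shockable border; clinically it may sit anywhere in 150-180) and
    the coarse-VF amplitude border to 200 uV.
    """

    beta: float = 0.25
    alpha_divisor: float = 10.0
    gamma_divisor: float = 8.0
    vt_rate_border: float = 180.0
    vf_amp_border: float = 200.0

    def __post_init__(self):
        if not (0 < self.beta < 1):
            raise ValueError("beta must lie in (0, 1)")
        if self.vt_rate_border <= 0 or self.vf_amp_border <= 0:
            raise ValueError("borders must be positive")


@dataclass
class RateResult:
    np_peaks: int
    hr: float
    peak_indices: list
    threshold: float
    c_max: float
    i_max: int
    degenerate: bool = False


def _first_difference(x: np.ndarray) -> np.ndarray:
    # x_d(0) uses x(-1) = x(0), so the first difference is zero there
    xd = np.empty_like(x)
    xd[0] = 0.0
    xd[1:] = x[1:] - x[:-1]
    return xd


def _moving_sum_causal(x: np.ndarray, alpha: int) -> np.ndarray:
    """sum_{k=0..alpha} x(n-k), out-of-range terms zero."""
    kernel = np.ones(alpha + 1)
    return np.convolve(x, kernel)[: x.size]


def heart_rate(
    episode,
    cfg: RateConfig | None = None,
    filter_cfg: FilterChainConfig | None = None,
    preprocess: bool = True,
) -> RateResult:
    """Count QRS-like peaks and convert to beats per minute.

    The threshold is fixed at beta times the *first* global maximum and is
    never recomputed; the first peak therefore always counts. Masking
    windows are clipped at the array boundaries.
    """
    if cfg is None:
        cfg = RateConfig()
    x = np.asarray(episode.samples, dtype=float)
    if preprocess:
        x = preprocess_stage1(x, episode.fs, filter_cfg)
    xd = _first_difference(x)
    xdp = np.where(xd >= 0, xd, 0.0)
    alpha = max(int(round(episode.fs / cfg.alpha_divisor)), 1)
    gamma = max(int(round(episode.fs / cfg.gamma_divisor)), 1)
    xdpf = _moving_sum_causal(xdp, alpha)

    i0 = int(np.argmax(xdpf))
    c0 = float(xdpf[i0])
    if c0 <= 0.0:
        return RateResult(np_peaks=0, hr=0.0, peak_indices=[], threshold=0.0,
                          c_max=0.0, i_max=i0, degenerate=True)
    th = cfg.beta * c0
    work = xdpf.copy()
    peaks = []
    c, i = c0, i0
    while c >= th:
        peaks.append(i)
        lo = max(i - gamma, 0)
        hi = min(i + gamma, work.size - 1)
        work[lo : hi + 1] = 0.0
        i = int(np.argmax(work))
        c = float(work[i])
    hr = len(peaks) * 60.0 / episode.le
    return RateResult(np_peaks=len(peaks), hr=hr, peak_indices=sorted(peaks),
                      threshold=th, c_max=c0, i_max=i0)


def vf_amplitude(episode_raw, gain: Optional[float] = None) -> float:
    """Peak absolute amplitude of the raw episode, in microvolts.

    ``gain`` is record units per microvolt; falls back to the episode's
    own calibration when present.
    """
    if gain is None:
        gain = getattr(episode_raw, "gain", None)
    if gain is None or gain <= 0:
        raise CalibrationRequiredError(
            "amplitude in uV requires a positive gain (record units per uV)"
        )
    x = np.asarray(episode_raw.samples, dtype=float)
    return float(np.max(np.abs(x))) / gain if x.size else 0.0
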