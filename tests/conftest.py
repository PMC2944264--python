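import numpy as np
import pytest

from vfseq import Episode, SynthSpec, synth


@pytest.fixture
def fs():
    return 250.0


@pytest.fixture
def sine_episode(fs):
    """8-s pure 5 Hz unit sinusoid episode (canonical VF-band tone)."""
    t = np.arange(int(8 * fs)) / fs
    return Episode(samples=np.sin(2 * np.pi * 5 * t), fs=fs, le=8, gain=1.0)


@pytest.fixture
def vf_episode():
    ep, truth = synth(SynthSpec(kind="vf", seed=11, peak_amplitude_uv=300.0))
    return ep, truth


@pytest.fixture
def vt_episode():
    ep, truth = synth(SynthSpec(kind="vt", seed=11, rate=200.0))
    return ep, truth


@pytest.fixture
def nsr_episode():
    ep, truth = synth(SynthSpec(kind="nsr", seed=11, rate=75.0))
    return ep, truth


def bandlimited_noise(seed: int, n: int = 500, fs: float = 250.0) -> np.ndarray:
    """Seeded band-limited noise: a handful of random tones plus smoothed
    white noise — the generic EMD stress input used by the sweeps."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    x = np.zeros(n)
    for _ in range(rng.integers(2, 6)):
        f = rng.uniform(1.0, 25.0)
        x += rng.uniform(0.2, 1.0) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    w = rng.standard_normal(n)
    kernel = np.ones(5) / 5.0
    x += 0.2 * np.convolve(w, kernel, mode="same")
    return x
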