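"""Empirical Mode Decomposition with cubic-spline envelopes and SD sifting.

EMD decomposes a signal x(n) into a small set of intrinsic mode functions
(IMFs) plus a residue,

    x(n) = sum_i c_i(n) + r_q(n),

where each IMF is an oscillation whose extrema and zero-crossing counts
differ by at most one and whose local envelope mean is (near) zero. IMFs
are extracted by *sifting*: the upper and lower envelopes are cubic splines
through the local maxima and minima, and their mean m(n) = (e_u + e_l)/2 is
subtracted repeatedly,

    h_k(n) = h_{k-1}(n) - m_k(n),

until the candidate satisfies the IMF conditions and the normalised change
between consecutive sifts,

    SD = sum_n |h_{k-1}(n) - h_k(n)|^2 / h_{k-1}(n)^2,

falls below a threshold (0.2 by convention; samples with h_{k-1}(n) = 0 are
excluded from the sum). Each accepted IMF is subtracted from the running
residue and extraction repeats until the residue is monotonic, negligibly
small, or the configured IMF budget is exhausted.

Boundary handling mirrors the two extrema nearest each end of the signal
before spline fitting, which suppresses envelope swings at the edges. The
decomposition is deterministic: identical input and config give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["SiftConfig", "ImfSet", "find_extrema", "envelopes", "sift_once",
           "emd", "is_imf", "InsufficientExtremaError"]


class InsufficientExtremaError(ValueError):
    """Raised when a signal has too few extrema to build spline envelopes
    (a monotone or trivial residue)."""


@dataclass
class SiftConfig:
    """Sifting and termination parameters.

    ``sd_threshold`` follows the 0.2 convention of the original EMD
    literature. ``max_imfs=None`` decomposes fully; the VF/VT detector
    passes ``max_imfs=2`` since only imf1 + imf2 are consumed.
    """

    sd_threshold: float = 0.2
    max_sifts_per_imf: int = 100
    max_imfs: int | None = None
    boundary_policy: str = "mirror"
    residue_monotone_stop: bool = True

    def __post_init__(self):
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be positive")
        if self.max_sifts_per_imf < 1:
            raise ValueError("max_sifts_per_imf must be >= 1")
        if self.boundary_policy != "mirror":
            raise ValueError(f"unknown boundary policy {self.boundary_policy!r}")


@dataclass
class ImfSet:
    """Ordered IMFs plus residue; satisfies x = sum(imfs) + residue."""

    imfs: list = field(default_factory=list)
    residue: np.ndarray = None
    sift_counts: list = field(default_factory=list)
    source_length: int = 0

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for c in self.imfs:
            out += c
        return out

    def imf_sum(self, k: int) -> np.ndarray:
        """Sum of the first k IMFs (missing IMFs count as zero)."""
        out = np.zeros(self.source_length)
        for c in self.imfs[:k]:
            out += c
        return out


def find_extrema(x) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior local maxima and minima.

    Plateaus count once, at their first sample: a run of equal values is a
    maximum (minimum) if the nearest differing neighbours on both sides are
    lower (higher). Endpoints are never extrema.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    diff = np.diff(x)
    # direction of the last nonzero step before each position
    maxima, minima = [], []
    prev_dir = 0  # -1 falling, +1 rising
    plateau_start = None
    for i in range(1, n):
        d = diff[i - 1]
        if d > 0:
            if prev_dir == -1 and plateau_start is not None:
                minima.append(plateau_start)
            prev_dir = 1
            plateau_start = i
        elif d < 0:
            if prev_dir == 1 and plateau_start is not None:
                maxima.append(plateau_start)
            prev_dir = -1
            plateau_start = i
        # d == 0: plateau continues; keep its first sample
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def _mirror_knots(idx: np.ndarray, vals: np.ndarray, n: int):
    """Mirror the two extrema nearest each end about the signal endpoints."""
    left_i = (-idx[:2][::-1]).astype(float)          # reflect about t=0
    left_v = vals[:2][::-1]
    right_i = (2 * (n - 1) - idx[-2:][::-1]).astype(float)  # about t=n-1
    right_v = vals[-2:][::-1]
    xi = np.concatenate([left_i, idx.astype(float), right_i])
    yi = np.concatenate([left_v, vals, right_v])
    # guard against duplicate abscissae (extremum exactly at an endpoint)
    keep = np.concatenate([[True], np.diff(xi) > 0])
    return xi[keep], yi[keep]


def envelopes(x, maxima=None, minima=None, policy: str = "mirror"):
    """Upper and lower cubic-spline envelopes e_u(n), e_l(n).

    Knots are the local extrema extended by mirroring; the spline passes
    exactly through every interior extremum. Raises
    :class:`InsufficientExtremaError` when fewer than two maxima or two
    minima exist (monotone/trivial residue condition).
    """
    x = np.asarray(x, dtype=float)
    if maxima is None or minima is None:
        maxima, minima = find_extrema(x)
    if len(maxima) < 2 or len(minima) < 2:
        raise InsufficientExtremaError(
            f"need >= 2 maxima and >= 2 minima, got {len(maxima)}/{len(minima)}"
        )
    n = x.size
    t = np.arange(n, dtype=float)
    xi_u, yi_u = _mirror_knots(maxima, x[maxima], n)
    xi_l, yi_l = _mirror_knots(minima, x[minima], n)
    e_u = CubicSpline(xi_u, yi_u)(t)
    e_l = CubicSpline(xi_l, yi_l)(t)
    return e_u, e_l


def sift_once(h):
    """One sifting pass: subtract the envelope mean.

    Returns ``(h_next, sd)`` where ``h_next = h - (e_u + e_l)/2`` and ``sd``
    is the normalised squared change between the two sifts (zero-amplitude
    samples of the previous iterate are excluded from the sum).
    """
    h = np.asarray(h, dtype=float)
    e_u, e_l = envelopes(h)
    m = 0.5 * (e_u + e_l)
    h_next = h - m
    # Zero-denominator guard: samples whose amplitude is negligible at the
    # iterate's working scale (< 1% of peak) are excluded from the sum.
    # The per-sample ratio is heavy-tailed near zero crossings — without a
    # relative guard the statistic never settles on broadband signals.
    scale = float(np.max(np.abs(h)))
    if scale == 0.0:
        return h_next, 0.0
    nz = np.abs(h) > 1e-2 * scale
    sd = float(np.sum((h[nz] - h_next[nz]) ** 2 / h[nz] ** 2))
    return h_next, sd


def zero_crossings(x) -> int:
    """Count zero crossings: sign changes between consecutive nonzero
    samples; a run of exact zeros counts once."""
    x = np.asarray(x, dtype=float)
    count = 0
    last_sign = 0
    in_zero_run = False
    for v in x:
        if v == 0.0:
            if not in_zero_run:
                count += 1
                in_zero_run = True
            continue
        s = 1 if v > 0 else -1
        if in_zero_run:
            in_zero_run = False
            last_sign = s  # transition already counted by the zero run
        elif last_sign != 0 and s != last_sign:
            count += 1
            last_sign = s
        else:
            last_sign = s
    return count


def is_imf(x, mean_tol: float = 0.05) -> bool:
    """Check the two IMF conditions.

    (1) the numbers of extrema and zero crossings differ by at most one;
    (2) the mean of the envelope midline (e_u + e_l)/2 is small:
    |mean| < ``mean_tol`` x RMS(x).
    """
    x = np.asarray(x, dtype=float)
    maxima, minima = find_extrema(x)
    n_ext = len(maxima) + len(minima)
    if abs(n_ext - zero_crossings(x)) > 1:
        return False
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0.0:
        return True
    try:
        e_u, e_l = envelopes(x, maxima, minima)
    except InsufficientExtremaError:
        # too few extrema to build envelopes (near-monotone slow mode):
        # the envelope-mean condition is vacuous, the count condition rules
        return True
    return abs(float(np.mean(0.5 * (e_u + e_l)))) < mean_tol * rms


def _extrema_zc_ok(h) -> bool:
    maxima, minima = find_extrema(h)
    return abs(len(maxima) + len(minima) - zero_crossings(h)) <= 1


def emd(x, cfg: SiftConfig | None = None) -> ImfSet:
    """Decompose ``x`` into IMFs plus a residue.

    Extraction of each IMF sifts until the SD criterion is met *and* the
    extrema/zero-crossing condition holds (or the per-IMF sift cap is
    reached). Decomposition stops at ``max_imfs``, when the residue is
    monotone (too few extrema to sift), or when the residue is negligible
    relative to the input.
    """
    if cfg is None:
        cfg = SiftConfig()
    x = np.asarray(x, dtype=float)
    n = x.size
    result = ImfSet(imfs=[], residue=x.copy(), sift_counts=[], source_length=n)
    if n < 3:
        return result
    scale = float(np.max(np.abs(x))) if n else 0.0
    if scale == 0.0:
        return result
    residue = x.copy()
    while cfg.max_imfs is None or len(result.imfs) < cfg.max_imfs:
        if float(np.max(np.abs(residue))) < 1e-10 * scale:
            break
        maxima, minima = find_extrema(residue)
        if len(maxima) < 2 or len(minima) < 2:
            break  # monotone residue: decomposition complete
        h = residue.copy()
        sifts = 0
        h_last_ok = None  # most recent iterate meeting the count condition
        sifts_last_ok = 0
        while sifts < cfg.max_sifts_per_imf:
            try:
                h_next, sd = sift_once(h)
            except InsufficientExtremaError:
                break
            sifts += 1
            h = h_next
            count_ok = _extrema_zc_ok(h)
            if count_ok:
                h_last_ok = h
                sifts_last_ok = sifts
            if sd < cfg.sd_threshold and count_ok:
                break
        if sifts == 0:
            break
        if not _extrema_zc_ok(h) and h_last_ok is not None:
            # sift cap hit after over-sifting eroded the extrema balance:
            # fall back to the last iterate that satisfied the IMF count
            h, sifts = h_last_ok, sifts_last_ok
        result.imfs.append(h)
        result.sift_counts.append(sifts)
        residue = residue - h
    result.residue = residue
    return result
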