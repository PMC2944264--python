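"""Three-stage sequential rhythm classification and the binary schemes.

Stage 1: MAV_a > MAV_d routes the episode into the VTVF branch, otherwise
it is a non-VTVF rhythm. Stage 2 (VTVF branch only): NMAV_a < NMAV_d calls
VF, otherwise VT. Stage 3 splits VT by heart rate (> 180 bpm is shockable
"VT-hi") and VF by peak amplitude (> 200 uV is shockable "coarse VF").
All inequalities are strict, so an episode landing exactly on a threshold
takes the negative branch.

The fine-grained labels collapse into three binary identification schemes:
VTVF vs the rest, VF vs the rest, and shockable (coarse VF + VT-hi) vs the
rest — the views under which detector quality is scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .detection_indices import IndexResult, WindowPlan, mav_a, nmav_a
from .emd_core import SiftConfig
from .preprocessing import FilterChainConfig
from .rate_and_amplitude import (CalibrationRequiredError, RateConfig,
                                 RateResult, heart_rate, vf_amplitude)

__all__ = ["Thresholds", "RhythmLabel", "ClassificationResult",
           "classify_episode", "to_scheme", "SCHEMES"]


class RhythmLabel(Enum):
    NON_VTVF = "nonVTVF"
    VT_LO = "VT_lo"
    VT_HI = "VT_hi"
    FINE_VF = "fine_VF"
    COARSE_VF = "coarse_VF"
    UNCLASSIFIABLE = "unclassifiable"


SCHEMES = ("vtvf", "vf", "shockable")

_SCHEME_POSITIVES = {
    "vtvf": {RhythmLabel.VT_LO, RhythmLabel.VT_HI,
             RhythmLabel.FINE_VF, RhythmLabel.COARSE_VF},
    "vf": {RhythmLabel.FINE_VF, RhythmLabel.COARSE_VF},
    "shockable": {RhythmLabel.VT_HI, RhythmLabel.COARSE_VF},
}


@dataclass
class Thresholds:
    """Decision thresholds, defaulting to the values trained for 8-s
    episodes: MAV_d = 0.27, NMAV_d = 0.65, VT rate border 180 bpm,
    coarse-VF amplitude border 200 uV."""

    mav_d: float = 0.27
    nmav_d: float = 0.65
    vt_rate_border: float = 180.0
    vf_amp_border: float = 200.0

    def __post_init__(self):
        if not (0 < self.mav_d < 1):
            raise ValueError("mav_d must lie in (0, 1)")
        if self.nmav_d <= 0:
            raise ValueError("nmav_d must be positive")
        if self.vt_rate_border <= 0 or self.vf_amp_border <= 0:
            raise ValueError("borders must be positive")


@dataclass
class ClassificationResult:
    label: RhythmLabel
    mav: Optional[IndexResult] = None
    nmav: Optional[IndexResult] = None
    rate: Optional[RateResult] = None
    amplitude_uv: Optional[float] = None
    reason: str = ""

    def in_scheme(self, scheme: str) -> Optional[bool]:
        return to_scheme(self.label, scheme)


def classify_episode(
    episode,
    thresholds: Thresholds | None = None,
    plan: WindowPlan | None = None,
    sift_cfg: SiftConfig | None = None,
    filter_cfg: FilterChainConfig | None = None,
    rate_cfg: RateConfig | None = None,
) -> ClassificationResult:
    """Run the full three-stage decision on one episode.

    Returns the rhythm label together with every intermediate quantity
    (index results, rate result, amplitude) for audit. When amplitude
    calibration is unavailable the coarse/fine VF split cannot be made and
    detected VF is labelled coarse (the shockable interpretation used when
    the databases' annotated VF is known to be coarse).
    """
    if thresholds is None:
        thresholds = Thresholds()
    if rate_cfg is None:
        rate_cfg = RateConfig(vt_rate_border=thresholds.vt_rate_border,
                              vf_amp_border=thresholds.vf_amp_border)
    m = mav_a(episode, plan, filter_cfg)
    if m.aggregate is None:
        return ClassificationResult(RhythmLabel.UNCLASSIFIABLE, mav=m,
                                    reason="all analysis windows degenerate")
    if not (m.aggregate > thresholds.mav_d):
        return ClassificationResult(RhythmLabel.NON_VTVF, mav=m)
    nm = nmav_a(episode, plan, sift_cfg, filter_cfg)
    if nm.aggregate is None:
        return ClassificationResult(RhythmLabel.UNCLASSIFIABLE, mav=m, nmav=nm,
                                    reason="all analysis windows degenerate")
    if nm.aggregate < thresholds.nmav_d:
        # VF branch: amplitude decides coarse vs fine
        try:
            amp = vf_amplitude(episode)
        except CalibrationRequiredError:
            return ClassificationResult(RhythmLabel.COARSE_VF, mav=m, nmav=nm,
                                        amplitude_uv=None,
                                        reason="uncalibrated; VF treated as coarse")
        label = (RhythmLabel.COARSE_VF if amp > thresholds.vf_amp_border
                 else RhythmLabel.FINE_VF)
        return ClassificationResult(label, mav=m, nmav=nm, amplitude_uv=amp)
    # VT branch: heart rate decides shockable vs intermediate
    rate = heart_rate(episode, rate_cfg, filter_cfg)
    label = (RhythmLabel.VT_HI if rate.hr > thresholds.vt_rate_border
             else RhythmLabel.VT_LO)
    return ClassificationResult(label, mav=m, nmav=nm, rate=rate)


def to_scheme(label: RhythmLabel, scheme: str) -> Optional[bool]:
    """Map a fine-grained label to one of the three binary schemes.

    Returns True/False for classifiable labels and ``None`` for
    unclassifiable episodes (excluded from both classes, counted apart).
    """
    if scheme not in _SCHEME_POSITIVES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if label is RhythmLabel.UNCLASSIFIABLE:
        return None
    return label in _SCHEME_POSITIVES[scheme]
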