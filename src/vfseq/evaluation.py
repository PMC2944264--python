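"""Detector quality parameters, threshold selection, episode bookkeeping.

Quality of a binary identification scheme is scored with the four standard
ratios: sensitivity TP/(TP+FN), specificity TN/(TN+FP), positive
predictivity TP/(TP+FP), and accuracy (TP+TN)/total. Ratios whose
denominator is zero are reported as not-applicable (None).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["QualityReport", "quality_parameters", "episode_census",
           "threshold_histogram", "HistogramResult"]


@dataclass
class QualityReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    pos_pred: Optional[float]
    accuracy: Optional[float]

    def as_percent(self, ndigits: int = 2) -> dict:
        """Ratios as percentages rounded to ``ndigits`` decimals."""
        def pc(v):
            return None if v is None else round(100.0 * v, ndigits)
        return {"sensitivity": pc(self.sensitivity),
                "specificity": pc(self.specificity),
                "pos_pred": pc(self.pos_pred),
                "accuracy": pc(self.accuracy)}


def quality_parameters(predicted: Sequence[bool], truth: Sequence[bool]) -> QualityReport:
    """Confusion counts and the four quality ratios."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths"
        )
    tp = sum(1 for p, t in zip(predicted, truth) if p and t)
    fp = sum(1 for p, t in zip(predicted, truth) if p and not t)
    tn = sum(1 for p, t in zip(predicted, truth) if not p and not t)
    fn = sum(1 for p, t in zip(predicted, truth) if not p and t)
    total = tp + fp + tn + fn
    return QualityReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=tp / (tp + fn) if tp + fn > 0 else None,
        specificity=tn / (tn + fp) if tn + fp > 0 else None,
        pos_pred=tp / (tp + fp) if tp + fp > 0 else None,
        accuracy=(tp + tn) / total if total > 0 else None,
    )


def episode_census(record_lengths: Sequence[tuple], le: int = 8, step: int = 1) -> int:
    """Total episode count over a corpus.

    Each (duration_s, channels) record contributes
    (duration - le + step) // step episodes per channel; for the standard
    1-s stride that is duration - le + 1.
    """
    total = 0
    for duration, channels in record_lengths:
        if duration < le:
            continue
        per_channel = (int(duration) - le) // step + 1
        total += per_channel * channels
    return total


@dataclass
class HistogramResult:
    bin_edges: np.ndarray
    density_pos: np.ndarray
    density_neg: np.ndarray
    suggested_threshold: float
    youden_at_threshold: float


def threshold_histogram(
    values: Sequence[float],
    labels: Sequence[bool],
    bins: int = 50,
    specificity_weight: float = 1.0,
) -> HistogramResult:
    """Class-conditional histograms of an index plus a suggested threshold.

    The suggested threshold maximises sensitivity + specificity_weight x
    specificity over candidate cuts (midpoints between consecutive distinct
    values), with positives called above the cut. A weight > 1 biases the
    choice toward specificity, the safety-critical ratio for a shock
    decision.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.size != labels.size:
        raise ValueError("values and labels must have equal length")
    if not labels.any() or labels.all():
        raise ValueError("need at least one positive and one negative label")
    edges = np.histogram_bin_edges(values, bins=bins)
    dens_pos, _ = np.histogram(values[labels], bins=edges, density=True)
    dens_neg, _ = np.histogram(values[~labels], bins=edges, density=True)
    uniq = np.unique(values)
    cuts = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else uniq
    best_cut, best_score = float(cuts[0]), -np.inf
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    for c in cuts:
        pred = values > c
        sens = np.sum(pred & labels) / n_pos
        spec = np.sum(~pred & ~labels) / n_neg
        score = sens + specificity_weight * spec
        if score > best_score:
            best_score, best_cut = score, float(c)
    return HistogramResult(bin_edges=edges, density_pos=dens_pos,
                           density_neg=dens_neg, suggested_threshold=best_cut,
                           youden_at_threshold=float(best_score))
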