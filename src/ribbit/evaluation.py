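"""Detection, evaluation, and level-calibration utilities.

Thresholding turns window score sequences into detection tables; file-level
evaluation aggregates a file's (optionally continuity-filtered) score
sequence — by default the maximum, the "any window fired" statistic — and
compares it against presence/absence labels with precision, recall, and F1.
A threshold sweep over the observed scores gives the precision-recall
curve.

The dB utilities implement the coarse soundscape-level estimate used with
autonomous recorders: digital level dBFS = 20*log10(2*rms), mapped to an
approximate environmental dBA via an offset measured from a calibration
tone of known dBA (valid only to the extent the soundscape resembles the
calibration noise's spectrum).
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .audio_io import AudioClip
from .core import ScoreSequence

__all__ = [
    "apply_threshold",
    "precision_recall_f1",
    "pr_curve",
    "best_f1_threshold",
    "score_histogram",
    "dbfs",
    "dba_offset",
    "estimate_dba",
    "file_scores",
    "round_metric",
]


def round_metric(value: float, ndigits: int = 2) -> float:
    """Round half-up to ``ndigits`` places, the convention for reported metrics."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def apply_threshold(seq: ScoreSequence, threshold: float) -> pd.DataFrame:
    """One row per analysis window; ``detected`` means score >= threshold.

    Columns: source_path, window_start_s, window_end_s, score, detected,
    threshold_used. Ties detect (inclusive comparison keeps a published
    threshold's semantics stable).
    """
    if math.isnan(threshold):
        raise ValueError("threshold must not be NaN")
    return pd.DataFrame(
        {
            "source_path": seq.source_path,
            "window_start_s": seq.window_start_s,
            "window_end_s": seq.window_start_s + seq.window_s,
            "score": seq.scores,
            "detected": seq.scores >= threshold,
            "threshold_used": threshold,
        }
    )


def file_scores(
    sequences: dict[str, ScoreSequence], aggregation: str = "max"
) -> dict[str, float]:
    """Collapse each file's score sequence to a single file-level score."""
    return {key: seq.aggregate(aggregation) for key, seq in sequences.items()}


def precision_recall_f1(
    labels: dict[str, bool],
    scores: dict[str, float],
    threshold: float,
) -> tuple[float, float, float]:
    """Precision, recall, and F1 at one threshold, over per-file scores.

    Precision is the fraction of files scoring >= threshold that truly
    contain the target; recall is the fraction of truly positive files
    scoring >= threshold; F1 is their harmonic mean (0 when both are 0).
    With no predicted positives precision is undefined and returned as NaN
    rather than a silent zero.
    """
    if set(labels) != set(scores):
        raise ValueError("labels and scores must cover the same files")
    if not any(labels.values()):
        raise ValueError("recall needs at least one positive label")
    tp = fp = fn = 0
    for key, positive in labels.items():
        predicted = scores[key] >= threshold
        if predicted and positive:
            tp += 1
        elif predicted:
            fp += 1
        elif positive:
            fn += 1
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn)
    if math.isnan(precision) or precision + recall == 0:
        f1 = 0.0 if not math.isnan(precision) else float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def pr_curve(labels: dict[str, bool], scores: dict[str, float]) -> pd.DataFrame:
    """Precision-recall sweep over the sorted unique file scores.

    Each observed score is used as a threshold (inclusive), so every
    achievable operating point appears once. Recall is non-increasing as
    the threshold rises.
    """
    thresholds = np.unique(list(scores.values()))
    rows = []
    for thr in thresholds:
        p, r, f1 = precision_recall_f1(labels, scores, float(thr))
        rows.append(dict(threshold=float(thr), precision=p, recall=r, f1=f1))
    return pd.DataFrame(rows)


def best_f1_threshold(labels: dict[str, bool], scores: dict[str, float]) -> tuple[float, float]:
    """(threshold, F1) maximizing F1 over the swept thresholds."""
    curve = pr_curve(labels, scores)
    idx = int(curve["f1"].fillna(-1.0).idxmax())
    return float(curve.loc[idx, "threshold"]), float(curve.loc[idx, "f1"])


def score_histogram(
    labels: dict[str, bool], scores: dict[str, float], bins: int = 30
) -> pd.DataFrame:
    """Histogram of file scores split by label, as plain tabular data.

    Useful for choosing a threshold visually at a "natural break" between
    the positive and negative score distributions; automated break finding
    is deliberately not provided.
    """
    values = np.array(list(scores.values()))
    edges = np.histogram_bin_edges(values, bins=bins)
    pos = np.array([scores[k] for k, v in labels.items() if v])
    neg = np.array([scores[k] for k, v in labels.items() if not v])
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "n_positive": np.histogram(pos, bins=edges)[0],
            "n_negative": np.histogram(neg, bins=edges)[0],
        }
    )


def dbfs(clip: AudioClip) -> float:
    """Digital level in dB relative to full scale: 20*log10(2*rms).

    A full-scale square wave (rms 1) reads +6.02 dBFS and an rms of 0.5
    reads 0 dBFS under this convention. A silent clip returns -inf.
    """
    rms = float(np.sqrt(np.mean(clip.samples**2)))
    if rms == 0.0:
        return float("-inf")
    return 20.0 * math.log10(2.0 * rms)


def dba_offset(calibration_dba: float, calibration_dbfs: float) -> float:
    """Offset (dB) between digital level and environmental level.

    From a matched calibration pair: a test noise of known ``calibration_dba``
    recorded at ``calibration_dbfs`` gives offset = dBFS - dBA (e.g. a
    69 dBA pink-noise test recorded at -19 dBFS gives -88 dB).
    """
    return calibration_dbfs - calibration_dba


def estimate_dba(clip: AudioClip, offset: float) -> float:
    """Approximate environmental level: dbfs(clip) - offset.

    A coarse estimate: it assumes the soundscape's spectrum resembles the
    calibration noise (e.g. pink noise), and recorder gain matches the
    calibration recording.
    """
    return dbfs(clip) - offset
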