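"""Batch scanning of WAV files against a species profile.

Long field recordings (10-minute to hour-long files) are processed
window-by-window: the WAV is memory-mapped, each analysis window is read
at the native rate, resampled to the profile's rate if needed, and scored
independently. Memory use is proportional to one analysis window, not the
file. Analysis windows do not overlap, so per-window resampling only
differs from whole-file resampling in a handful of filter-edge samples per
window.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .audio_io import AudioClip, _to_float, resample
from .core import ScoreSequence, SpeciesProfile, continuity_filter, score_clip
from .evaluation import apply_threshold

__all__ = ["scan_file", "scan_files", "summarize"]

log = logging.getLogger("ribbit")


def _file_dbfs(path: str | Path, chunk: int = 1 << 20) -> float:
    """Digital level of a whole file, computed in streamed chunks."""
    rate, data = wavfile.read(path, mmap=True)
    total = 0.0
    count = 0
    for start in range(0, data.shape[0], chunk):
        x = _to_float(np.asarray(data[start : start + chunk]))
        if x.ndim == 2:
            x = x.mean(axis=1)
        total += float(np.sum(x**2))
        count += len(x)
    rms = np.sqrt(total / count) if count else 0.0
    return float("-inf") if rms == 0 else float(20.0 * np.log10(2.0 * rms))


def scan_file(path: str | Path, profile: SpeciesProfile) -> ScoreSequence:
    """Score every analysis window of a WAV file (streamed)."""
    path = Path(path)
    try:
        native_rate, data = wavfile.read(path, mmap=True)
    except Exception as exc:
        raise IOError(f"could not read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"empty audio file: {path}")
    native_win = int(round(profile.analysis_window_s * native_rate))
    n_windows = data.shape[0] // native_win
    scores = np.empty(n_windows)
    for i in range(n_windows):
        chunk = np.asarray(data[i * native_win : (i + 1) * native_win])
        samples = _to_float(chunk)
        if samples.ndim == 2:
            samples = samples.mean(axis=1)
        clip = AudioClip(samples, float(native_rate))
        if native_rate != profile.sample_rate:
            clip = resample(clip, profile.sample_rate)
        scores[i] = score_clip(clip, profile)
    return ScoreSequence(
        scores=scores,
        window_start_s=np.arange(n_windows) * profile.analysis_window_s,
        window_s=profile.analysis_window_s,
        source_path=str(path),
    )


def scan_files(
    paths: list[str | Path],
    profile: SpeciesProfile,
    use_continuity: bool = True,
    threshold: float | None = None,
    aggregation: str = "max",
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame]:
    """Score a batch of files in deterministic (sorted) order.

    Returns ``(scores, detections, summary)`` tables: per-window scores
    (continuity-filtered when enabled and the sequence is long enough),
    per-window detections if a threshold was given (else ``None``), and a
    per-file summary with the aggregated score and digital level.
    Unreadable files are logged and skipped; if every file fails, raises.
    """
    score_rows: list[pd.DataFrame] = []
    det_rows: list[pd.DataFrame] = []
    summary_rows: list[dict] = []
    failures = 0
    for path in sorted(str(p) for p in paths):
        t0 = time.monotonic()
        try:
            seq = scan_file(path, profile)
        except (IOError, ValueError) as exc:
            log.warning("skipping %s: %s", path, exc)
            failures += 1
            continue
        if use_continuity and profile.continuity_n > 1:
            if profile.continuity_n <= len(seq):
                seq = continuity_filter(seq, profile.continuity_n)
            else:
                log.warning(
                    "%s: only %d windows, continuity filter n=%d skipped",
                    path, len(seq), profile.continuity_n,
                )
        frame = pd.DataFrame(
            {
                "source_path": path,
                "window_start_s": seq.window_start_s,
                "window_end_s": seq.window_start_s + seq.window_s,
                "score": seq.scores,
                "filtered": seq.filtered,
            }
        )
        score_rows.append(frame)
        if threshold is not None:
            det_rows.append(apply_threshold(seq, threshold))
        level = _file_dbfs(path)
        summary_rows.append(
            dict(
                source_path=path,
                n_windows=len(seq),
                score=seq.aggregate(aggregation),
                aggregation=aggregation,
                dbfs=level,
                elapsed_s=round(time.monotonic() - t0, 3),
            )
        )
        log.info("%s: %d windows in %.2f s", path, len(seq), time.monotonic() - t0)
    if not summary_rows:
        raise IOError(f"no readable input files ({failures} failures)")
    scores = pd.concat(score_rows, ignore_index=True)
    detections = pd.concat(det_rows, ignore_index=True) if det_rows else None
    return scores, detections, pd.DataFrame(summary_rows)


def summarize(seq: ScoreSequence, aggregation: str = "max") -> float:
    """File-level score for one sequence."""
    return seq.aggregate(aggregation)
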