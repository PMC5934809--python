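"""Per-beat feature assembly: RR intervals, running-average RR, QRS width.

The running average RR is causal (only already-seen beats) and, by default,
selective in the Pan–Tompkins tradition: an interval only enters the
average when it falls inside a plausibility band around the current
average.  A plain mean would let the compensatory pauses of sustained
bigeminy/trigeminy inflate the reference interval until the premature-beat
rules sit exactly on their decision boundary; the selective average keeps
it anchored to the underlying sinus rate.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .preprocess import NoiseMask
from .qrs import QrsComplex

__all__ = [
    "FeatureConfig",
    "BeatFeature",
    "compute_rr_series",
    "running_avg_rr",
    "assemble_beat_features",
]


@dataclass(frozen=True)
class FeatureConfig:
    avg_window: int = 8        # intervals in the running average
    selective: bool = True     # Pan-Tompkins-style acceptance band
    accept_low: float = 0.75   # band bounds, relative to the current average
    accept_high: float = 1.2


@dataclass(frozen=True)
class BeatFeature:
    """Feature record for one beat.

    ``rr_prev_ms``/``rr_next_ms``/``avg_rr_ms`` are ``None`` where undefined
    (first/last beat) — never silently zero.
    """

    beat_index: int
    r: int
    rr_prev_ms: float | None
    rr_next_ms: float | None
    avg_rr_ms: float | None
    qrs_width_ms: float
    in_noise: bool


def compute_rr_series(rpeaks: np.ndarray, fs: float) -> np.ndarray:
    """RR intervals in ms between consecutive R peaks (empty if < 2 peaks)."""
    rpeaks = np.asarray(rpeaks, dtype=np.int64)
    if rpeaks.size < 2:
        return np.empty(0, dtype=np.float64)
    return np.diff(rpeaks) * 1000.0 / fs


def running_avg_rr(rr: np.ndarray,
                   config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Causal average RR aligned with each interval.

    ``out[i]`` is the reference average for the beat whose *current* RR is
    ``rr[i]``: the mean of (up to) ``avg_window`` previously accepted
    intervals, excluding ``rr[i]`` itself.  With fewer than ``avg_window``
    intervals seen, the mean of the available ones is used; ``out[0]``
    falls back to ``rr[0]``.  In selective mode an interval is accepted into
    the history only if it lies within ``(accept_low, accept_high)`` times
    the average current at its own position.
    """
    rr = np.asarray(rr, dtype=np.float64)
    out = np.empty_like(rr)
    hist: deque[float] = deque(maxlen=config.avg_window)
    for i, v in enumerate(rr):
        avg = float(np.mean(hist)) if hist else float(v)
        out[i] = avg
        if (not config.selective or not hist
                or config.accept_low * avg < v < config.accept_high * avg):
            hist.append(float(v))
    return out


def assemble_beat_features(rpeaks: np.ndarray, qrs: list[QrsComplex],
                           mask: NoiseMask | None, fs: float,
                           config: FeatureConfig = FeatureConfig()
                           ) -> list[BeatFeature]:
    """One BeatFeature per R peak; beats overlapping the mask are flagged.

    A beat is ``in_noise`` when its half-open ``[onset, offset)`` window
    intersects a flagged segment; such beats are excluded downstream from
    classification and template building.
    """
    rpeaks = np.asarray(rpeaks, dtype=np.int64)
    if len(qrs) != rpeaks.size:
        raise ValueError(
            f"rpeaks ({rpeaks.size}) and qrs ({len(qrs)}) length mismatch")
    rr = compute_rr_series(rpeaks, fs)
    avg = running_avg_rr(rr, config) if rr.size else np.empty(0)
    feats: list[BeatFeature] = []
    for i, (r, q) in enumerate(zip(rpeaks, qrs)):
        rr_prev = float(rr[i - 1]) if i >= 1 else None
        rr_next = float(rr[i]) if i < rr.size else None
        avg_rr = float(avg[i - 1]) if i >= 1 else (
            float(avg[0]) if avg.size else None)
        in_noise = mask.intersects(q.onset, q.offset) if mask is not None else False
        feats.append(BeatFeature(beat_index=i, r=int(r), rr_prev_ms=rr_prev,
                                 rr_next_ms=rr_next, avg_rr_ms=avg_rr,
                                 qrs_width_ms=q.width_ms, in_noise=in_noise))
    return feats


def features_to_rows(feats: list[BeatFeature]) -> list[dict]:
    """Plain-dict rows for export (e.g. ``pandas.DataFrame(rows)``)."""
    return [vars(f).copy() for f in feats]
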