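"""Preprocessing: band-pass filtering, edge trimming, artifact masking.

The band-pass (0.5–40 Hz by default) removes baseline drift, high-frequency
noise and powerline interference.  Artifact masking slides non-overlapping
windows over the filtered record and flags bursts, flatlines (lead-off) and
saturation against a dynamic threshold derived from a running median of the
window peak-to-peak range; flagged segments are abandoned by all later
stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import EcgSignal

__all__ = [
    "FilterConfig",
    "ArtifactConfig",
    "NoiseMask",
    "bandpass_filter",
    "trim_edges",
    "detect_artifacts",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    order: int = 3
    low_hz: float = 0.5
    high_hz: float = 40.0


@dataclass(frozen=True)
class ArtifactConfig:
    window_s: float = 2.0        # non-overlapping analysis window
    history: int = 30            # windows in the running median
    burst_k: float = 4.0         # flag if range > burst_k * median range
    flat_mv: float = 0.05        # flag if range below this (flatline/lead-off)
    full_scale_mv: float = 5.0   # recorder bound; |x| >= 99% of it = saturation
    saturation_frac: float = 0.99


@dataclass(frozen=True)
class NoiseMask:
    """Per-sample boolean artifact mask.

    ``segments`` are the maximal runs of flagged samples as half-open
    ``(start, end)`` sample intervals, sorted and non-overlapping.
    """

    flags: np.ndarray
    segments: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags, dtype=bool)
        object.__setattr__(self, "flags", flags)
        object.__setattr__(self, "segments", _runs(flags))

    def __len__(self) -> int:
        return self.flags.size

    @property
    def flagged_fraction(self) -> float:
        return float(self.flags.mean()) if self.flags.size else 0.0

    def intersects(self, start: int, end: int) -> bool:
        """True if any sample of half-open ``[start, end)`` is flagged."""
        start = max(start, 0)
        end = min(end, self.flags.size)
        return bool(self.flags[start:end].any()) if end > start else False

    @classmethod
    def empty(cls, n: int) -> "NoiseMask":
        return cls(np.zeros(n, dtype=bool))

    def to_intervals_csv(self, path) -> None:
        """Export flagged segments as BED-like 'start_sample,end_sample' CSV."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("start_sample,end_sample\n")
            for a, b in self.segments:
                fh.write(f"{a},{b}\n")


def _runs(flags: np.ndarray) -> tuple[tuple[int, int], ...]:
    if flags.size == 0 or not flags.any():
        return ()
    padded = np.concatenate(([False], flags, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return tuple(zip(starts.tolist(), ends.tolist()))


def bandpass_filter(sig: EcgSignal, low_hz: float = 0.5, high_hz: float = 40.0,
                    order: int = 3) -> EcgSignal:
    """Zero-phase Butterworth band-pass.

    Applied forward-backward (``sosfiltfilt``) so R-peak timing is not
    skewed by filter group delay; this matters because QRS boundaries are
    later placed at fixed offsets around the R peak.
    """
    if not 0 < low_hz < high_hz:
        raise ValueError(f"need 0 < low_hz < high_hz, got {low_hz}, {high_hz}")
    if high_hz >= sig.fs / 2:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {sig.fs / 2}")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=sig.fs, output="sos")
    # pad length capped for very short inputs
    padlen = min(3 * 25 * order, len(sig) - 1)
    out = sps.sosfiltfilt(sos, sig.samples, padlen=padlen)
    return sig.with_samples(out)


def trim_edges(sig: EcgSignal, minutes: float = 2.0) -> EcgSignal:
    """Drop the first and last ``minutes`` of the record (attach/detach noise)."""
    if minutes < 0:
        raise ValueError("minutes must be >= 0")
    if minutes == 0:
        return sig
    cut = int(round(minutes * 60 * sig.fs))
    if len(sig) <= 2 * cut:
        raise ValueError(
            f"record of {sig.duration_s:.1f} s too short to trim "
            f"{minutes} min from each end")
    return EcgSignal(sig.samples[cut:len(sig) - cut], fs=sig.fs,
                     lead=sig.lead, t0=sig.t0 + minutes * 60)


def detect_artifacts(sig: EcgSignal,
                     config: ArtifactConfig = ArtifactConfig()) -> NoiseMask:
    """Dynamic-threshold artifact masking on a filtered signal.

    Windows of ``window_s`` are flagged when their peak-to-peak range exceeds
    ``burst_k`` times the running median range of the previous ``history``
    windows (motion/burst), falls below ``flat_mv`` (flatline), or any sample
    comes within ``saturation_frac`` of the recorder full-scale bound.  The
    first ``history`` windows are judged against the global median range so
    a cold start does not trigger false flags.
    """
    x = sig.samples
    n = x.size
    win = max(1, int(round(config.window_s * sig.fs)))
    nwin = int(np.ceil(n / win))
    flags = np.zeros(n, dtype=bool)
    if nwin == 0:
        return NoiseMask(flags)

    ranges = np.empty(nwin)
    flat_ranges = np.empty(nwin)
    maxabs = np.empty(nwin)
    for i in range(nwin):
        seg = x[i * win:(i + 1) * win]
        ranges[i] = seg.max() - seg.min()
        maxabs[i] = np.abs(seg).max()
        # flatline is judged on half-windows so that a dropout partially
        # covered by filter transients or window straddling is still caught
        mid = seg.size // 2
        if mid:
            flat_ranges[i] = min(seg[:mid].max() - seg[:mid].min(),
                                 seg[mid:].max() - seg[mid:].min())
        else:
            flat_ranges[i] = ranges[i]

    global_median = float(np.median(ranges))
    sat_level = config.saturation_frac * config.full_scale_mv
    for i in range(nwin):
        if i < config.history:
            med = global_median
        else:
            med = float(np.median(ranges[i - config.history:i]))
        burst = ranges[i] > config.burst_k * med and med > 0
        flat = flat_ranges[i] < config.flat_mv
        saturated = maxabs[i] >= sat_level
        if burst or flat or saturated:
            flags[i * win:min((i + 1) * win, n)] = True

    mask = NoiseMask(flags)
    if mask.flagged_fraction == 1.0:
        log.warning("artifact mask flagged the entire record")
    return mask
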