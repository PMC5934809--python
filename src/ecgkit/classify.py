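"""Rule-based beat classification, rhythm-run detection, template correction.

Beat rules (strict inequalities, all durations in ms, ``avg`` the running
average RR):

* NB:  width < 120  and  0.75*avg < rr_prev < 1.2*avg
* APB: width < 120  and  rr_prev < 0.75*avg  and  rr_prev + rr_next < 2*avg
* VPB: width > 120  and  rr_prev < 0.75*avg  and  rr_prev + rr_next >= 2*avg

Anything else (including width exactly 120 ms) is UNCLASSIFIED.  Bigeminy
is a maximal alternation of VPB and normal beats with at least ``bg_min``
VPBs; trigeminy repeats two normals plus one VPB with at least ``tg_min``
VPBs.  Post-extrasystolic beats routinely fall outside the NB band (their
preceding interval is the compensatory pause), so run detection treats
UNCLASSIFIED narrow beats as normal-like when scanning for alternation.

An averaged normal-beat template is used to reconfirm abnormal calls: a
beat whose waveform matches the template is demoted back to NB.  Matching
morphology genuinely contradicts a wide-QRS (VPB) call; a narrow APB has a
normal QRS by definition, so for APB calls the demotion additionally
requires the prematurity itself to be marginal.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .features import BeatFeature
from .io import BeatLabel, EcgSignal, RhythmEvent
from .qrs import ms_to_samples

__all__ = [
    "RuleConfig",
    "EventConfig",
    "TemplateConfig",
    "NbTemplate",
    "classify_beat",
    "classify_beats",
    "detect_rhythm_events",
    "build_template",
    "template_correct",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RuleConfig:
    wide_ms: float = 120.0   # narrow/wide QRS boundary (strict on both sides)
    rr_low: float = 0.75     # lower NB band / prematurity bound
    rr_high: float = 1.2     # upper NB band
    pause: float = 2.0       # compensatory-pause bound on rr_prev + rr_next


@dataclass(frozen=True)
class EventConfig:
    bg_min: int = 3                        # minimum VPBs in a bigeminy run
    tg_min: int = 2                        # minimum VPBs in a trigeminy run
    unclassified_as_normal: bool = True    # see module docstring


@dataclass(frozen=True)
class TemplateConfig:
    window_ms: float = 100.0   # half-window around R
    max_beats: int = 50
    corr: float = 0.9          # demotion threshold (normalized cross-corr.)
    apb_guard: float = 0.70    # demote APB only if rr_prev >= guard * avg


@dataclass(frozen=True)
class NbTemplate:
    """Amplitude-normalized mean normal-beat waveform centered on R."""

    waveform: np.ndarray
    window_ms: float
    n_beats: int

    def __post_init__(self) -> None:
        if self.n_beats < 1:
            raise ValueError("template needs at least one beat")


def classify_beat(feat: BeatFeature,
                  config: RuleConfig = RuleConfig()) -> BeatLabel:
    """Label one beat from its features.

    Beats with an undefined neighbor interval (first/last of a record)
    cannot satisfy the premature-beat rules; they default to NB when
    narrow, else UNCLASSIFIED.
    """
    w = feat.qrs_width_ms
    narrow = w < config.wide_ms
    if feat.rr_prev_ms is None or feat.rr_next_ms is None or feat.avg_rr_ms is None:
        return BeatLabel.NB if narrow else BeatLabel.UNCLASSIFIED
    rr, rr_next, avg = feat.rr_prev_ms, feat.rr_next_ms, feat.avg_rr_ms
    premature = rr < config.rr_low * avg
    pause_sum = rr + rr_next
    if narrow and config.rr_low * avg < rr < config.rr_high * avg:
        return BeatLabel.NB
    if narrow and premature and pause_sum < config.pause * avg:
        return BeatLabel.APB
    if w > config.wide_ms and premature and pause_sum >= config.pause * avg:
        return BeatLabel.VPB
    return BeatLabel.UNCLASSIFIED


def classify_beats(feats: list[BeatFeature],
                   config: RuleConfig = RuleConfig()) -> list[BeatLabel | None]:
    """Labels for a beat sequence; in-noise beats get ``None`` (no label)."""
    return [None if f.in_noise else classify_beat(f, config) for f in feats]


def _symbol(label: BeatLabel | None, config: EventConfig) -> str:
    if label is BeatLabel.VPB:
        return "V"
    if label is BeatLabel.NB:
        return "N"
    if label is BeatLabel.UNCLASSIFIED and config.unclassified_as_normal:
        return "N"
    return "x"


def detect_rhythm_events(labels: list[BeatLabel | None],
                         config: EventConfig = EventConfig()
                         ) -> list[RhythmEvent]:
    """Find maximal bigeminy/trigeminy runs in a beat-label sequence.

    BG: a maximal alternation ``V N V N ...`` containing at least ``bg_min``
    VPBs; the event spans from its first VPB through the normal beat after
    its last VPB (when present).  TG: maximal repetition ``(N N V)+`` with
    at least ``tg_min`` VPBs, extended over up to two trailing normals.
    Events of one kind never overlap.
    """
    s = "".join(_symbol(l, config) for l in labels)
    events: list[RhythmEvent] = []

    raw_bg = [(m.start(), m.end()) for m in re.finditer(r"V(?:NV)*", s)]
    for start, end in raw_bg:
        n_vpb = (end - start + 1) // 2
        if n_vpb < config.bg_min:
            continue
        if end < len(s) and s[end] == "N":
            end += 1
        events.append(RhythmEvent("BG", start, end))

    raw_tg = [(m.start(), m.end()) for m in re.finditer(r"(?:NNV)+", s)]
    for k, (start, end) in enumerate(raw_tg):
        n_vpb = (end - start) // 3
        if n_vpb < config.tg_min:
            continue
        limit = raw_tg[k + 1][0] if k + 1 < len(raw_tg) else len(s)
        for _ in range(2):
            if end < min(len(s), limit) and s[end] == "N":
                end += 1
        events.append(RhythmEvent("TG", start, end))

    return sorted(events, key=lambda e: (e.start_beat, e.kind))


def _beat_window(x: np.ndarray, r: int, half: int) -> np.ndarray | None:
    if r - half < 0 or r + half + 1 > x.size:
        return None
    return x[r - half:r + half + 1]


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation (Pearson) of two windows."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def build_template(sig: EcgSignal, feats: list[BeatFeature],
                   labels: list[BeatLabel | None],
                   config: TemplateConfig = TemplateConfig()
                   ) -> NbTemplate | None:
    """Average the first noise-free NB beats into a normal-beat template.

    The template is the pointwise mean of up to ``max_beats`` windows of
    R +/- ``window_ms``, zero-meaned and scaled to unit norm.  Returns
    ``None`` (with a warning) when no eligible beat exists, in which case
    the correction step is skipped.
    """
    half = ms_to_samples(config.window_ms, sig.fs)
    windows = []
    for f, lab in zip(feats, labels):
        if lab is not BeatLabel.NB or f.in_noise:
            continue
        w = _beat_window(sig.samples, f.r, half)
        if w is not None:
            windows.append(w)
        if len(windows) >= config.max_beats:
            break
    if not windows:
        log.warning("no noise-free NB beats available; template unavailable")
        return None
    mean = np.mean(windows, axis=0)
    mean = mean - mean.mean()
    norm = np.linalg.norm(mean)
    if norm > 0:
        mean = mean / norm
    return NbTemplate(waveform=mean, window_ms=config.window_ms,
                      n_beats=len(windows))


def template_correct(labels: list[BeatLabel | None], sig: EcgSignal,
                     feats: list[BeatFeature], template: NbTemplate | None,
                     config: TemplateConfig = TemplateConfig()
                     ) -> list[BeatLabel | None]:
    """Reconfirm abnormal calls against the normal-beat template.

    A VPB call whose window correlates with the template at or above
    ``corr`` is demoted to NB (a matching narrow morphology refutes the
    wide-QRS premise).  An APB call is demoted only when the morphology
    matches *and* its prematurity is marginal
    (``rr_prev >= apb_guard * avg``): a clearly premature narrow beat is an
    APB regardless of its normal QRS shape.  NB beats are never changed;
    the operation is idempotent.
    """
    if template is None:
        return list(labels)
    half = ms_to_samples(template.window_ms, sig.fs)
    out = list(labels)
    for i, (f, lab) in enumerate(zip(feats, labels)):
        if lab not in (BeatLabel.APB, BeatLabel.VPB):
            continue
        w = _beat_window(sig.samples, f.r, half)
        if w is None or _ncc(w, template.waveform) < config.corr:
            continue
        if lab is BeatLabel.VPB:
            out[i] = BeatLabel.NB
        elif (f.rr_prev_ms is not None and f.avg_rr_ms is not None
                and f.rr_prev_ms >= config.apb_guard * f.avg_rr_ms):
            out[i] = BeatLabel.NB
    return out
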