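"""End-to-end orchestration of the automatic ECG analysis pipeline.

Stage order: edge trimming -> band-pass filtering -> morphological R-peak
enhancement -> artifact masking (computed on the filtered signal,
independent of detection, and applied before classification) -> R
detection -> QRS delineation -> per-beat features -> rule classification
-> normal-template correction -> rhythm-run detection.  Two execution
backends (a naive loop and a vectorized one) are interchangeable and must
produce identical annotations; per-stage wall-clock timings are recorded
but never part of any correctness contract.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

from . import classify as _cls
from . import features as _feat
from . import metrics as _metrics
from . import preprocess as _pre
from . import qrs as _qrs
from .io import AnnotationSet, Beat, BeatLabel, EcgSignal

__all__ = ["PipelineConfig", "StageTimings", "PipelineResult",
           "PipelineStageError", "run_pipeline"]

log = logging.getLogger(__name__)

#: records longer than this are edge-trimmed by default
_AUTO_TRIM_THRESHOLD_S = 600.0
_AUTO_TRIM_MINUTES = 2.0


class PipelineStageError(RuntimeError):
    """Wraps a stage failure with the stage name attached."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    filter: _pre.FilterConfig = field(default_factory=_pre.FilterConfig)
    artifact: _pre.ArtifactConfig = field(default_factory=_pre.ArtifactConfig)
    morph: _qrs.MorphConfig = field(default_factory=_qrs.MorphConfig)
    rdet: _qrs.DetectorConfig = field(default_factory=_qrs.DetectorConfig)
    qrs: _qrs.DelineationConfig = field(default_factory=_qrs.DelineationConfig)
    features: _feat.FeatureConfig = field(default_factory=_feat.FeatureConfig)
    rules: _cls.RuleConfig = field(default_factory=_cls.RuleConfig)
    template: _cls.TemplateConfig = field(default_factory=_cls.TemplateConfig)
    events: _cls.EventConfig = field(default_factory=_cls.EventConfig)
    backend: str = "vectorized"
    #: None -> trim 2 min from each edge of records longer than 10 min,
    #: nothing from shorter ones
    trim_minutes: float | None = None
    match_tol_ms: float = 75.0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = {}
        sections = {
            "filter": _pre.FilterConfig, "artifact": _pre.ArtifactConfig,
            "morph": _qrs.MorphConfig, "rdet": _qrs.DetectorConfig,
            "qrs": _qrs.DelineationConfig, "features": _feat.FeatureConfig,
            "rules": _cls.RuleConfig, "template": _cls.TemplateConfig,
            "events": _cls.EventConfig,
        }
        for key, val in d.items():
            if key in sections:
                kw[key] = sections[key](**val)
            elif key in ("backend", "trim_minutes", "match_tol_ms"):
                kw[key] = val
            else:
                raise ValueError(f"unknown pipeline config key {key!r}")
        return cls(**kw)


@dataclass
class StageTimings:
    """Per-stage wall-clock seconds plus fractions of the total."""

    seconds: dict[str, float] = field(default_factory=dict)

    def add(self, stage: str, dt: float) -> None:
        self.seconds[stage] = self.seconds.get(stage, 0.0) + dt

    @property
    def total(self) -> float:
        return sum(self.seconds.values())

    def fractions(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {k: 0.0 for k in self.seconds}
        return {k: v / total for k, v in self.seconds.items()}


@dataclass
class PipelineResult:
    annotations: AnnotationSet
    report: _metrics.PerfReport | None
    timings: StageTimings
    mask: _pre.NoiseMask
    labels: list[BeatLabel | None]
    features: list[_feat.BeatFeature]


def run_pipeline(sig: EcgSignal, config: PipelineConfig = PipelineConfig(),
                 truth: AnnotationSet | None = None,
                 scored_only: bool = True) -> PipelineResult:
    """Run the full analysis chain on one record.

    Returns predicted annotations (in-noise beats are reported as
    UNCLASSIFIED and never enter rhythm-run patterns), a performance
    report when ground truth is supplied, and per-stage timings.
    """
    timings = StageTimings()

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc
        timings.add(name, time.perf_counter() - t0)
        return out

    minutes = config.trim_minutes
    if minutes is None:
        minutes = (_AUTO_TRIM_MINUTES
                   if sig.duration_s > _AUTO_TRIM_THRESHOLD_S else 0.0)
    sig = stage("trim", _pre.trim_edges, sig, minutes)
    if len(sig) == 0:
        raise PipelineStageError("trim", ValueError("empty post-trim signal"))

    filtered = stage("filter", _pre.bandpass_filter, sig,
                     config.filter.low_hz, config.filter.high_hz,
                     config.filter.order)
    enhanced = stage("morphology", _qrs.morphological_transform, filtered,
                     config.morph, config.backend)
    mask = stage("artifact", _pre.detect_artifacts, filtered, config.artifact)
    rpeaks = stage("r_detection", _qrs.detect_r_peaks, enhanced, mask,
                   config.rdet)
    qrs_list = stage("delineation", _qrs.delineate_qrs, filtered, rpeaks,
                     enhanced, config.qrs)
    feats = stage("features", _feat.assemble_beat_features, rpeaks, qrs_list,
                  mask, sig.fs, config.features)

    def _classify_and_correct():
        labels = _cls.classify_beats(feats, config.rules)
        template = _cls.build_template(filtered, feats, labels, config.template)
        labels = _cls.template_correct(labels, filtered, feats, template,
                                       config.template)
        events = _cls.detect_rhythm_events(labels, config.events)
        return labels, events

    labels, events = stage("classification", _classify_and_correct)

    ann = AnnotationSet(
        beats=[Beat(int(r), lab if lab is not None else BeatLabel.UNCLASSIFIED)
               for r, lab in zip(rpeaks, labels)],
        events=events, fs=sig.fs, record_id="")

    report = None
    if truth is not None:
        report = stage("scoring", _metrics.score_annotations, ann, truth,
                       sig.fs, config.match_tol_ms, scored_only)
    return PipelineResult(annotations=ann, report=report, timings=timings,
                          mask=mask, labels=labels, features=feats)
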