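"""Beat matching and classification scoring, plus ratio calculators.

Scoring is one-vs-rest per class over the scored instance universe: beat
instances (NB/APB/VPB) and rhythm-event instances (BG couplets, TG
triplets).  For each class ``c``::

    ACCU = (TPOS + TNEG) / (TPOS + FNEG + FPOS + TNEG)
    SENS = TPOS / (TPOS + FNEG)
    SPEC = TNEG / (FPOS + TNEG)

Detection misses of a class-``c`` truth instance count as FNEG.  Speedup
(``t_s / t_p``) and energy saving (``(e_s - e_p) / e_s``) are pure ratio
calculators for user-supplied wall-clock and battery measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AnnotationSet, BeatLabel

__all__ = [
    "ConfusionCounts",
    "PerfReport",
    "match_beats",
    "confusion_counts",
    "perf",
    "speedup",
    "energy_saving",
    "score_annotations",
    "CLASS_ORDER",
]

CLASS_ORDER = ("NB", "APB", "VPB", "BG", "TG")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts for a single class."""

    class_label: str
    tpos: int = 0
    tneg: int = 0
    fpos: int = 0
    fneg: int = 0

    def __post_init__(self) -> None:
        if min(self.tpos, self.tneg, self.fpos, self.fneg) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tpos + self.tneg + self.fpos + self.fneg


def perf(counts: ConfusionCounts) -> tuple[float | None, float | None, float | None]:
    """(ACCU, SENS, SPEC) as fractions; ``None`` where a denominator is zero."""
    accu = ((counts.tpos + counts.tneg) / counts.total
            if counts.total > 0 else None)
    pos = counts.tpos + counts.fneg
    sens = counts.tpos / pos if pos > 0 else None
    neg = counts.fpos + counts.tneg
    spec = counts.tneg / neg if neg > 0 else None
    return accu, sens, spec


def speedup(t_s: float, t_p: float) -> float:
    """Serial-over-parallel execution-time ratio SP = Ts / Tp."""
    if t_s <= 0 or t_p <= 0:
        raise ValueError("execution times must be positive")
    return t_s / t_p


def energy_saving(e_s: float, e_p: float) -> float:
    """Fraction of energy saved: (Es - Ep) / Es."""
    if e_s <= 0:
        raise ValueError("baseline energy must be positive")
    if e_p < 0:
        raise ValueError("energy must be non-negative")
    return (e_s - e_p) / e_s


def match_beats(pred: np.ndarray, truth: np.ndarray, fs: float,
                tol_ms: float = 75.0
                ) -> tuple[dict[int, int], list[int], list[int]]:
    """Greedy one-to-one nearest pairing of beat indices within tolerance.

    Returns ``(pairs, unmatched_truth, unmatched_pred)`` where ``pairs``
    maps truth positions to pred positions.  Candidate pairs are taken in
    order of increasing time difference (ties broken by position), each
    beat used at most once; unpaired truth beats are detection misses.
    """
    pred = np.asarray(pred, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    tol = tol_ms * fs / 1000.0
    cands: list[tuple[float, int, int]] = []
    j0 = 0
    for ti, tv in enumerate(truth):
        # advance over predictions definitely out of range
        while j0 < pred.size and pred[j0] < tv - tol:
            j0 += 1
        j = j0
        while j < pred.size and pred[j] <= tv + tol:
            cands.append((abs(float(pred[j] - tv)), ti, j))
            j += 1
    cands.sort()
    pairs: dict[int, int] = {}
    used_pred: set[int] = set()
    for _, ti, pj in cands:
        if ti in pairs or pj in used_pred:
            continue
        pairs[ti] = pj
        used_pred.add(pj)
    unmatched_truth = [i for i in range(truth.size) if i not in pairs]
    unmatched_pred = [j for j in range(pred.size) if j not in used_pred]
    return pairs, unmatched_truth, unmatched_pred


def confusion_counts(pairs: list[tuple[str, str | None]], cls: str
                     ) -> ConfusionCounts:
    """One-vs-rest counts from (truth_class, predicted_class) instances.

    ``predicted_class`` is ``None`` for detection misses (these count as
    FNEG when the truth class is ``cls``, TNEG otherwise).
    """
    tp = tn = fp = fn = 0
    for truth_cls, pred_cls in pairs:
        if truth_cls == cls:
            if pred_cls == cls:
                tp += 1
            else:
                fn += 1
        else:
            if pred_cls == cls:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(cls, tpos=tp, tneg=tn, fpos=fp, fneg=fn)


@dataclass
class PerfReport:
    """Per-class performance over a scored instance set."""

    counts: dict[str, ConfusionCounts]
    n_instances: int

    def table(self) -> pd.DataFrame:
        """SENS/SPEC/ACCU per class in %, plus macro averages."""
        rows = []
        for cls in CLASS_ORDER:
            if cls not in self.counts:
                continue
            c = self.counts[cls]
            accu, sens, spec = perf(c)
            rows.append({
                "class": cls,
                "n": c.tpos + c.fneg,
                "SENS%": None if sens is None else 100 * sens,
                "SPEC%": None if spec is None else 100 * spec,
                "ACCU%": None if accu is None else 100 * accu,
            })
        df = pd.DataFrame(rows).set_index("class")
        df.loc["Average"] = [df["n"].sum(), df["SENS%"].mean(),
                             df["SPEC%"].mean(), df["ACCU%"].mean()]
        return df

    def sensitivity(self, cls: str) -> float | None:
        return perf(self.counts[cls])[1]

    def specificity(self, cls: str) -> float | None:
        return perf(self.counts[cls])[2]

    def accuracy(self, cls: str) -> float | None:
        return perf(self.counts[cls])[0]

    def macro_average(self) -> dict[str, float]:
        df = self.table()
        avg = df.loc["Average"]
        return {"SENS%": float(avg["SENS%"]), "SPEC%": float(avg["SPEC%"]),
                "ACCU%": float(avg["ACCU%"])}

    def to_csv(self, path) -> None:
        self.table().to_csv(path, float_format="%.2f")

    def to_dict(self) -> dict:
        out = {}
        for cls, c in self.counts.items():
            accu, sens, spec = perf(c)
            out[cls] = {"tpos": c.tpos, "tneg": c.tneg, "fpos": c.fpos,
                        "fneg": c.fneg, "sens": sens, "spec": spec,
                        "accu": accu}
        return out


def _event_spans(ann: AnnotationSet) -> list[tuple[str, int, int]]:
    """Events as (kind, start_sample, end_sample) via their member beats."""
    out = []
    idx = ann.r_indices
    for e in ann.events:
        if e.start_beat >= len(idx):
            continue
        last = min(e.end_beat, len(idx)) - 1
        out.append((e.kind, int(idx[e.start_beat]), int(idx[last]) + 1))
    return out


def _instance_pairs(pred: AnnotationSet, truth: AnnotationSet, fs: float,
                    tol_ms: float, scored_only: bool
                    ) -> list[tuple[str, str | None]]:
    pairs, _, _ = match_beats(pred.r_indices, truth.r_indices, fs, tol_ms)
    inst: list[tuple[str, str | None]] = []
    for ti, tb in enumerate(truth.beats):
        if scored_only and not tb.scored:
            continue
        if tb.label is BeatLabel.UNCLASSIFIED:
            continue
        if ti in pairs:
            plabel = pred.beats[pairs[ti]].label.value
            if plabel == BeatLabel.UNCLASSIFIED.value:
                plabel = None
        else:
            plabel = None
        inst.append((tb.label.value, plabel))
    pred_spans = _event_spans(pred)
    for kind, a, b in _event_spans(truth):
        hit = None
        for pk, pa, pb in pred_spans:
            if pa < b and a < pb:
                if pk == kind:
                    hit = kind
                    break
                hit = pk
        inst.append((kind, hit))
    return inst


def score_annotations(pred: AnnotationSet, truth: AnnotationSet, fs: float,
                      tol_ms: float = 75.0, scored_only: bool = True
                      ) -> PerfReport:
    """Score one record's predictions against ground truth."""
    return score_many([(pred, truth)], fs, tol_ms, scored_only)


def score_many(records: list[tuple[AnnotationSet, AnnotationSet]], fs: float,
               tol_ms: float = 75.0, scored_only: bool = True) -> PerfReport:
    """Pooled scoring over multiple (pred, truth) record pairs."""
    inst: list[tuple[str, str | None]] = []
    for pred, truth in records:
        inst.extend(_instance_pairs(pred, truth, fs, tol_ms, scored_only))
    counts = {cls: confusion_counts(inst, cls) for cls in CLASS_ORDER
              if any(cls in pair for pair in inst)}
    return PerfReport(counts=counts, n_instances=len(inst))
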