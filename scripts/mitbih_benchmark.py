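#!/usr/bin/env python
"""Optional benchmark on MIT-BIH arrhythmia database records.

Not part of the acceptance surface: the database must be obtained
separately (PhysioNet), and its reference annotations are distributed in
a binary format this package does not parse. Export them to CSV first,
one line per beat, ``sample,symbol`` (e.g. with ``rdann -r 100 -a atr``
post-processed to CSV); symbols N/L/R/e/j map to NB, A/a/J/S to APB,
V/E to VPB, everything else is ignored.

Usage:
    python scripts/mitbih_benchmark.py RECORD.hea RECORD.beats.csv [...]

Each positional pair is a WFDB header plus its beat CSV; per-record and
pooled NB/APB/VPB sensitivities are printed.
"""

from __future__ import annotations

import sys
from pathlib import Path

from ecgkit import (AnnotationSet, Beat, BeatLabel, PipelineConfig,
                    read_signal, run_pipeline, score_many)

SYMBOL_MAP = {
    "N": BeatLabel.NB, "L": BeatLabel.NB, "R": BeatLabel.NB,
    "e": BeatLabel.NB, "j": BeatLabel.NB,
    "A": BeatLabel.APB, "a": BeatLabel.APB, "J": BeatLabel.APB,
    "S": BeatLabel.APB,
    "V": BeatLabel.VPB, "E": BeatLabel.VPB,
}


def load_beat_csv(path: Path, fs: float) -> AnnotationSet:
    beats = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sample, symbol = line.split(",")[:2]
        label = SYMBOL_MAP.get(symbol.strip())
        if label is not None:
            beats.append(Beat(int(sample), label))
    return AnnotationSet(beats=beats, fs=fs)


def main(argv: list[str]) -> int:
    if len(argv) < 2 or len(argv) % 2:
        print(__doc__)
        return 2
    pairs = []
    for hea, csv in zip(argv[0::2], argv[1::2]):
        sig = read_signal(hea, format="wfdb")
        truth = load_beat_csv(Path(csv), sig.fs)
        result = run_pipeline(sig, PipelineConfig(trim_minutes=0.0))
        pairs.append((result.annotations, truth))
        rep = score_many([pairs[-1]], sig.fs)
        print(f"== {hea}")
        print(rep.table().to_string(float_format=lambda v: f"{v:.2f}"))
    if len(pairs) > 1:
        print("== pooled")
        print(score_many(pairs, sig.fs).table()
              .to_string(float_format=lambda v: f"{v:.2f}"))
    return 0


if __name__ == "__main__":
    raise SystemExit(main(sys.argv[1:]))
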