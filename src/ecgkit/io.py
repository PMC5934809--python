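"""Reading and writing ECG signals and beat/rhythm annotations.

Two native formats are provided — a diff-able CSV and a compact binary —
plus a reader for the WFDB header/signal dialect used by the MIT-BIH
arrhythmia database (integer samples converted to mV via the per-channel
gain and baseline declared in the ``.hea`` header).

All sample indices are 0-based; intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import enum
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "EcgSignal",
    "BeatLabel",
    "Beat",
    "RhythmEvent",
    "AnnotationSet",
    "FormatError",
    "read_signal",
    "write_signal",
    "read_annotations",
    "write_annotations",
]


class FormatError(ValueError):
    """Raised when a file does not parse in the named dialect."""


class BeatLabel(str, enum.Enum):
    """Per-beat rhythm class."""

    NB = "NB"            # normal sinus beat
    APB = "APB"          # atrial premature beat
    VPB = "VPB"          # ventricular premature beat
    UNCLASSIFIED = "UNCLASSIFIED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class EcgSignal:
    """Uniformly sampled single-lead voltage series.

    Parameters
    ----------
    samples : ndarray
        Voltage samples in mV.
    fs : float
        Sampling frequency in Hz; must be positive.
    lead : str
        Free-text lead label.
    t0 : float
        Start offset of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    lead: str = "ecg"
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (``t0`` offset included)."""
        return self.t0 + np.arange(len(self)) / self.fs

    def with_samples(self, samples: np.ndarray) -> "EcgSignal":
        return replace(self, samples=samples)


@dataclass(frozen=True)
class Beat:
    """A single annotated beat: R-peak sample index plus class label.

    ``scored`` marks beats that belong to the scored instance set of a
    ground-truth annotation (padding beats in the synthetic fixtures carry
    ``scored=False``); predictions always leave it True.
    """

    r_index: int
    label: BeatLabel
    scored: bool = True


@dataclass(frozen=True)
class RhythmEvent:
    """Run-level rhythm event over a half-open beat-ordinal range."""

    kind: str                 # "BG" or "TG"
    start_beat: int
    end_beat: int             # exclusive

    def __post_init__(self) -> None:
        if self.kind not in ("BG", "TG"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.end_beat > self.start_beat:
            raise ValueError("event range must be non-empty")

    def overlaps(self, other: "RhythmEvent") -> bool:
        return (self.start_beat < other.end_beat
                and other.start_beat < self.end_beat)


@dataclass
class AnnotationSet:
    """Beat annotations plus run-level rhythm events for one record."""

    beats: list[Beat] = field(default_factory=list)
    events: list[RhythmEvent] = field(default_factory=list)
    fs: float | None = None
    record_id: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx = [b.r_index for b in self.beats]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("beat r_index values must be strictly increasing")
        for kind in ("BG", "TG"):
            evs = sorted((e for e in self.events if e.kind == kind),
                         key=lambda e: e.start_beat)
            for a, b in zip(evs, evs[1:]):
                if a.overlaps(b):
                    raise ValueError(f"overlapping {kind} events: {a} / {b}")

    @property
    def r_indices(self) -> np.ndarray:
        return np.asarray([b.r_index for b in self.beats], dtype=np.int64)

    def labels(self) -> list[BeatLabel]:
        return [b.label for b in self.beats]

    def count(self, label: BeatLabel, scored_only: bool = False) -> int:
        return sum(1 for b in self.beats
                   if b.label is label and (b.scored or not scored_only))


# ---------------------------------------------------------------------------
# Native CSV signal format:  "# fs=<Hz> lead=<name> t0=<s>" then one mV/line
# ---------------------------------------------------------------------------

def _write_signal_csv(sig: EcgSignal, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs={sig.fs:.10g} lead={sig.lead} t0={sig.t0:.10g}\n")
        np.savetxt(fh, sig.samples, fmt="%.9f")


def _read_signal_csv(path: Path) -> EcgSignal:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise FormatError(f"{path}: missing '# fs=...' header line")
        meta: dict[str, str] = {}
        for tok in header.lstrip("#").split():
            if "=" not in tok:
                raise FormatError(f"{path}: malformed header token {tok!r}")
            key, val = tok.split("=", 1)
            meta[key] = val
        if "fs" not in meta:
            raise FormatError(f"{path}: header missing required field 'fs'")
        try:
            fs = float(meta["fs"])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric fs={meta['fs']!r}") from exc
        samples = np.loadtxt(fh, dtype=np.float64, ndmin=1)
    return EcgSignal(samples, fs=fs, lead=meta.get("lead", "ecg"),
                     t0=float(meta.get("t0", 0.0)))


# ---------------------------------------------------------------------------
# Native binary format: 16-byte header + little-endian float32 samples
#   magic b"ECGB" | fs float32 | n uint32 | t0 float32
# ---------------------------------------------------------------------------

_BIN_MAGIC = b"ECGB"
_BIN_HEADER = struct.Struct("<4sfIf")


def _write_signal_binary(sig: EcgSignal, path: Path) -> None:
    with open(path, "wb") as fh:
        fh.write(_BIN_HEADER.pack(_BIN_MAGIC, sig.fs, len(sig), sig.t0))
        fh.write(sig.samples.astype("<f4").tobytes())


def _read_signal_binary(path: Path) -> EcgSignal:
    with open(path, "rb") as fh:
        raw = fh.read(_BIN_HEADER.size)
        if len(raw) < _BIN_HEADER.size:
            raise FormatError(f"{path}: truncated binary header")
        magic, fs, n, t0 = _BIN_HEADER.unpack(raw)
        if magic != _BIN_MAGIC:
            raise FormatError(f"{path}: bad magic {magic!r} (field 'magic')")
        data = np.frombuffer(fh.read(4 * n), dtype="<f4")
        if data.size != n:
            raise FormatError(f"{path}: expected {n} samples, got {data.size}")
    return EcgSignal(data.astype(np.float64), fs=float(fs), t0=float(t0))


# ---------------------------------------------------------------------------
# WFDB header/signal dialect (MIT-BIH compatibility)
# ---------------------------------------------------------------------------

def _parse_wfdb_header(hea_path: Path) -> tuple[str, int, float, int, list[dict]]:
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{hea_path}: empty header")
    rec = lines[0].split()
    if len(rec) < 2:
        raise FormatError(f"{hea_path}: record line needs 'name nsig [fs [n]]'")
    name = rec[0].split("/")[0]
    try:
        nsig = int(rec[1])
    except ValueError as exc:
        raise FormatError(f"{hea_path}: bad signal count {rec[1]!r}") from exc
    fs = float(rec[2]) if len(rec) > 2 else 250.0
    nsamp = int(rec[3]) if len(rec) > 3 else 0
    chans = []
    for ln in lines[1:1 + nsig]:
        f = ln.split()
        if len(f) < 2:
            raise FormatError(f"{hea_path}: malformed signal line {ln!r}")
        fmt = f[1].split("x")[0].split(":")[0].split("+")[0]
        gain_tok = f[2] if len(f) > 2 else "200"
        gain_tok = gain_tok.split("/")[0]
        baseline = None
        if "(" in gain_tok:
            gain_str, base_str = gain_tok.rstrip(")").split("(")
            baseline = int(base_str)
        else:
            gain_str = gain_tok
        gain = float(gain_str) if float(gain_str) != 0 else 200.0
        adc_zero = int(f[4]) if len(f) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        chans.append({"file": f[0], "fmt": fmt, "gain": gain,
                      "baseline": baseline,
                      "desc": " ".join(f[9:]) if len(f) > 9 else ""})
    return name, nsig, fs, nsamp, chans


def _decode_fmt16(raw: bytes, nsig: int) -> np.ndarray:
    data = np.frombuffer(raw, dtype="<i2")
    n = data.size // nsig
    return data[: n * nsig].reshape(n, nsig).astype(np.int64)


def _decode_fmt212(raw: bytes, nsig: int) -> np.ndarray:
    """Unpack 12-bit two-sample triplets (the MIT-BIH storage format)."""
    b = np.frombuffer(raw, dtype=np.uint8)
    b = b[: 3 * (b.size // 3)].reshape(-1, 3).astype(np.int64)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    # sign-extend 12-bit two's complement
    first = np.where(first > 2047, first - 4096, first)
    second = np.where(second > 2047, second - 4096, second)
    flat = np.empty(first.size * 2, dtype=np.int64)
    flat[0::2], flat[1::2] = first, second
    n = flat.size // nsig
    return flat[: n * nsig].reshape(n, nsig)


def _read_signal_wfdb(path: Path, channel: int = 0) -> EcgSignal:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    name, nsig, fs, nsamp, chans = _parse_wfdb_header(hea)
    if not 0 <= channel < nsig:
        raise ValueError(f"channel {channel} out of range for {nsig} signals")
    ch = chans[channel]
    dat_path = hea.parent / ch["file"]
    raw = dat_path.read_bytes()
    if ch["fmt"] == "16":
        adus = _decode_fmt16(raw, nsig)
    elif ch["fmt"] == "212":
        adus = _decode_fmt212(raw, nsig)
    else:
        raise FormatError(f"{hea}: unsupported WFDB format {ch['fmt']!r} "
                          "(field 'format'; only 16 and 212 are supported)")
    if nsamp:
        adus = adus[:nsamp]
    mv = (adus[:, channel] - ch["baseline"]) / ch["gain"]
    return EcgSignal(mv, fs=fs, lead=ch["desc"] or f"ch{channel}")


def read_signal(path: str | Path, format: str = "native_csv",
                channel: int = 0) -> EcgSignal:
    """Read an ECG signal; ``format`` is one of native_csv / native_binary / wfdb.

    For the wfdb dialect the stored integers are converted to mV with the
    channel's gain (adu/mV) and baseline; ``channel`` selects the signal
    (first channel by default).
    """
    path = Path(path)
    if format == "wfdb":
        return _read_signal_wfdb(path, channel)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "native_csv":
        return _read_signal_csv(path)
    if format == "native_binary":
        return _read_signal_binary(path)
    raise ValueError(f"unknown signal format {format!r}")


def write_signal(sig: EcgSignal, path: str | Path,
                 format: str = "native_csv") -> None:
    path = Path(path)
    if format == "native_csv":
        _write_signal_csv(sig, path)
    elif format == "native_binary":
        _write_signal_binary(sig, path)
    else:
        raise ValueError(f"unknown signal format {format!r}")


# ---------------------------------------------------------------------------
# Annotation CSV: "# fs=<Hz> record=<id>", beat lines "sample,label[,scored]",
# event lines "kind,start_beat,end_beat"
# ---------------------------------------------------------------------------

def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    ann.validate()
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fs = "" if ann.fs is None else f"{ann.fs:.10g}"
        fh.write(f"# fs={fs} record={ann.record_id}\n")
        for b in ann.beats:
            fh.write(f"{b.r_index},{b.label.value},{int(b.scored)}\n")
        for e in ann.events:
            fh.write(f"{e.kind},{e.start_beat},{e.end_beat}\n")


def read_annotations(path: str | Path) -> AnnotationSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    beats: list[Beat] = []
    events: list[RhythmEvent] = []
    fs: float | None = None
    record_id = ""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise FormatError(f"{path}: missing annotation header line")
        for tok in header.lstrip("#").split():
            key, _, val = tok.partition("=")
            if key == "fs" and val:
                fs = float(val)
            elif key == "record":
                record_id = val
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if fields[0] in ("BG", "TG"):
                if len(fields) != 3:
                    raise FormatError(f"{path}:{lineno}: event line needs "
                                      "'kind,start_beat,end_beat'")
                events.append(RhythmEvent(fields[0], int(fields[1]),
                                          int(fields[2])))
            else:
                try:
                    r_index = int(fields[0])
                    label = BeatLabel(fields[1])
                except (ValueError, IndexError) as exc:
                    raise FormatError(
                        f"{path}:{lineno}: malformed beat line {line!r}") from exc
                scored = bool(int(fields[2])) if len(fields) > 2 else True
                beats.append(Beat(r_index, label, scored))
    return AnnotationSet(beats=beats, events=events, fs=fs, record_id=record_id)
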