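"""Synthetic single-lead ECG generator with exact beat-level ground truth.

Emulates a multi-parameter patient simulator driving a 150 Hz wearable
holter: scripted rhythms (normal sinus, atrial/ventricular premature
beats, bigeminy, trigeminy) are rendered as sums of Gaussian P-QRS-T
components so that every R sample, beat label and rhythm-run instance is
known exactly.  The ``simulator`` fixture profile produces 40
five-minute records at 150 Hz and 60 bpm whose summed ground-truth
instance counts are exactly 3120 NB, 240 APB, 240 VPB, 600 BG couplets
and 400 TG triplets.

Timing model: sinus beats sit on a 1000 ms grid (at 60 bpm) with bounded
Gaussian timing jitter; an atrial premature beat arrives at 0.6x the base
interval and is followed by a non-compensatory pause (prev+next interval
= 1.7x base); a ventricular premature beat arrives at 0.6x base with a
full compensatory pause plus a small margin (prev+next = 2x base + 40 ms)
so the pause comparison never sits exactly on the rule boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import AnnotationSet, Beat, BeatLabel, EcgSignal, RhythmEvent

__all__ = [
    "GaussComponent",
    "BeatMorphology",
    "NARROW_BEAT",
    "WIDE_BEAT",
    "APB_BEAT",
    "NoiseSpec",
    "GeneratorConfig",
    "generate_record",
    "generate_fixture_set",
    "inject_noise",
    "simulator_profile_script",
    "FIXTURE_COUNTS",
]

FIXTURE_COUNTS = {"NB": 3120, "APB": 240, "VPB": 240, "BG": 600,
                  "TG": 400}


@dataclass(frozen=True)
class GaussComponent:
    """One Gaussian bump: amplitude (mV), center offset from R (ms), sigma (ms)."""

    amp_mv: float
    center_ms: float
    sigma_ms: float


@dataclass(frozen=True)
class BeatMorphology:
    """Sum-of-Gaussians beat shape with a declared nominal QRS duration.

    ``qrs_span_ms`` reports the Q-onset-to-S-offset distance, taking each
    QRS component's onset/offset at 2 sigma from its center.
    """

    p: GaussComponent | None
    qrs: tuple[GaussComponent, ...]   # Q, R, S bumps (R must dominate)
    t: GaussComponent
    qrs_duration_ms: float            # nominal narrow (80) or wide (160)

    @property
    def qrs_span_ms(self) -> float:
        onset = min(c.center_ms - 2.0 * c.sigma_ms for c in self.qrs)
        offset = max(c.center_ms + 2.0 * c.sigma_ms for c in self.qrs)
        return offset - onset

    @property
    def components(self) -> tuple[GaussComponent, ...]:
        parts = tuple(self.qrs) + (self.t,)
        return parts + (self.p,) if self.p else parts


#: Narrow sinus beat: 80 ms QRS, upright T, sinus P.
NARROW_BEAT = BeatMorphology(
    p=GaussComponent(0.15, -170.0, 25.0),
    qrs=(GaussComponent(-0.12, -25.0, 7.5),    # Q
         GaussComponent(1.00, 0.0, 13.0),      # R
         GaussComponent(-0.18, 25.0, 7.5)),    # S
    t=GaussComponent(0.35, 260.0, 50.0),
    qrs_duration_ms=80.0,
)

#: Atrial premature beat: same narrow QRS, low ectopic P.
APB_BEAT = replace(NARROW_BEAT, p=GaussComponent(0.10, -150.0, 20.0))

#: Ventricular premature beat: 160 ms dome-shaped QRS, no P, discordant T.
WIDE_BEAT = BeatMorphology(
    p=None,
    qrs=(GaussComponent(-0.10, -60.0, 8.0),
         GaussComponent(1.80, 0.0, 40.0),
         GaussComponent(-0.08, 62.0, 8.0)),
    t=GaussComponent(-0.35, 280.0, 55.0),
    qrs_duration_ms=160.0,
)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive contamination: drift/powerline sinusoids, bursts, flatlines."""

    baseline_mv: float = 0.0           # 0.3 Hz baseline-drift amplitude
    baseline_hz: float = 0.3
    powerline_mv: float = 0.0          # 50 Hz interference amplitude
    powerline_hz: float = 50.0
    bursts: tuple[tuple[float, float, float], ...] = ()   # (start_s, dur_s, amp_mv)
    flatlines: tuple[tuple[float, float], ...] = ()       # (start_s, dur_s)

    @property
    def is_silent(self) -> bool:
        return (self.baseline_mv == 0 and self.powerline_mv == 0
                and not self.bursts and not self.flatlines)


@dataclass(frozen=True)
class GeneratorConfig:
    fs: float = 150.0
    duration_s: float = 300.0
    hr_bpm: float = 60.0
    #: (kind, count) instructions; kind in {NB, APB, VPB, BG, TG}.  For BG the
    #: count is VPB-NB couplets, for TG it is NB-NB-VPB triplets.  None means
    #: fill the record with sinus beats.
    rhythm_script: tuple[tuple[str, int], ...] | None = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    record_id: str = "synth"
    jitter_ms: float = 10.0            # sinus timing jitter sigma (clipped 3x)
    prematurity: float = 0.6           # premature interval / base interval
    apb_pause: float = 1.1             # APB next interval / base (non-comp.)
    vpb_pause_margin_ms: float = 40.0  # full pause overshoot past 2x base
    first_beat_s: float = 0.5
    #: None -> every NB beat scored; an int -> only that many eligible sinus
    #: NB beats per record are scored (the fixture-quota interpretation).
    nb_quota: int | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.hr_bpm <= 0 or self.duration_s <= 0:
            raise ValueError("fs, hr_bpm and duration_s must be positive")
        if self.rhythm_script is not None:
            kinds = {k for k, _ in self.rhythm_script}
            bad = kinds - {"NB", "APB", "VPB", "BG", "TG"}
            if bad:
                raise ValueError(f"unknown script kinds: {sorted(bad)}")


@dataclass
class _BeatSpec:
    t_ms: float
    label: BeatLabel
    morphology: BeatMorphology
    sinus_context: bool       # preceding interval was a plain sinus interval
    in_run: bool = False      # member of a BG/TG run


def _expand_script(config: GeneratorConfig,
                   rng: np.random.Generator
                   ) -> tuple[list[_BeatSpec], list[tuple[str, int, int]]]:
    """Lay out beat times/labels plus (kind, start_beat, end_beat) events."""
    base = 60000.0 / config.hr_bpm
    limit = config.duration_s * 1000.0
    jit = config.jitter_ms

    beats: list[_BeatSpec] = []
    events: list[tuple[str, int, int]] = []
    t = config.first_beat_s * 1000.0
    j_prev = 0.0
    pending: float | None = None   # forced interval into the next beat

    def jitter() -> float:
        return float(np.clip(rng.normal(0.0, jit), -3 * jit, 3 * jit)) if jit else 0.0

    def add_nb(in_run: bool = False) -> None:
        nonlocal t, j_prev, pending
        if pending is not None:
            t = t + pending
            pending = None
            beats.append(_BeatSpec(t, BeatLabel.NB, NARROW_BEAT,
                                   sinus_context=False, in_run=in_run))
            j_prev = 0.0
        else:
            j = jitter()
            t = t - j_prev + base + j
            beats.append(_BeatSpec(t, BeatLabel.NB, NARROW_BEAT,
                                   sinus_context=True, in_run=in_run))
            j_prev = j

    def add_premature(label: BeatLabel, morph: BeatMorphology,
                      next_interval: float, in_run: bool = False) -> None:
        nonlocal t, j_prev, pending
        t = t + config.prematurity * base
        beats.append(_BeatSpec(t, label, morph, sinus_context=False,
                               in_run=in_run))
        j_prev = 0.0
        pending = next_interval

    vpb_next = (2.0 - config.prematurity) * base + config.vpb_pause_margin_ms

    script = config.rhythm_script
    if script is None:
        script = (("NB", 10 ** 9),)   # sinus fill, bounded by duration below

    # first beat is always sinus
    beats.append(_BeatSpec(t, BeatLabel.NB, NARROW_BEAT, sinus_context=False))

    for kind, count in script:
        for _ in range(count):
            if kind == "NB":
                add_nb()
                if beats[-1].t_ms >= limit:
                    beats.pop()
                    if config.rhythm_script is not None:
                        raise ValueError(
                            "rhythm script does not fit into duration_s")
                    return beats, events
            elif kind == "APB":
                add_premature(BeatLabel.APB, APB_BEAT,
                              config.apb_pause * base)
            elif kind == "VPB":
                add_premature(BeatLabel.VPB, WIDE_BEAT, vpb_next)
            elif kind == "BG":
                start = len(beats)
                add_premature(BeatLabel.VPB, WIDE_BEAT, vpb_next, in_run=True)
                add_nb(in_run=True)
                events.append(("BG", start, start + 2))
            elif kind == "TG":
                start = len(beats)
                add_nb(in_run=True)
                add_nb(in_run=True)
                add_premature(BeatLabel.VPB, WIDE_BEAT, vpb_next, in_run=True)
                events.append(("TG", start, start + 3))
        if beats and beats[-1].t_ms >= limit:
            raise ValueError("rhythm script does not fit into duration_s")

    # sinus padding to fill the record
    while True:
        add_nb()
        if beats[-1].t_ms >= limit:
            beats.pop()
            break
    return beats, events


def _render(beats: list[_BeatSpec], config: GeneratorConfig) -> np.ndarray:
    n = int(round(config.duration_s * config.fs))
    x = np.zeros(n, dtype=np.float64)
    fs = config.fs
    for b in beats:
        r_sample = int(round(b.t_ms * fs / 1000.0))
        r_t_ms = r_sample * 1000.0 / fs
        for comp in b.morphology.components:
            half_ms = 5.0 * comp.sigma_ms
            lo = max(0, int(np.floor((r_t_ms + comp.center_ms - half_ms)
                                     * fs / 1000.0)))
            hi = min(n, int(np.ceil((r_t_ms + comp.center_ms + half_ms)
                                    * fs / 1000.0)) + 1)
            if hi <= lo:
                continue
            tt = np.arange(lo, hi) * 1000.0 / fs
            x[lo:hi] += comp.amp_mv * np.exp(
                -0.5 * ((tt - r_t_ms - comp.center_ms) / comp.sigma_ms) ** 2)
    return x


def _assign_scored(beats: list[_BeatSpec], quota: int | None) -> list[bool]:
    """Which beats belong to the scored instance set.

    Non-NB beats and run members keep their own scoring (ectopic beats are
    scored as beats; run members are scored through their events, so the
    beat flag is False).  For NB beats, either all are scored (quota None)
    or the first ``quota`` *eligible* sinus beats are: eligible means a
    plain sinus preceding interval (not a post-extrasystolic pause), not a
    run member, and not the first or last beat of the record.
    """
    scored = []
    taken = 0
    for i, b in enumerate(beats):
        if b.label is not BeatLabel.NB:
            scored.append(not b.in_run)
            continue
        if quota is None:
            scored.append(not b.in_run)
            continue
        eligible = (b.sinus_context and not b.in_run
                    and 0 < i < len(beats) - 1)
        if eligible and taken < quota:
            scored.append(True)
            taken += 1
        else:
            scored.append(False)
    if quota is not None and taken < quota:
        raise ValueError(
            f"record has only {taken} eligible sinus beats for a quota of {quota}")
    return scored


def generate_record(config: GeneratorConfig) -> tuple[EcgSignal, AnnotationSet]:
    """Render one annotated record (deterministic for a given seed)."""
    rng = np.random.default_rng(config.seed)
    beats, raw_events = _expand_script(config, rng)
    x = _render(beats, config)
    sig = EcgSignal(x, fs=config.fs, lead="synth-I")
    if not config.noise.is_silent:
        sig = inject_noise(sig, config.noise, rng)
    scored = _assign_scored(beats, config.nb_quota)
    ann = AnnotationSet(
        beats=[Beat(int(round(b.t_ms * config.fs / 1000.0)), b.label, s)
               for b, s in zip(beats, scored)],
        events=[RhythmEvent(k, a, b) for k, a, b in raw_events],
        fs=config.fs, record_id=config.record_id)
    return sig, ann


def inject_noise(sig: EcgSignal, noise: NoiseSpec,
                 rng: np.random.Generator | int | None = None) -> EcgSignal:
    """Add scripted contamination to a signal.

    Baseline drift and powerline interference are pure sinusoids; bursts
    are uniform random noise over their span; flatlines zero the span.
    Overlapping a flatline with a burst is rejected.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(sig)
    fs = sig.fs
    for fs_, fd in noise.flatlines:
        for bs, bd, _ in noise.bursts:
            if fs_ < bs + bd and bs < fs_ + fd:
                raise ValueError("overlapping flatline and burst spans")
    t = np.arange(n) / fs
    x = sig.samples.copy()
    if noise.baseline_mv:
        x += noise.baseline_mv * np.sin(2 * np.pi * noise.baseline_hz * t)
    if noise.powerline_mv:
        x += noise.powerline_mv * np.sin(2 * np.pi * noise.powerline_hz * t)
    for start_s, dur_s, amp in noise.bursts:
        a, b = int(round(start_s * fs)), int(round((start_s + dur_s) * fs))
        if a < 0 or b > n:
            raise ValueError(f"burst [{start_s}, {start_s + dur_s}] s outside record")
        x[a:b] += rng.uniform(-amp, amp, size=b - a)
    for start_s, dur_s in noise.flatlines:
        a, b = int(round(start_s * fs)), int(round((start_s + dur_s) * fs))
        if a < 0 or b > n:
            raise ValueError(f"flatline [{start_s}, {start_s + dur_s}] s outside record")
        x[a:b] = 0.0
    return sig.with_samples(x)


def simulator_profile_script() -> tuple[tuple[str, int], ...]:
    """Per-record rhythm script of the 40-record fixture profile.

    Each record carries 6 APB, 6 VPB, 3 bigeminy runs of 5 couplets and
    2 trigeminy runs of 5 triplets, separated by sinus blocks; summed over
    40 records this realizes the fixture totals (240 APB, 240 VPB, 600 BG
    couplets, 400 TG triplets), and an NB quota of 78 per record realizes
    the 3120 scored normal beats.
    """
    script: list[tuple[str, int]] = [("NB", 20)]
    for _ in range(3):
        script += [("APB", 1), ("NB", 8)]
    for _ in range(3):
        script += [("VPB", 1), ("NB", 8)]
    script += [("BG", 5), ("NB", 10), ("TG", 5), ("NB", 10)]
    for _ in range(3):
        script += [("APB", 1), ("NB", 8)]
    for _ in range(3):
        script += [("VPB", 1), ("NB", 8)]
    script += [("BG", 5), ("NB", 10), ("TG", 5), ("NB", 10), ("BG", 5)]
    return tuple(script)


NB_QUOTA_PER_RECORD = 78


def generate_fixture_set(profile: str = "simulator", seed: int = 0,
                         ) -> list[tuple[EcgSignal, AnnotationSet]]:
    """Generate the 40-record evaluation fixture.

    Records are 5 min at 150 Hz and 60 bpm; ground-truth instance totals
    are exactly ``FIXTURE_COUNTS``.  Different master seeds change
    only jitter realizations, never the instance counts.
    """
    if profile != "simulator":
        raise ValueError(f"unknown profile {profile!r}")
    script = simulator_profile_script()
    seeds = np.random.SeedSequence(seed).generate_state(40) % (2 ** 31)
    out = []
    for i in range(40):
        cfg = GeneratorConfig(rhythm_script=script, seed=int(seeds[i]),
                              record_id=f"synth{i:02d}",
                              nb_quota=NB_QUOTA_PER_RECORD)
        out.append(generate_record(cfg))
    return out
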