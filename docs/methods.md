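# Methods

This note documents the models and procedures implemented in `ecgkit`,
the parameters that matter, and the design decisions taken where the
design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal model and preprocessing

The input is a uniformly sampled single-lead voltage series in mV
(`EcgSignal`), natively 150 Hz wearable-holter data; a minimal
MIT-BIH-compatible reader (header parsing, formats 16 and 212,
gain/baseline conversion to mV) supports standard arrhythmia-database
records. All sample indices are 0-based and intervals half-open.

**Edge trimming** (`trim.minutes`, default 2 min for records longer than
10 min, 0 otherwise) drops the attach/detach transients of ambulatory
recordings.

**Band-pass filtering** is a Butterworth band-pass of order 3
(`filter.order`), 0.5–40 Hz (`filter.low_hz`, `filter.high_hz`), applied
forward-backward (`sosfiltfilt`) for zero phase. Zero phase matters
because QRS boundaries are later placed at fixed offsets around the R
sample; a causal IIR would shift R by its group delay. The band removes
baseline drift (< 0.5 Hz) and attenuates muscle noise and 50/60 Hz
powerline interference (measured single-tone gains in the tests: ≈ 1.0 at
10 Hz, < 0.01 at 60 Hz for 150 Hz sampling).

**Artifact masking** slides 2-s non-overlapping windows
(`artifact.window_s`) over the filtered record and compares each window's
peak-to-peak range against a running median *M* of the previous 30
windows (`artifact.history`; the first 30 windows use the global median
so a cold start does not false-flag). A window is flagged when

* range > 4·*M* (`artifact.burst_k`) — motion/electrode burst;
* either half-window range < 0.05 mV (`artifact.flat_mv`) — flatline /
  lead-off; halves are used because a dropout that straddles window
  boundaries, plus the high-pass ring-down at its edges, can keep a full
  window's range above the threshold;
* any |sample| ≥ 99 % of the recorder full-scale bound
  (`artifact.full_scale_mv`, default ±5 mV) — saturation.

Flagged samples form the `NoiseMask`; beats whose QRS window intersects
it are excluded from classification and template building. The exact
dynamic-threshold rule used with the original recorder hardware is not
public; this rule is this package's own concrete, testable formulation
and every constant is configurable.

## R-peak enhancement and detection

**Morphological transform.** Residual baseline is estimated as the
average of opening-then-closing and closing-then-opening with a flat
structuring element of 0.2 s (`morph.baseline_s`, longer than any QRS)
and subtracted; narrow peaks are then extracted as a top-hat (signal
minus opening) with a 0.06 s element (`morph.peak_s`, shorter than a
QRS), and the absolute value is returned. Element lengths in seconds are
converted to the nearest odd sample count. Two interchangeable backends
compute the erosions/dilations — a naive per-sample loop and a
stride-trick vectorized version — with identical edge handling
(edge-replication padding), so their outputs are bitwise equal and the
end-to-end annotations must agree exactly; this mirrors a serial/parallel
implementation split without asserting anything about wall-clock time.

**Adaptive detection.** Local maxima of the enhanced envelope are
accepted when they exceed `rdet.threshold_frac` (0.4) times the median of
the last 8 accepted peak amplitudes, initialized from the 98th percentile
of the first 10 s. A 200 ms refractory period (`rdet.refractory_ms`)
suppresses double-fires (within it, the larger peak wins); when no peak
has been accepted for 1.5× (`rdet.searchback_factor`) the running average
RR, the skipped stretch is re-scanned at half threshold (search-back), so
a premature wide beat with a smaller enhanced amplitude is still
recovered.

**Delineation.** Nominal QRS boundaries are placed 50 ms before and
80 ms after R (`qrs.pre_ms`, `qrs.post_ms`; at 150 Hz: 8 and 12 samples
with round-half-up), clipped at record edges. The QRS *width* used by the
classification rules is measured separately: within R ± 100 ms
(`qrs.width_window_ms`) the window is linearly detrended between its
endpoints (they lie outside the QRS by construction; the 0.5 Hz
high-pass leaves an inter-beat baseline offset of the same order as the
threshold) and the width is the duration of the contiguous stretch
around R where |x| stays above 10 % (`qrs.width_frac`) of |x| at R.
Fixed boundaries alone would force a constant 130 ms width on every beat
and make any narrow/wide rule degenerate, and the top-hat output is
unsuitable for width measurement because opening with a flat element of
length L clips a unimodal peak at its value L/2 away from the apex — the
top-hat bump's support saturates at L regardless of the true QRS width.

## Per-beat features

RR intervals are sample-index differences converted to ms. The running
average ⟨RR⟩ is causal (uses only already-seen intervals, excluding the
current one; with fewer than 8 seen, the mean of those available) and by
default *selective*: an interval enters the 8-deep history
(`features.avg_window`) only if it lies within (0.75, 1.2)× the current
average, the acceptance band of the classic two-average detection
heuristics. A plain mean is available (`features.selective = false`) but
is not the default because compensatory pauses corrupt it exactly where
it matters: in sustained bigeminy the window holds alternating 0.6·b and
~1.4·b intervals, so 2·⟨RR⟩ equals the premature beat's pause sum and the
VPB pause rule degenerates to a float-rounding coin flip, while in
trigeminy the window's phase bias pushes 2·⟨RR⟩ above any physiological
pause and in-run VPBs become unclassifiable. The selective average stays
anchored to the underlying sinus rate, which is what "average RR" means
in holter practice.

First/last beats have explicit `None` sentinels for the missing neighbor
interval — never a silent zero — and default to NB when narrow
(UNCLASSIFIED otherwise), since the premature-beat rules need both
neighbors.

## Classification

The beat rules are applied with strict inequalities exactly as stated in
the README table (`rules.wide_ms` = 120, `rules.rr_low` = 0.75,
`rules.rr_high` = 1.2, `rules.pause` = 2.0); a width of exactly 120 ms is
UNCLASSIFIED by construction. The three rules are mutually exclusive for
any feature vector (verified exhaustively over a feature grid in the
tests).

**Rhythm runs.** Bigeminy events are maximal alternations V N V N …
containing at least 3 VPBs (`events.bg_min`; clinical convention requires
three consecutive cycles, so a single couplet is not bigeminy), spanning
the first VPB through the normal beat after the last. Trigeminy events
are maximal (N N V)+ repetitions with at least 2 VPBs (`events.tg_min`),
extended over up to two trailing normals. UNCLASSIFIED beats count as
normal-like inside run patterns (`events.unclassified_as_normal`): the
beat that follows any compensatory pause has a preceding interval of
~1.44× the sinus average and therefore cannot satisfy the NB band, so a
literal reading would leave every bigeminy's in-run sinus beats
unclassified and no alternation would ever be found. Events do not
relabel their member beats; beat labels and events are reported
separately so beat-level rates stay well defined.

**Template reconfirmation.** The normal template is the pointwise mean of
the first 50 (`tmpl.max_beats`) noise-free NB windows of R ± 100 ms
(`tmpl.window_ms`), zero-meaned and unit-normalized. A VPB call whose
zero-mean normalized cross-correlation with the template reaches 0.9
(`tmpl.corr`) is demoted to NB: matching narrow morphology refutes the
wide-QRS premise. An APB call is demoted only when the morphology matches
*and* the prematurity is marginal (`rr_prev` ≥ 0.70·⟨RR⟩,
`tmpl.apb_guard`). The asymmetry is deliberate: an APB has a normal
narrow QRS by definition, so template agreement carries no evidence
against it (a measured true-APB correlation is ≈ 1.0), and unconditional
demotion would erase the class entirely; the guard still catches
normal beats pushed just past the 0.75 boundary by timing glitches.
Correction only ever demotes abnormal calls to NB — it never promotes —
and is idempotent. If no eligible NB beat exists the template is
unavailable and correction is skipped with a warning.

## Scoring

Predicted and true beats are paired greedily, nearest first, one-to-one,
within ±75 ms (`match_tol_ms`; the literature's common acceptance window
is 150 ms — half of it is used since beats here are 600 ms apart at
minimum). Scoring is one-vs-rest over the *scored instance universe*:
beat instances (NB/APB/VPB) and event instances (one BG instance per
couplet, one TG instance per triplet). A truth event counts as recovered
if any predicted event of the same kind overlaps it in time; an
overlapping event of the other kind counts against that kind. Unmatched
truth beats are detection misses (FNEG for their class). Rates with a
zero denominator are reported as not-available, never as silent zeros.

## The synthetic generator

`synth` emulates a bench signal generator driving a 150 Hz single-lead
holter. Beats are sums of Gaussian P-QRS-T components with exact, scripted
timing, so every R sample, label and run instance is known by
construction:

* narrow beats: R amplitude 1.0 mV (σ 13 ms), Q/S at ∓25 ms, upright T,
  sinus P; 2σ QRS span 80 ms. The atrial-premature variant differs only
  in a lower ectopic P.
* wide beats: dome-shaped R of 1.8 mV (σ 40 ms), no P, discordant T;
  2σ QRS span 160 ms.
* timing: sinus beats sit on the 60 bpm grid with Gaussian timing jitter
  (σ 10 ms, clipped at 3σ so beat counts are deterministic and the NB
  band is never violated by jitter alone); premature beats arrive at
  0.6× the base interval; the APB pause is non-compensatory
  (prev + next = 1.7× base) and the VPB pause is full plus a 40 ms margin
  (prev + next = 2× base + 40 ms). The margin keeps the pause-sum rule
  strictly decidable: an exactly-complete pause sits on the ≥ boundary,
  where the jitter-averaged reference interval flips the comparison sign
  essentially at random.

The fixture profile generates 40 five-minute records whose summed
ground-truth instances are exactly 3120 NB, 240 APB, 240 VPB, 600 BG
couplets and 400 TG triplets: per record, 6 isolated APBs, 6 isolated
VPBs, 3 bigeminy runs of 5 couplets and 2 trigeminy runs of 5 triplets
interleaved with sinus blocks, plus a per-record quota of 78 scored
sinus beats. Sinus beats beyond the quota are unscored padding; so are
run-member normal beats (scored through their events) and
post-compensatory sinus beats, which under the strict NB band are
structurally UNCLASSIFIED (their preceding interval is the pause). Both
scoring interpretations are available — `nb_quota=None` scores every
sinus beat — and the scorer's `scored_only` flag switches between them.
Different master seeds change jitter realizations only, never instance
counts.

What the generator does *not* emulate: morphology variability between
beats of the same class, respiratory and heart-rate-variability
modulation, P-wave visibility issues, electrode contact dynamics, or
multi-lead projection. Consequently, passing the fixture shows the
pipeline's logic is correct under clean, well-separated conditions — the
regime a bench simulator produces — and says little about performance on
noisy clinical recordings, where published results for this family of
methods are markedly lower.

## Numerical choices

* ms→samples conversion is round-half-up of ms·fs/1000 (50 ms at 150 Hz
  → 8 samples), fixed and documented so boundary placement is
  reproducible across sampling rates.
* Structuring-element lengths round to the nearest odd sample count so
  elements are centered.
* Morphology backends pad by edge replication; both compute identical
  windows, so equality is exact, not approximate.
* Normalized cross-correlation zero-means both windows; a zero-variance
  window correlates at 0.
* Degenerate inputs: empty enhanced signal → no peaks; fully masked
  record → empty annotation; all-flagged artifact mask is allowed and
  logged; template unavailable → correction skipped with a warning;
  zero-denominator rates → not-available.

## Problem sizes in tests

The default suite exercises 30–120 s records for unit-level checks, the
full 40-record (200 min) fixture for the acceptance checks, 20 seeds of
45 s records for backend-equivalence properties, and exhaustive
enumeration up to length-12 label sequences for the run-detector oracle;
the complete suite runs in well under a minute on one CPU.

## Known limitations

* The rule set classifies only NB/APB/VPB plus BG/TG runs; atrial
  fibrillation, flutter, and tachy-/brady-arrhythmias are out of scope.
* Width exactly 120 ms is deliberately unclassifiable under the strict
  inequalities; real-world implementations may prefer ≤/>.
* The WFDB reader handles single-channel extraction of formats 16 and
  212 only.
* Stage timings are measured and reported but hardware-dependent; no
  test or acceptance check asserts them.
* Scoring assumes pred and truth annotations share the record's sample
  clock; apply identical trimming to both when comparing.
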