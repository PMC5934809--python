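"""Judgment rules, rhythm-run detection (vs brute-force oracle), templates."""

import itertools

import numpy as np
import pytest

from ecgkit import (BeatLabel, PipelineConfig, bandpass_filter, build_template,
                    classify_beat, detect_rhythm_events, run_pipeline,
                    template_correct)
from ecgkit.classify import EventConfig, TemplateConfig, _ncc
from ecgkit.features import BeatFeature
from ecgkit.io import RhythmEvent
from ecgkit.qrs import ms_to_samples
from ecgkit.synth import GeneratorConfig, generate_record

FS = 150.0


def _feat(width, rr_prev, rr_next, avg, r=1000, idx=5, in_noise=False):
    return BeatFeature(beat_index=idx, r=r, rr_prev_ms=rr_prev,
                       rr_next_ms=rr_next, avg_rr_ms=avg, qrs_width_ms=width,
                       in_noise=in_noise)


class TestBeatRules:
    @pytest.mark.parametrize("width,rr_prev,rr_next,avg,expected", [
        (100, 1000, 1000, 1000, BeatLabel.NB),
        (100, 600, 1200, 1000, BeatLabel.APB),     # 600<750, 1800<2000
        (160, 700, 1400, 1000, BeatLabel.VPB),     # 700<750, 2100>=2000
        (120, 1000, 1000, 1000, BeatLabel.UNCLASSIFIED),  # exactly on boundary
        (120, 600, 1200, 1000, BeatLabel.UNCLASSIFIED),
        (100, 600, 1500, 1000, BeatLabel.UNCLASSIFIED),   # premature, full pause, narrow
        (160, 1000, 1000, 1000, BeatLabel.UNCLASSIFIED),  # wide but not premature
    ])
    def test_table_rules(self, width, rr_prev, rr_next, avg, expected):
        assert classify_beat(_feat(width, rr_prev, rr_next, avg)) is expected

    def test_undefined_neighbors_policy(self):
        assert classify_beat(_feat(100, None, 1000, 1000)) is BeatLabel.NB
        assert classify_beat(_feat(160, 1000, None, 1000)) is BeatLabel.UNCLASSIFIED

    def test_rule_partition_exhaustive_grid(self):
        """At most one of the NB/APB/VPB predicates fires for any features."""
        widths = [60, 100, 119, 120, 121, 140, 180]
        rrs = range(300, 1601, 100)
        avgs = range(600, 1401, 200)
        for w, rp, rn, avg in itertools.product(widths, rrs, rrs, avgs):
            # independent restatement of the three rules
            nb = w < 120 and 0.75 * avg < rp < 1.2 * avg
            apb = w < 120 and rp < 0.75 * avg and rp + rn < 2 * avg
            vpb = w > 120 and rp < 0.75 * avg and rp + rn >= 2 * avg
            assert nb + apb + vpb <= 1
            got = classify_beat(_feat(w, float(rp), float(rn), float(avg)))
            expected = (BeatLabel.NB if nb else BeatLabel.APB if apb
                        else BeatLabel.VPB if vpb else BeatLabel.UNCLASSIFIED)
            assert got is expected


def _oracle_events(labels, bg_min=3, tg_min=2):
    """Brute-force run detector: direct scanning, no regex.

    Mirrors the documented semantics: maximal V(NV)* alternations with
    >= bg_min VPBs (extended over one trailing normal); maximal (NNV)+
    blocks with >= tg_min VPBs, extended over up to two trailing normals
    but never into the next block.
    """
    s = ["V" if l is BeatLabel.VPB else
         "N" if l in (BeatLabel.NB, BeatLabel.UNCLASSIFIED) else "x"
         for l in labels]
    n = len(s)
    events = []

    # BG: scan for alternating segments starting at a V
    i = 0
    while i < n:
        if s[i] != "V":
            i += 1
            continue
        j = i
        while j + 2 < n and s[j + 1] == "N" and s[j + 2] == "V":
            j += 2
        n_v = (j - i) // 2 + 1
        if n_v >= bg_min:
            end = j + 1
            if end < n and s[end] == "N":
                end += 1
            events.append(RhythmEvent("BG", i, end))
        i = j + 1

    # TG: scan for (NNV)+ blocks
    blocks = []
    i = 0
    while i + 2 < n:
        if s[i] == "N" and s[i + 1] == "N" and s[i + 2] == "V":
            j = i
            while j + 2 < n and s[j] == "N" and s[j + 1] == "N" and s[j + 2] == "V":
                j += 3
            blocks.append((i, j))
            i = j
        else:
            i += 1
    for k, (a, b) in enumerate(blocks):
        if (b - a) // 3 < tg_min:
            continue
        limit = blocks[k + 1][0] if k + 1 < len(blocks) else n
        end = b
        for _ in range(2):
            if end < min(n, limit) and s[end] == "N":
                end += 1
        events.append(RhythmEvent("TG", a, end))
    return sorted(events, key=lambda e: (e.start_beat, e.kind))


class TestRhythmEvents:
    def test_bigeminy_example(self):
        labels = [BeatLabel.VPB, BeatLabel.NB] * 3
        events = detect_rhythm_events(labels)
        assert events == [RhythmEvent("BG", 0, 6)]

    def test_trigeminy_example(self):
        labels = [BeatLabel.NB, BeatLabel.NB, BeatLabel.VPB] * 2 + \
                 [BeatLabel.NB, BeatLabel.NB]
        events = detect_rhythm_events(labels)
        assert events == [RhythmEvent("TG", 0, 8)]

    def test_all_normal_no_events(self):
        assert detect_rhythm_events([BeatLabel.NB] * 20) == []

    def test_couplet_below_minimum_ignored(self):
        labels = [BeatLabel.NB, BeatLabel.VPB, BeatLabel.NB, BeatLabel.VPB,
                  BeatLabel.NB]
        assert detect_rhythm_events(labels) == []

    def test_unclassified_counts_as_normal_by_default(self):
        labels = [BeatLabel.VPB, BeatLabel.UNCLASSIFIED] * 3
        assert detect_rhythm_events(labels) == [RhythmEvent("BG", 0, 6)]
        off = EventConfig(unclassified_as_normal=False)
        assert detect_rhythm_events(labels, off) == []

    def test_matches_oracle_exhaustively(self):
        """Regex detector == brute-force oracle on all {NB,VPB}^<=12."""
        for length in range(1, 13):
            for bits in itertools.product([BeatLabel.NB, BeatLabel.VPB],
                                          repeat=length):
                labels = list(bits)
                assert detect_rhythm_events(labels) == _oracle_events(labels), labels


@pytest.fixture(scope="module")
def prepared(nsr_record):
    sig, ann = nsr_record
    res = run_pipeline(sig, PipelineConfig())
    filt = bandpass_filter(sig)
    return sig, ann, res, filt


class TestTemplate:
    def test_template_length(self, prepared):
        _, _, res, filt = prepared
        tmpl = build_template(filt, res.features, res.labels)
        assert tmpl.waveform.size == 2 * round(100 * FS / 1000) + 1

    def test_template_matches_held_out_beat(self, prepared):
        _, ann, res, filt = prepared
        tmpl = build_template(filt, res.features, res.labels,
                              TemplateConfig(max_beats=50))
        assert tmpl.n_beats == 50
        half = ms_to_samples(100, FS)
        r = ann.r_indices[80]   # beyond the 50 used to build it
        w = filt.samples[r - half:r + half + 1]
        assert _ncc(w, tmpl.waveform) >= 0.95

    def test_identical_beats_template_equals_one_beat(self, prepared):
        _, ann, res, filt = prepared
        tmpl = build_template(filt, res.features, res.labels)
        half = ms_to_samples(100, FS)
        r = res.features[10].r
        w = filt.samples[r - half:r + half + 1]
        assert _ncc(w, tmpl.waveform) >= 0.999

    def test_no_eligible_beats_returns_none(self, prepared):
        _, _, res, filt = prepared
        labels = [BeatLabel.VPB] * len(res.features)
        assert build_template(filt, res.features, labels) is None

    def test_true_vpb_not_demoted(self, prepared):
        _, _, res, filt = prepared
        tmpl = build_template(filt, res.features, res.labels)
        sigv, annv = generate_record(GeneratorConfig(
            duration_s=60, seed=6,
            rhythm_script=(("NB", 10), ("VPB", 1), ("NB", 10))))
        resv = run_pipeline(sigv, PipelineConfig())
        assert BeatLabel.VPB in resv.labels
        filtv = bandpass_filter(sigv)
        tmplv = build_template(filtv, resv.features, resv.labels)
        corrected = template_correct(resv.labels, filtv, resv.features, tmplv)
        assert corrected == resv.labels   # run_pipeline already corrected

    def test_marginal_apb_glitch_demoted(self, prepared):
        """A normal-morphology beat called APB on a marginal RR glitch
        correlates with the template and is relabeled NB."""
        _, _, res, filt = prepared
        tmpl = build_template(filt, res.features, res.labels)
        feats = list(res.features)
        labels = list(res.labels)
        f = feats[20]
        glitch = BeatFeature(beat_index=f.beat_index, r=f.r,
                             rr_prev_ms=0.73 * f.avg_rr_ms,
                             rr_next_ms=f.rr_next_ms, avg_rr_ms=f.avg_rr_ms,
                             qrs_width_ms=f.qrs_width_ms, in_noise=False)
        feats[20] = glitch
        assert classify_beat(glitch) is BeatLabel.APB
        labels[20] = BeatLabel.APB
        corrected = template_correct(labels, filt, feats, tmpl)
        assert corrected[20] is BeatLabel.NB

    def test_clearly_premature_apb_kept(self, prepared):
        _, _, res, filt = prepared
        tmpl = build_template(filt, res.features, res.labels)
        feats = list(res.features)
        labels = list(res.labels)
        f = feats[30]
        apb = BeatFeature(beat_index=f.beat_index, r=f.r,
                          rr_prev_ms=0.6 * f.avg_rr_ms,
                          rr_next_ms=1.1 * f.avg_rr_ms, avg_rr_ms=f.avg_rr_ms,
                          qrs_width_ms=f.qrs_width_ms, in_noise=False)
        feats[30] = apb
        labels[30] = BeatLabel.APB
        corrected = template_correct(labels, filt, feats, tmpl)
        assert corrected[30] is BeatLabel.APB

    def test_no_abnormal_labels_identity(self, prepared):
        _, _, res, filt = prepared
        tmpl = build_template(filt, res.features, res.labels)
        labels = [BeatLabel.NB] * len(res.features)
        assert template_correct(labels, filt, res.features, tmpl) == labels

    def test_idempotent(self, prepared):
        sigm, annm = generate_record(GeneratorConfig(
            duration_s=120, seed=13,
            rhythm_script=(("NB", 20), ("VPB", 1), ("NB", 10), ("APB", 1),
                           ("NB", 10), ("BG", 4), ("NB", 10))))
        resm = run_pipeline(sigm, PipelineConfig())
        filtm = bandpass_filter(sigm)
        tmpl = build_template(filtm, resm.features, resm.labels)
        once = template_correct(resm.labels, filtm, resm.features, tmpl)
        twice = template_correct(once, filtm, resm.features, tmpl)
        assert once == twice

    def test_missing_template_is_noop(self, prepared):
        _, _, res, filt = prepared
        labels = list(res.labels)
        assert template_correct(labels, filt, res.features, None) == labels
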