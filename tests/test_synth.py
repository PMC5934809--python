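"""Generator contracts: timing, morphology, determinism, fixture counts."""

import collections

import numpy as np
import pytest

from ecgkit import BeatLabel, PipelineConfig, bandpass_filter, run_pipeline
from ecgkit.qrs import delineate_qrs, morphological_transform
from ecgkit.synth import (APB_BEAT, GeneratorConfig, NARROW_BEAT, NoiseSpec,
                          FIXTURE_COUNTS, WIDE_BEAT,
                          generate_fixture_set, generate_record, inject_noise,
                          simulator_profile_script)

FS = 150.0


class TestMorphologies:
    @pytest.mark.parametrize("morph,nominal", [
        (NARROW_BEAT, 80.0), (APB_BEAT, 80.0), (WIDE_BEAT, 160.0)])
    def test_qrs_span_matches_nominal(self, morph, nominal):
        assert abs(morph.qrs_span_ms - nominal) <= 5.0

    def test_r_dominates(self):
        for morph in (NARROW_BEAT, APB_BEAT, WIDE_BEAT):
            q, r, s = morph.qrs
            assert r.amp_mv > abs(q.amp_mv) and r.amp_mv > abs(s.amp_mv)


class TestGenerateRecord:
    def test_all_nb_5min_exact_beats(self):
        sig, ann = generate_record(GeneratorConfig(seed=1, jitter_ms=0.0))
        assert len(sig) == 45000
        assert len(ann.beats) == 300
        rr = np.diff(ann.r_indices) * 1000 / FS
        np.testing.assert_allclose(rr, 1000.0)
        assert all(b.label is BeatLabel.NB for b in ann.beats)

    def test_beat_count_stable_under_jitter(self):
        for seed in range(5):
            _, ann = generate_record(GeneratorConfig(seed=seed))
            assert len(ann.beats) == 300

    def test_deterministic_for_seed(self):
        a_sig, a_ann = generate_record(GeneratorConfig(seed=7))
        b_sig, b_ann = generate_record(GeneratorConfig(seed=7))
        np.testing.assert_array_equal(a_sig.samples, b_sig.samples)
        assert a_ann.beats == b_ann.beats

    def test_seed_changes_jitter_not_structure(self):
        script = simulator_profile_script()
        a = generate_record(GeneratorConfig(rhythm_script=script, seed=1,
                                            nb_quota=78))[1]
        b = generate_record(GeneratorConfig(rhythm_script=script, seed=2,
                                            nb_quota=78))[1]
        assert [x.label for x in a.beats] == [x.label for x in b.beats]
        assert a.events == b.events
        assert any(x.r_index != y.r_index for x, y in zip(a.beats, b.beats))

    def test_annotation_fidelity(self, mixed_record):
        """Signal argmax within +/-30 ms of each annotated R is the R sample."""
        sig, ann = mixed_record
        half = int(round(0.030 * FS))
        for b in ann.beats:
            lo = b.r_index - half
            w = sig.samples[lo:b.r_index + half + 1]
            assert lo + int(np.argmax(w)) == b.r_index

    def test_apb_timing(self, mixed_record):
        """APBs are premature (0.6x) with a non-compensatory pause."""
        _, ann = mixed_record
        idx = ann.r_indices
        for i, b in enumerate(ann.beats):
            if b.label is BeatLabel.APB:
                rr_prev = (idx[i] - idx[i - 1]) * 1000 / FS
                rr_next = (idx[i + 1] - idx[i]) * 1000 / FS
                assert rr_prev == pytest.approx(600.0, abs=40)
                assert rr_prev + rr_next < 2000.0

    def test_vpb_timing(self, mixed_record):
        """VPBs are premature with a (slightly over-)complete pause."""
        _, ann = mixed_record
        idx = ann.r_indices
        for i, b in enumerate(ann.beats):
            if b.label is BeatLabel.VPB:
                rr_prev = (idx[i] - idx[i - 1]) * 1000 / FS
                rr_next = (idx[i + 1] - idx[i]) * 1000 / FS
                assert rr_prev == pytest.approx(600.0, abs=40)
                assert rr_prev + rr_next >= 2000.0

    def test_vpb_delineates_wide(self):
        sig, ann = generate_record(GeneratorConfig(
            duration_s=30, seed=2, rhythm_script=(("NB", 5), ("VPB", 1),
                                                  ("NB", 5))))
        filt = bandpass_filter(sig)
        enh = morphological_transform(filt)
        vr = [b.r_index for b in ann.beats if b.label is BeatLabel.VPB]
        q = delineate_qrs(filt, np.array(vr), enh)[0]
        assert q.width_ms > 120

    def test_overlong_script_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            generate_record(GeneratorConfig(duration_s=30,
                                            rhythm_script=(("NB", 100),)))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            GeneratorConfig(rhythm_script=(("AF", 3),))


class TestInjectNoise:
    def test_zero_spec_identity(self, nsr_record):
        sig, _ = nsr_record
        out = inject_noise(sig, NoiseSpec(), rng=0)
        np.testing.assert_array_equal(out.samples, sig.samples)

    def test_baseline_amplitude(self):
        sig, _ = generate_record(GeneratorConfig(duration_s=100, seed=3))
        out = inject_noise(sig, NoiseSpec(baseline_mv=0.5), rng=0)
        drift = out.samples - sig.samples
        # single-bin amplitude estimate at 0.3 Hz over an integer period count
        n = int(30 / 0.3 * FS)
        t = np.arange(n) / FS
        amp = 2 * abs(np.mean(drift[:n] * np.exp(-2j * np.pi * 0.3 * t)))
        assert amp == pytest.approx(0.5, abs=0.01)

    def test_powerline_component(self):
        sig, _ = generate_record(GeneratorConfig(duration_s=60, seed=3))
        out = inject_noise(sig, NoiseSpec(powerline_mv=0.2, powerline_hz=50.0),
                           rng=0)
        drift = out.samples - sig.samples
        n = int(10 * FS)
        t = np.arange(n) / FS
        amp = 2 * abs(np.mean(drift[:n] * np.exp(-2j * np.pi * 50.0 * t)))
        assert amp == pytest.approx(0.2, abs=0.01)

    def test_flatline_zeroes_span(self, nsr_record):
        sig, _ = nsr_record
        out = inject_noise(sig, NoiseSpec(flatlines=((10.0, 2.0),)), rng=0)
        assert (out.samples[int(10 * FS):int(12 * FS)] == 0).all()

    def test_overlapping_flatline_burst_rejected(self, nsr_record):
        sig, _ = nsr_record
        spec = NoiseSpec(bursts=((10.0, 2.0, 1.0),), flatlines=((11.0, 2.0),))
        with pytest.raises(ValueError, match="overlap"):
            inject_noise(sig, spec, rng=0)

    def test_out_of_record_burst_rejected(self, nsr_record):
        sig, _ = nsr_record
        with pytest.raises(ValueError, match="outside"):
            inject_noise(sig, NoiseSpec(bursts=((119.0, 5.0, 1.0),)), rng=0)


@pytest.fixture(scope="module")
def fixture(request):
    return generate_fixture_set(seed=0)


class TestFixtureSet:
    def test_forty_records_5min_150hz(self, fixture):
        assert len(fixture) == 40
        for sig, _ in fixture:
            assert sig.fs == 150.0
            assert sig.duration_s == 300.0

    def test_instance_totals_exact(self, fixture):
        totals = collections.Counter()
        for _, ann in fixture:
            for b in ann.beats:
                if b.scored:
                    totals[b.label.value] += 1
            for e in ann.events:
                totals[e.kind] += 1
        assert dict(totals) == FIXTURE_COUNTS

    def test_counts_seed_invariant(self):
        other = generate_fixture_set(seed=123)
        totals = collections.Counter()
        for _, ann in other:
            for b in ann.beats:
                if b.scored:
                    totals[b.label.value] += 1
            for e in ann.events:
                totals[e.kind] += 1
        assert dict(totals) == FIXTURE_COUNTS

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError):
            generate_fixture_set("other")
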