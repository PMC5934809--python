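"""Shared fixtures: synthetic records and cached pipeline runs."""

from __future__ import annotations

import pytest

from ecgkit import PipelineConfig, run_pipeline
from ecgkit.synth import GeneratorConfig, generate_record, simulator_profile_script

FS = 150.0


@pytest.fixture(scope="session")
def nsr_record():
    """Two minutes of clean normal sinus rhythm at 60 bpm."""
    return generate_record(GeneratorConfig(duration_s=120.0, seed=42))


@pytest.fixture(scope="session")
def mixed_record():
    """One full-profile 5-min record (APB/VPB/BG/TG plus sinus) with NB quota."""
    return generate_record(GeneratorConfig(
        rhythm_script=simulator_profile_script(), seed=3, nb_quota=78))


@pytest.fixture(scope="session")
def mixed_result(mixed_record):
    sig, ann = mixed_record
    return run_pipeline(sig, PipelineConfig(), truth=ann)
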