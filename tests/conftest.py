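import pytest

from ppgarr.preprocess import PreprocConfig, Waveform, preprocess_record
from ppgarr.synth import (
    DEFAULT_SPECS,
    NOISE_FREE,
    RhythmSpec,
    synth_pulsatile_record,
    synth_record,
)

FS = 250.0


@pytest.fixture(scope="session")
def clean_normal_record():
    """Noise-free fixed-rate (75 bpm) record: onsets every 0.8 s."""
    spec = RhythmSpec("normal", (75.0, 75.0), 0.0, 0.0, 0.45)
    return synth_pulsatile_record(spec, NOISE_FREE, 20.0, FS, seed=0)


@pytest.fixture(scope="session")
def clean_normal_segments(clean_normal_record):
    return preprocess_record(
        Waveform(clean_normal_record.samples, FS), PreprocConfig(), "rec0", "normal"
    )


@pytest.fixture(scope="session")
def vf_segments():
    rec = synth_record(DEFAULT_SPECS["vf"], duration_s=30.0, fs=FS, seed=3)
    return preprocess_record(Waveform(rec.samples, FS), PreprocConfig(), "vf0", "vf")


@pytest.fixture(scope="session")
def small_feature_table():
    """Feature table for a small balanced synthetic dataset (6 records/class, 30 s)."""
    from ppgarr.features import build_feature_table
    from ppgarr.synth import generate_records

    records = generate_records(6, 30.0, FS, global_seed=7)
    return build_feature_table(records)
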