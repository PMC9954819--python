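import numpy as np
import pytest

from deepeeg.models import ModelConfig
from deepeeg.preprocess import SegmentSet, minmax_scale, segment_recordings, zscore
from deepeeg.synth import SynthSpec, generate_labeled_dataset
from deepeeg.training import TrainConfig

#: low-rate band mix that respects Nyquist at fs = 64 Hz
LOWRATE_BANDS = {"delta": 1.0, "theta": 0.7, "alpha": 0.8, "beta": 0.3}


def tiny_spec(seed=0, n_channels=4, fs=64.0, gain=5.0) -> SynthSpec:
    """Small, fast synthetic-EEG spec for unit tests."""
    return SynthSpec(
        fs=fs,
        n_channels=n_channels,
        band_powers=dict(LOWRATE_BANDS),
        ictal_amp_gain=gain,
        seed=seed,
    )


def tiny_model_config(**overrides) -> ModelConfig:
    """Narrow model (same topology) for fast training tests."""
    base = dict(
        encoder_filters=(4, 4, 8, 8),
        decoder_filters=(8, 4, 4, 1),
        bilstm_units=8,
        dense_units=10,
        dropout_rate=0.25,
        seed=0,
    )
    base.update(overrides)
    return ModelConfig(**base)


def make_labeled_segments(
    n_records=24, duration_s=30.0, segment_length_s=1.0, seed=0, **spec_kw
) -> SegmentSet:
    """Labeled segments from a tiny synthetic cohort (both classes)."""
    spec = tiny_spec(seed=seed, **spec_kw)
    recs = generate_labeled_dataset(
        spec, n_records=n_records, seizure_fraction=0.5, duration_s=duration_s
    )
    return segment_recordings(recs, segment_length_s)


def normalized(segments: SegmentSet) -> SegmentSet:
    out, params = zscore(segments)
    out, _ = minmax_scale(out, params)
    return out


@pytest.fixture(scope="session")
def tiny_segments() -> SegmentSet:
    """Session-wide small labeled segment set (4 ch, 64 samples/segment)."""
    return make_labeled_segments(seed=7)


@pytest.fixture()
def fast_train_config() -> TrainConfig:
    return TrainConfig(epochs=2, batch_size=16, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
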