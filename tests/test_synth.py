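"""Synthetic EEG generator: spectra, seizures, artifacts, cohorts."""

import numpy as np
import pytest
from scipy import signal as sps

from conftest import LOWRATE_BANDS, tiny_spec
from deepeeg.annotations import parse_annotation_summary
from deepeeg.edf import read_edf
from deepeeg.errors import ConfigurationError
from deepeeg.synth import (
    ArtifactConfig,
    SynthSpec,
    add_artifacts,
    generate_background,
    generate_labeled_dataset,
    inject_ictal,
    write_cohort,
)


def _peak_freq(x, fs):
    freqs, psd = sps.periodogram(x, fs=fs)
    return freqs[np.argmax(psd)]


def _band_fraction(x, fs, lo, hi):
    freqs, psd = sps.welch(x, fs=fs, nperseg=min(1024, x.shape[-1]))
    sel = (freqs >= lo) & (freqs <= hi)
    return psd[..., sel].sum() / psd.sum()


class TestBackground:
    def test_sample_count(self):
        rec = generate_background(SynthSpec(n_channels=3, seed=0), 10.0)
        assert rec.n_samples == 2560
        assert rec.n_channels == 3
        assert rec.annotations == []

    def test_alpha_only_spectrum_peaks_in_band_every_channel(self):
        spec = SynthSpec(
            n_channels=6, band_powers={"alpha": 1.0}, seed=1
        )
        rec = generate_background(spec, 30.0)
        for ch in range(rec.n_channels):
            peak = _peak_freq(rec.signal[ch], rec.fs)
            assert 8.0 <= peak <= 13.0, f"channel {ch} peaks at {peak} Hz"

    def test_deterministic_under_seed(self):
        spec = SynthSpec(n_channels=4, seed=42)
        a = generate_background(spec, 5.0)
        b = generate_background(spec, 5.0)
        assert np.array_equal(a.signal, b.signal)

    def test_channels_are_correlated(self):
        rec = generate_background(SynthSpec(n_channels=8, seed=3), 20.0)
        corr = np.corrcoef(rec.signal)
        off_diag = np.abs(corr[np.triu_indices(8, k=1)])
        assert off_diag.max() > 0.1

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ConfigurationError, match="Nyquist"):
            SynthSpec(fs=64.0, band_powers={"gamma": 1.0})

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_background(SynthSpec(seed=0), 0.0)


class TestInjectIctal:
    @pytest.fixture()
    def background(self):
        return generate_background(tiny_spec(seed=5, fs=256.0,
                                             n_channels=4), 30.0)

    def test_amplitude_and_annotation(self, background):
        spec = tiny_spec(seed=5, fs=256.0, n_channels=4, gain=5.0)
        rec = inject_ictal(background, 10.0, 20.0, spec)
        assert len(rec.annotations) == 1
        i0, i1 = int(10 * rec.fs), int(20 * rec.fs)
        inside = rec.signal[:, i0:i1].std()
        outside_mask = np.ones(rec.n_samples, bool)
        outside_mask[i0:i1] = False
        outside = rec.signal[:, outside_mask].std()
        assert inside >= 2.5 * outside

    def test_dominant_frequency_is_discharge_rate(self, background):
        spec = tiny_spec(seed=5, fs=256.0, n_channels=4)
        rec = inject_ictal(background, 10.0, 20.0, spec)
        i0, i1 = int(10 * rec.fs), int(20 * rec.fs)
        for ch in range(rec.n_channels):
            peak = _peak_freq(rec.signal[ch, i0:i1], rec.fs)
            assert 2.5 <= peak <= 3.5

    def test_zero_length_interval_rejected(self, background):
        spec = tiny_spec(fs=256.0, n_channels=4)
        with pytest.raises(ValueError):
            inject_ictal(background, 10.0, 10.0, spec)

    def test_overlapping_intervals_rejected(self, background):
        spec = tiny_spec(fs=256.0, n_channels=4)
        rec = inject_ictal(background, 10.0, 20.0, spec)
        with pytest.raises(ValueError, match="overlap"):
            inject_ictal(rec, 15.0, 25.0, spec)

    def test_out_of_range_interval_rejected(self, background):
        spec = tiny_spec(fs=256.0, n_channels=4)
        with pytest.raises(ValueError):
            inject_ictal(background, 25.0, 45.0, spec)


class TestArtifacts:
    @pytest.fixture()
    def background(self):
        return generate_background(SynthSpec(n_channels=4, seed=9), 60.0)

    def test_all_zero_amplitudes_is_noop(self, background):
        out = add_artifacts(background, ArtifactConfig())
        assert np.array_equal(out.signal, background.signal)

    def test_emg_component_band_limited(self, background):
        cfg = ArtifactConfig(emg_amplitude_uv=10.0)
        out = add_artifacts(background, cfg, seed=2)
        added = out.signal - background.signal
        assert _band_fraction(added, background.fs, 20.0, 60.0) >= 0.9

    def test_white_noise_variance(self):
        # ~4e5 samples: sample variance within a generous chi-square CI
        rec = generate_background(SynthSpec(n_channels=4, seed=11), 400.0)
        cfg = ArtifactConfig(white_noise_sigma_uv=1.0)
        out = add_artifacts(rec, cfg, seed=3)
        added = out.signal - rec.signal
        assert 0.97 <= added.var() <= 1.03

    def test_blinks_only_on_frontal_channels_and_slow(self, background):
        cfg = ArtifactConfig(blink_amplitude_uv=50.0, frontal_channels=(0, 1))
        out = add_artifacts(background, cfg, seed=4)
        added = out.signal - background.signal
        assert np.all(added[2:] == 0)
        blink = added[0]
        assert blink.any()
        assert _band_fraction(blink, background.fs, 0.0, 2.0) >= 0.9


class TestCohort:
    def test_counts_and_single_seizure(self):
        spec = tiny_spec(seed=1)
        recs = generate_labeled_dataset(spec, 20, 0.5, duration_s=20.0)
        assert len(recs) == 20
        annotated = [r for r in recs if r.annotations]
        assert len(annotated) == 10
        assert all(len(r.annotations) == 1 for r in annotated)

    def test_deterministic_cohort(self):
        spec = tiny_spec(seed=2)
        a = generate_labeled_dataset(spec, 4, 0.5, duration_s=20.0)
        b = generate_labeled_dataset(spec, 4, 0.5, duration_s=20.0)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.signal, rb.signal)
            assert ra.annotations == rb.annotations

    def test_zero_fraction_means_no_annotations(self):
        recs = generate_labeled_dataset(tiny_spec(seed=3), 5, 0.0, 20.0)
        assert all(r.annotations == [] for r in recs)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_labeled_dataset(tiny_spec(), 0, 0.5, 20.0)
        with pytest.raises(ConfigurationError):
            generate_labeled_dataset(tiny_spec(), 5, 1.5, 20.0)

    def test_written_cohort_round_trips_through_ingestion(self, tmp_path):
        spec = tiny_spec(seed=4)
        recs = generate_labeled_dataset(spec, 4, 0.5, duration_s=20.0)
        names = write_cohort(recs, tmp_path)
        assert len(names) == 4
        for name, rec in zip(names, recs):
            back = read_edf(tmp_path / name)
            assert back.n_samples == rec.n_samples
            assert np.max(np.abs(back.signal - rec.signal)) < 0.05
            ivs = parse_annotation_summary(tmp_path / "summary.txt", name)
            assert ivs == rec.annotations


def test_separable_in_band_power_space_at_gain_3():
    """Ictal windows at >=3x amplitude are linearly separable from
    background in band-power features (floor for classifier tests)."""
    from sklearn.linear_model import LogisticRegression

    from deepeeg.benchmark import band_power_features
    from deepeeg.preprocess import segment_recordings

    spec = tiny_spec(seed=6, gain=3.0)
    recs = generate_labeled_dataset(spec, 10, 0.5, duration_s=30.0)
    segs = segment_recordings(recs, 1.0)
    X = band_power_features(segs.tensor, segs.fs)
    clf = LogisticRegression(max_iter=2000).fit(X, segs.labels)
    assert clf.score(X, segs.labels) == 1.0
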