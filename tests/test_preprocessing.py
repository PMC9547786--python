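"""Filters, channel rejection, scaling and spectral estimation."""

import numpy as np
import pytest
from scipy.signal.windows import hann

from neurocouple import (
    CANONICAL_BANDS,
    artifact_reject,
    band_filter,
    band_power,
    bandpass_fir,
    cardiac_respiratory_filter,
    reject_low_snr_channels,
    remove_motion_pca,
    resting_state_filter,
    scale_minmax,
    welch_psd,
)
from neurocouple.preprocessing import BandDefinition

from conftest import make_recording


def _tone(freq, fs, dur):
    t = np.arange(0, dur, 1 / fs)
    return np.sin(2 * np.pi * freq * t)[:, None]


def _steady_amplitude(x, fs):
    """Peak amplitude over the middle half (edge transients discarded)."""
    n = len(x)
    return np.abs(x[n // 4 : 3 * n // 4]).max()


class TestBandFilters:
    @pytest.mark.parametrize("band", list(CANONICAL_BANDS))
    def test_midband_passes_within_1db(self, band):
        b = CANONICAL_BANDS[band]
        mid = np.sqrt(b.lowcut * b.highcut)
        rec = make_recording(_tone(mid, 500.0, 40.0))
        out = band_filter(rec, band)
        ratio = _steady_amplitude(out.data[:, 0], 500.0)
        assert 10 ** (-1 / 20) < ratio < 10 ** (1 / 20)

    @pytest.mark.parametrize("band", list(CANONICAL_BANDS))
    @pytest.mark.parametrize("side", ["low", "high"])
    def test_one_octave_outside_attenuated_40db(self, band, side):
        b = CANONICAL_BANDS[band]
        freq = b.lowcut / 2 if side == "low" else min(b.highcut * 2, 200.0)
        rec = make_recording(_tone(freq, 500.0, 40.0))
        out = band_filter(rec, band)
        assert _steady_amplitude(out.data[:, 0], 500.0) < 10 ** (-40 / 20)

    def test_alpha_example_amplitude(self, sinusoid_recording):
        out = bandpass_fir(sinusoid_recording, 8.0, 12.0)
        amp = _steady_amplitude(out.data[:, 0], 500.0)
        assert 0.9 < amp < 1.1

    def test_dc_rejected_by_gamma(self):
        rec = make_recording(np.full((20000, 1), 3.3))
        out = bandpass_fir(rec, 30.0, 100.0)
        assert np.abs(out.data).max() < 0.01

    def test_highcut_at_nyquist_rejected(self, sinusoid_recording):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_fir(sinusoid_recording, 0.1, 250.0)

    def test_unknown_band_name(self, sinusoid_recording):
        with pytest.raises(ValueError, match="unknown band"):
            band_filter(sinusoid_recording, "mu")

    def test_linearity(self, rng):
        x = rng.standard_normal((20000, 2))
        y = rng.standard_normal((20000, 2))
        fa = band_filter(make_recording(x), "alpha").data
        fb = band_filter(make_recording(y), "alpha").data
        fab = band_filter(make_recording(2.0 * x - 0.5 * y), "alpha").data
        assert np.allclose(fab, 2.0 * fa - 0.5 * fb, atol=1e-9)

    def test_bands_partition_energy(self, rng):
        x = rng.standard_normal((60 * 500, 1))
        rec = make_recording(x)
        total = bandpass_fir(rec, 1.0, 100.0).data.var()
        parts = sum(band_filter(rec, b).data.var() for b in CANONICAL_BANDS)
        assert abs(parts - total) / total < 0.15

    def test_band_definition_validation(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 10.0, 5.0)


class TestRestingStateFilter:
    def test_cardiac_attenuated(self):
        rec = make_recording(_tone(1.0, 19.5, 600.0), fs=19.5, modality="HbO")
        out = resting_state_filter(rec)
        assert _steady_amplitude(out.data[:, 0], 19.5) < 10 ** (-40 / 20)

    def test_resting_band_passes(self):
        rec = make_recording(_tone(0.05, 19.5, 600.0), fs=19.5, modality="HbO")
        out = resting_state_filter(rec)
        amp = _steady_amplitude(out.data[:, 0], 19.5)
        assert 10 ** (-1 / 20) < amp < 10 ** (1 / 20)

    def test_zero_in_zero_out(self):
        rec = make_recording(np.zeros((8000, 2)), fs=19.5, modality="HbO")
        assert np.allclose(resting_state_filter(rec).data, 0.0)

    def test_short_record_warns(self):
        rec = make_recording(np.zeros((1000, 1)), fs=19.5, modality="HbO")
        with pytest.warns(UserWarning, match="3 cycles"):
            resting_state_filter(rec)

    def test_cardiac_respiratory_lowpass(self):
        rec = make_recording(_tone(1.0, 19.5, 300.0), fs=19.5, modality="HbO")
        out = cardiac_respiratory_filter(rec, cutoff=0.2)
        assert _steady_amplitude(out.data[:, 0], 19.5) < 10 ** (-40 / 20)


class TestChannelRejection:
    def test_identical_channels_all_kept(self, rng):
        x = np.tile(rng.standard_normal((1000, 1)), (1, 10))
        out, rejected = reject_low_snr_channels(make_recording(x))
        assert rejected == [] and out.n_channels == 10

    def test_weak_channel_rejected(self, rng):
        x = np.tile(rng.standard_normal((1000, 1)), (1, 10))
        x[:, 3] *= 0.1
        out, rejected = reject_low_snr_channels(make_recording(x))
        assert rejected == ["ch3"] and out.n_channels == 9

    def test_zero_fraction_keeps_all(self, rng):
        x = rng.standard_normal((1000, 4)) * [1.0, 0.01, 1.0, 1.0]
        _out, rejected = reject_low_snr_channels(make_recording(x), 0.0)
        assert rejected == []

    def test_idempotent(self, rng):
        x = rng.standard_normal((1000, 8)) * np.linspace(0.1, 2.0, 8)
        first, _ = reject_low_snr_channels(make_recording(x))
        second, rejected = reject_low_snr_channels(first)
        assert rejected == [] and second.channel_labels == first.channel_labels


class TestMotionPCA:
    def test_rank_one_removed(self, rng):
        base = rng.standard_normal((500, 1))
        weights = rng.standard_normal((1, 6))
        rec = make_recording(base @ weights)
        out = remove_motion_pca(rec, 1)
        assert np.linalg.norm(out.data - out.data.mean(0)) < 1e-6 * np.linalg.norm(rec.data)

    def test_zero_components_identity(self, rng):
        rec = make_recording(rng.standard_normal((300, 4)))
        assert np.allclose(remove_motion_pca(rec, 0).data, rec.data)

    def test_variance_accounting_matches_eigendecomposition(self, rng):
        x = rng.standard_normal((400, 6)) @ rng.standard_normal((6, 6))
        rec = make_recording(x)
        out = remove_motion_pca(rec, 2)
        evals = np.linalg.eigvalsh(np.cov(x - x.mean(0), rowvar=False))
        expected = x.var(axis=0, ddof=1).sum() - evals[-2:].sum()
        assert np.isclose(out.data.var(axis=0, ddof=1).sum(), expected)

    def test_too_many_components_rejected(self, rng):
        rec = make_recording(rng.standard_normal((100, 3)))
        with pytest.raises(ValueError):
            remove_motion_pca(rec, 3)


class TestArtifactReject:
    def test_constant_channel_unflagged(self):
        rec = make_recording(np.full((100, 1), 0.5))
        _out, mask = artifact_reject(rec)
        assert not mask.any()

    def test_single_spike_flagged(self):
        x = np.full((100, 1), 0.4)
        x[50, 0] = 0.9
        _out, mask = artifact_reject(make_recording(x), 0.1)
        assert mask.sum() == 1 and mask[50, 0]

    def test_threshold_one_flags_nothing_in_unit_range(self, rng):
        x = rng.random((200, 3))
        _out, mask = artifact_reject(make_recording(x), 1.0)
        assert not mask.any()

    def test_nonpositive_threshold_rejected(self, rng):
        with pytest.raises(ValueError):
            artifact_reject(make_recording(rng.random((10, 1))), 0.0)


class TestScaling:
    def test_worked_example(self):
        rec = make_recording(np.array([[0.0], [5.0], [10.0]]))
        out, _ = scale_minmax(rec)
        assert np.allclose(out.data[:, 0], [-0.5, 0.0, 0.5])

    def test_roundtrip(self, rng):
        rec = make_recording(rng.standard_normal((500, 4)) * [1, 10, 100, 0.1])
        out, params = scale_minmax(rec)
        assert np.allclose(params.inverse(out.data), rec.data, atol=1e-12)

    def test_channels_span_unit_interval_before_centering(self, rng):
        rec = make_recording(rng.standard_normal((300, 3)) * [2, 5, 9] + 7)
        out, params = scale_minmax(rec)
        unit = out.data + params.means
        assert np.allclose(unit.min(0), 0.0) and np.allclose(unit.max(0), 1.0)

    def test_constant_channel_maps_to_half(self):
        rec = make_recording(np.full((50, 1), 3.0))
        with pytest.warns(UserWarning, match="constant"):
            out, params = scale_minmax(rec)
        assert np.allclose(out.data + params.means, 0.5)


class TestWelch:
    def test_unit_sinusoid_power(self, sinusoid_recording):
        psd = welch_psd(sinusoid_recording, window_s=4.0, overlap=0.5)
        total = band_power(psd, 0.0, 250.0)[0]
        assert abs(total - 0.5) / 0.5 < 0.05

    def test_white_noise_variance(self, rng):
        sigma = 2.5
        rec = make_recording(sigma * rng.standard_normal((60 * 500, 1)))
        psd = welch_psd(rec)
        total = band_power(psd, 0.0, 250.0)[0]
        assert abs(total - sigma**2) / sigma**2 < 0.10

    def test_zero_signal(self):
        rec = make_recording(np.zeros((5000, 2)))
        assert np.allclose(welch_psd(rec).power, 0.0)

    def test_matches_single_periodogram(self, rng):
        x = rng.standard_normal(2048)
        rec = make_recording(x[:, None], fs=256.0)
        psd = welch_psd(rec, window_s=2048 / 256.0, overlap=0.0)
        w = hann(2048, sym=False)
        spec = np.abs(np.fft.rfft(x * w)) ** 2 / (256.0 * np.sum(w**2))
        spec[1:-1] *= 2  # one-sided
        assert np.allclose(psd.power[0], spec, rtol=1e-10, atol=1e-12)

    def test_record_shorter_than_window(self, rng):
        rec = make_recording(rng.standard_normal((100, 1)))
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(rec, window_s=4.0)
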