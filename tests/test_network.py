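"""Autoencoder shape contracts, training behavior and sequencing."""

import numpy as np
import pytest

from neurocouple import CrossModalAutoencoder, make_sequences
from neurocouple.model.sequences import stitch_predictions

from conftest import make_recording


def _fit_tiny(X, y, **kw):
    params = dict(
        feature_maps=(3, 2), decoder_maps=3, lstm_units=(8, 6, 10, 20),
        epochs=2, batch_size=4, dropout=0.0, random_state=0,
        val_fraction=0.0, test_fraction=0.0,
    )
    params.update(kw)
    return CrossModalAutoencoder(**params).fit(X, y)


@pytest.fixture()
def tiny_pair(rng):
    X = rng.standard_normal((6, 3, 500, 5)).astype(np.float32)
    y = rng.standard_normal((6, 3, 20, 2)).astype(np.float32)
    return X, y


class TestShapeChain:
    def test_default_configuration_matches_reference_sizes(self, rng):
        X = rng.standard_normal((2, 4, 500, 21)).astype(np.float32)
        y = rng.standard_normal((2, 4, 20, 6)).astype(np.float32)
        m = CrossModalAutoencoder(epochs=1, batch_size=2, random_state=0)
        m.fit(X, y)
        t = m.trace_shapes(X)
        assert t["conv_block1"] == (4, 125, 16)
        assert t["conv_block2"] == (4, 62, 4)
        assert t["reshape_encoder"] == (4, 248)
        assert t["encoder_lstm1"] == (4, 512)
        assert t["latent"] == (1, 256)
        assert t["repeat"] == (4, 256)
        assert t["decoder_lstm3"] == (4, 312)
        assert t["decoder_lstm4"] == (4, 695)
        assert t["reshape_decoder"] == (4, 5, 139)
        assert t["deconv1"] == (4, 10, 8)
        assert t["output"] == (4, 20, 6)

    def test_random_valid_configs_conform(self, rng):
        for _ in range(8):
            f1 = int(rng.integers(2, 8))
            f2 = int(rng.integers(2, 6))
            f4 = int(rng.integers(2, 6))
            u1, u2, u3 = (int(rng.integers(4, 24)) for _ in range(3))
            u4 = 5 * int(rng.integers(2, 30))
            s = int(rng.integers(2, 5))
            cf = int(rng.integers(1, 4))
            X = rng.standard_normal((2, s, 500, 3)).astype(np.float32)
            y = rng.standard_normal((2, s, 20, cf)).astype(np.float32)
            m = _fit_tiny(X, y, feature_maps=(f1, f2), decoder_maps=f4,
                          lstm_units=(u1, u2, u3, u4), epochs=1)
            t = m.trace_shapes(X)
            assert t["conv_block1"] == (s, 125, f1)
            assert t["conv_block2"] == (s, 62, f2)
            assert t["reshape_encoder"] == (s, 62 * f2)
            assert t["latent"] == (1, u2)
            assert t["decoder_lstm4"] == (s, u4)
            assert t["reshape_decoder"] == (s, 5, u4 // 5)
            assert t["output"] == (s, 20, cf)

    def test_flattened_width_follows_feature_maps(self, rng):
        X = rng.standard_normal((2, 2, 500, 4)).astype(np.float32)
        y = rng.standard_normal((2, 2, 20, 2)).astype(np.float32)
        m = _fit_tiny(X, y, feature_maps=(3, 4), epochs=1)
        assert m.trace_shapes(X)["reshape_encoder"] == (2, 248)  # 62 * 4

    def test_indivisible_decoder_width_rejected(self, tiny_pair):
        X, y = tiny_pair
        with pytest.raises(ValueError, match="divisible"):
            _fit_tiny(X, y, lstm_units=(8, 6, 10, 21))


class TestTraining:
    def test_seed_reproducibility(self, tiny_pair):
        X, y = tiny_pair
        kw = dict(dropout=0.2, epochs=3, val_fraction=0.2, test_fraction=0.2)
        a = _fit_tiny(X, y, **kw)
        b = _fit_tiny(X, y, **kw)
        assert a.loss_curve_ == b.loss_curve_
        assert a.val_loss_curve_ == b.val_loss_curve_

    def test_zero_learning_rate_flat_loss(self, tiny_pair):
        X, y = tiny_pair
        m = _fit_tiny(X, y, learning_rate=0.0, epochs=4)
        assert np.ptp(m.loss_curve_) < 1e-12

    def test_unit_init_relu_diverges_with_diagnostic(self, rng):
        # unit-scale positive init needs full-width inputs to blow up
        X = rng.standard_normal((4, 4, 500, 21)).astype(np.float32)
        y = rng.standard_normal((4, 4, 20, 6)).astype(np.float32)
        with np.errstate(all="ignore"), pytest.raises(
            RuntimeError, match="epoch"
        ):
            CrossModalAutoencoder(
                init="unit-uniform", activation="relu", learning_rate=0.05,
                epochs=5, batch_size=4, dropout=0.0, random_state=0,
                val_fraction=0.0, test_fraction=0.0,
            ).fit(X, y)

    def test_split_proportions(self, rng):
        X = rng.standard_normal((20, 2, 500, 3)).astype(np.float32)
        y = rng.standard_normal((20, 2, 20, 2)).astype(np.float32)
        m = _fit_tiny(X, y, epochs=1, val_fraction=0.2, test_fraction=0.2)
        r = m.report_
        assert len(r.train_idx) == 12 and len(r.val_idx) == 4
        assert len(r.test_idx) == 4
        all_idx = np.concatenate([r.train_idx, r.val_idx, r.test_idx])
        assert sorted(all_idx) == list(range(20))

    def test_loss_curves_have_epoch_length(self, tiny_pair):
        X, y = tiny_pair
        m = _fit_tiny(X, y, epochs=5)
        assert len(m.loss_curve_) == 5 == len(m.val_loss_curve_)

    def test_three_dim_targets_accepted(self, rng):
        X = rng.standard_normal((4, 2, 500, 3)).astype(np.float32)
        y = rng.standard_normal((4, 2, 40)).astype(np.float32)
        m = _fit_tiny(X, y, epochs=1)
        assert m.predict(X).shape == (4, 2, 20, 2)


class TestPredict:
    def test_deterministic_inference(self, tiny_pair):
        X, y = tiny_pair
        m = _fit_tiny(X, y, dropout=0.3)
        assert np.array_equal(m.predict(X), m.predict(X))

    def test_output_shape(self, tiny_pair):
        X, y = tiny_pair
        m = _fit_tiny(X, y)
        assert m.predict(X).shape == (6, 3, 20, 2)

    def test_unfitted_predict_rejected(self, tiny_pair):
        X, _ = tiny_pair
        with pytest.raises(RuntimeError, match="not fitted"):
            CrossModalAutoencoder().predict(X)

    def test_sklearn_param_roundtrip(self):
        m = CrossModalAutoencoder(epochs=7)
        params = m.get_params()
        assert params["epochs"] == 7
        m2 = CrossModalAutoencoder().set_params(**params)
        assert m2.get_params() == params


class TestMakeSequences:
    def _pair(self, rng, dur=12.0):
        eeg = make_recording(rng.standard_normal((int(dur * 500), 4)))
        fnirs = make_recording(
            rng.standard_normal((int(dur * 20), 3)), fs=20.0, modality="HbO"
        )
        return eeg, fnirs

    def test_window_arithmetic(self, rng):
        # 10 s of pairable data plus the 1-s target shift
        eeg, fnirs = self._pair(rng, dur=11.0)
        pair = make_sequences(eeg, fnirs, seq_len=5, shift_elems=1)
        assert pair.eeg.shape == (2, 5, 500, 4)
        assert pair.fnirs.shape == (2, 5, 20 * 3)

    def test_target_is_shifted_one_element(self, rng):
        eeg, fnirs = self._pair(rng)
        pair = make_sequences(eeg, fnirs, seq_len=5, shift_elems=1)
        expected = fnirs.data[20 : 20 + 100].reshape(5, 60)
        assert np.array_equal(pair.fnirs[0], expected)

    def test_mask_drops_intersecting_window(self, rng):
        eeg, fnirs = self._pair(rng, dur=25.0)
        clean = make_sequences(eeg, fnirs, seq_len=5)
        mask = np.zeros(fnirs.n_samples, dtype=bool)
        mask[30] = True  # inside the first fNIRS target window
        masked = make_sequences(eeg, fnirs, seq_len=5, fnirs_mask=mask)
        assert masked.n_samples == clean.n_samples - 1

    def test_segment_boundaries_respected(self, rng):
        eeg = make_recording(
            rng.standard_normal((24 * 500, 2)),
            segments=[(0, 6000), (6000, 12000)],
        )
        fnirs = make_recording(
            rng.standard_normal((24 * 20, 2)), fs=20.0, modality="HbO",
            segments=[(0, 240), (240, 480)],
        )
        pair = make_sequences(eeg, fnirs, seq_len=5, shift_elems=1)
        # each 12-s segment yields two windows anchored at its own start;
        # none crosses the 12-s junction
        assert pair.n_samples == 4
        assert list(pair.target_starts_s) == [1.0, 6.0, 13.0, 18.0]

    def test_noninteger_rate_rejected(self, rng):
        eeg = make_recording(rng.standard_normal((5000, 2)))
        fnirs = make_recording(
            rng.standard_normal((195, 2)), fs=19.5, modality="HbO"
        )
        with pytest.raises(ValueError, match="resample"):
            make_sequences(eeg, fnirs, seq_len=3)

    def test_too_short_recording(self, rng):
        eeg, fnirs = self._pair(rng, dur=4.0)
        with pytest.raises(ValueError, match="too short"):
            make_sequences(eeg, fnirs, seq_len=5)

    def test_stitch_recovers_targets(self, rng):
        eeg, fnirs = self._pair(rng, dur=32.0)
        pair = make_sequences(eeg, fnirs, seq_len=5, shift_elems=1)
        blocks = pair.fnirs.reshape(pair.n_samples, 5, 20, 3)
        times, data = stitch_predictions(pair, blocks, 20.0)
        i0 = int(times[0] * 20)
        assert np.array_equal(data, fnirs.data[i0 : i0 + len(data)])
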