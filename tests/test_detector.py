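"""Autoencoder mechanics, threshold calibration and evaluation bookkeeping.

Heavy end-to-end training lives in the session-scoped ``trained_detector``
fixture; the trainings here are deliberately tiny (few tensors, few epochs).
"""

import dataclasses

import numpy as np
import pytest

import dystonia_screen as ds
from dystonia_screen.errors import (
    EmptyGroup,
    ShapeMismatch,
    TooFewErrors,
    TooFewParticipants,
)
from dystonia_screen.nn import conv_backward, conv_forward


def _tensor(subject: str, seed: int = 0) -> ds.TrialTensor:
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.2, 0.8, size=(21, 3, 128))
    meta = ds.TrialMeta(subject_id=subject, group="healthy", hand="right",
                        task_id=4, tempo_bpm=100.0)
    return ds.TrialTensor(values=values, meta=meta)


class TestConvPrimitives:
    """Gradient checks for the hand-rolled convolution layers."""

    @pytest.mark.parametrize("stride", [(1, 1), (1, 2), (3, 2)])
    def test_conv_gradients_match_finite_differences(self, stride, rng):
        x = rng.normal(size=(2, 3, 9, 12)).astype(np.float64)
        w = rng.normal(size=(4, 3, 3, 3)).astype(np.float64) * 0.3
        b = rng.normal(size=4).astype(np.float64)
        y = conv_forward(x, w, b, stride)
        dy = rng.normal(size=y.shape)
        dx, dw, db = conv_backward(dy, x, w, stride)
        eps = 1e-6
        for arr, grad in ((x, dx), (w, dw), (b, db)):
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            arr[idx] += eps
            up = float((conv_forward(x, w, b, stride) * dy).sum())
            arr[idx] -= 2 * eps
            down = float((conv_forward(x, w, b, stride) * dy).sum())
            arr[idx] += eps
            numeric = (up - down) / (2 * eps)
            assert numeric == pytest.approx(float(grad[idx]), rel=1e-4, abs=1e-7)

    def test_architecture_is_7_plus_7_conv_layers(self):
        net = ds.ConvAutoencoder(seed=0)
        assert net.config.n_encoder_layers == 7
        assert net.config.n_decoder_layers == 7
        assert len(net.layers) == 14
        assert net.config.latent_dim < 21 * 3 * 128

    def test_reconstruction_shape_preserved(self, healthy_tensor):
        net = ds.ConvAutoencoder(seed=0)
        x = healthy_tensor.values.transpose(1, 0, 2)
        assert net.reconstruct(x).shape == x.shape


class TestSplitByParticipant:
    def test_80_20_split_of_10_participants(self):
        tensors = [_tensor(f"P{i}", seed=i) for i in range(10) for _ in range(3)]
        train, val = ds.split_by_participant(tensors, seed=1)
        train_ids = {t.meta.subject_id for t in train}
        val_ids = {t.meta.subject_id for t in val}
        assert len(train_ids) == 8 and len(val_ids) == 2
        assert train_ids.isdisjoint(val_ids)

    def test_deterministic_given_seed(self):
        tensors = [_tensor(f"P{i}", seed=i) for i in range(10)]
        a = ds.split_by_participant(tensors, seed=7)
        b = ds.split_by_participant(tensors, seed=7)
        assert [t.meta.subject_id for t in a[0]] == [t.meta.subject_id for t in b[0]]

    def test_single_participant_raises(self):
        with pytest.raises(TooFewParticipants):
            ds.split_by_participant([_tensor("only"), _tensor("only")])


class TestTraining:
    def test_memorizes_repeated_tensor(self, healthy_tensor):
        """50 identical copies: reconstruction error collapses below 1e-3."""
        config = ds.AutoencoderConfig(max_epochs=60, patience=60)
        train = [healthy_tensor] * 50
        model = ds.train_autoencoder(train, config=config, seed=0)
        assert ds.reconstruction_error(model, healthy_tensor) < 1e-3

    def test_loss_history_deterministic(self, healthy_tensor):
        config = ds.AutoencoderConfig(max_epochs=5, patience=5)
        train = [healthy_tensor] * 8
        a = ds.train_autoencoder(train, config=config, seed=3)
        b = ds.train_autoencoder(train, config=config, seed=3)
        assert a.loss_history == b.loss_history

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            ds.train_autoencoder([], seed=0)

    def test_smoothed_loss_non_increasing(self, trained_detector):
        """Patience-window moving average trends down throughout the run.

        Minibatch shuffling wobbles the average a few percent around the
        late-training plateau, so the check is that it never climbs more
        than 10% above its running minimum and ends far below its start.
        """
        artifact, _ = trained_detector
        loss = np.asarray(artifact.model.loss_history)
        patience = artifact.model.network.config.patience
        smoothed = np.convolve(loss, np.ones(patience) / patience, mode="valid")
        running_min = np.minimum.accumulate(smoothed)
        assert np.all(smoothed <= 1.10 * running_min + 1e-9)
        assert smoothed[-1] < 0.1 * smoothed[0]


class TestReconstructionError:
    def test_zero_for_perfect_reconstruction(self):
        values = np.full((21, 3, 128), 0.4)

        class _Identity:
            input_shape = (3, 21, 128)

            def reconstruct(self, x):
                return x.astype(np.float32)

        model = ds.TrainedModel(network=_Identity(), loss_history=[0.0])
        assert ds.reconstruction_error(model, ds.TrialTensor(values=values)) == 0.0

    def test_constant_offset_error_is_squared_offset(self):
        values = np.full((21, 3, 128), 0.4)

        class _Offset:
            def reconstruct(self, x):
                return x + np.float32(0.1)

        model = ds.TrainedModel(network=_Offset(), loss_history=[0.0])
        err = ds.reconstruction_error(model, ds.TrialTensor(values=values))
        assert err == pytest.approx(0.01, rel=1e-5)

    def test_batch_errors_match_scalar_path(self, trained_detector, healthy_cohort_tensors):
        artifact, _ = trained_detector
        sample = healthy_cohort_tensors[:5]
        batch = ds.reconstruction_errors(artifact.model, sample)
        scalar = [ds.reconstruction_error(artifact.model, t) for t in sample]
        np.testing.assert_allclose(batch, scalar, rtol=1e-6)


class TestCalibration:
    def test_zero_variance_threshold_equals_mean(self):
        rec = ds.calibrate_threshold([1.0, 1.0, 1.0, 1.0])
        assert rec.mean_err == 1.0 and rec.sd_err == 0.0 and rec.threshold == 1.0

    def test_two_point_hand_arithmetic(self):
        rec = ds.calibrate_threshold([0.0, 2.0])
        assert rec.mean_err == pytest.approx(1.0)
        assert rec.sd_err == pytest.approx(np.sqrt(2.0))
        assert rec.threshold == pytest.approx(1.0 + 2 * np.sqrt(2.0))

    def test_identical_errors_any_count(self):
        for k in (2, 5, 11):
            rec = ds.calibrate_threshold([3e-4] * k)
            assert rec.threshold == pytest.approx(3e-4)

    def test_single_error_raises(self):
        with pytest.raises(TooFewErrors):
            ds.calibrate_threshold([1e-4])

    def test_record_identity_enforced(self):
        with pytest.raises(ValueError):
            ds.CalibrationRecord(mean_err=1.0, sd_err=1.0, threshold=2.0,
                                 n_validation=4)

    def test_threshold_identity_to_machine_precision(self, trained_detector):
        cal = trained_detector[0].calibration
        assert cal.threshold == cal.mean_err + 2.0 * cal.sd_err


class TestClassify:
    def test_boundary_is_normal(self):
        rec = ds.calibrate_threshold([1.0, 3.0])
        assert ds.classify(rec.threshold, rec) == "normal"
        assert ds.classify(rec.threshold + 1e-12, rec) == "abnormal"

    def test_monotone_in_error(self):
        rec = ds.calibrate_threshold([1.0, 3.0])
        labels = [ds.classify(e, rec) for e in np.linspace(0, 10, 50)]
        flips = sum(a == "abnormal" and b == "normal"
                    for a, b in zip(labels, labels[1:]))
        assert flips == 0


class TestEvaluate:
    def test_sensitivity_and_specificity_arithmetic(self):
        preds = [(4, "md", "abnormal")] * 9 + [(4, "md", "normal")] \
            + [(4, "healthy", "normal")] * 19 + [(4, "healthy", "abnormal")]
        report = ds.evaluate(preds)
        ev = report.tasks[4]
        assert ev.sensitivity == pytest.approx(0.9)
        assert ev.specificity == pytest.approx(0.95)
        assert not ev.chance_flag

    def test_chance_flag_at_half_sensitivity(self):
        preds = [(1, "md", "abnormal"), (1, "md", "normal"),
                 (1, "healthy", "normal")]
        assert ds.evaluate(preds).tasks[1].chance_flag

    def test_task_without_patients_raises(self):
        with pytest.raises(EmptyGroup):
            ds.evaluate([(2, "healthy", "normal")])


class TestPersistence:
    def test_artifact_roundtrip(self, tmp_path, healthy_tensor):
        config = ds.AutoencoderConfig(max_epochs=3, patience=3)
        model = ds.train_autoencoder([healthy_tensor] * 6, config=config, seed=1)
        record = ds.calibrate_threshold([1e-4, 2e-4, 3e-4], split_seed=1,
                                        init_seed=1)
        artifact = ds.DetectorArtifact(model=model, calibration=record, task_id=4)
        ds.save_artifact(artifact, tmp_path / "model")
        loaded = ds.load_artifact(tmp_path / "model")
        assert dataclasses.asdict(loaded.calibration) == dataclasses.asdict(record)
        err_a = ds.reconstruction_error(model, healthy_tensor)
        err_b = ds.reconstruction_error(loaded.model, healthy_tensor)
        assert err_a == pytest.approx(err_b, rel=1e-7)

    def test_shape_mismatch_rejected(self, trained_detector):
        artifact, _ = trained_detector
        bad = np.zeros((3, 21, 64), dtype=np.float32)
        with pytest.raises(ShapeMismatch):
            artifact.model.network.reconstruct(bad)
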