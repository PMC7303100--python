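"""Tests for the loss functions, ROI splits and the training loop."""

import numpy as np
import pytest

from octmotion.nets import ModelConfig, build_model
from octmotion.nn import Tensor
from octmotion.training import (LossConfig, TrainConfig, TrainingDiverged,
                                loss, split_rois, train)
from octmotion.trajectories import MotionSequence

TINY = ModelConfig(initial_channels=(2, 3, 4), stem_strides=(1, 1, 1))


def _preds(arr, aux=None):
    out = {"y_tn": Tensor(np.asarray(arr, dtype=float))}
    if aux is not None:
        out["y_tn1"] = Tensor(np.asarray(aux[0], dtype=float))
        out["y_tn2"] = Tensor(np.asarray(aux[1], dtype=float))
    return out


class TestLoss:
    def test_unit_squared_norm(self):
        val = loss(_preds([[0.0, 0.0, 0.0]]),
                   (np.array([[1.0, 0.0, 0.0]]), None, None), LossConfig())
        assert val.item() == pytest.approx(1.0)

    def test_weighted_auxiliary_example(self):
        """Main error 1 plus 0.5 x auxiliary squared norm 4 gives 3."""
        preds = _preds([[0.0, 0.0, 0.0]],
                       aux=([[0.0, 0.0, 0.0]], [[0.0, 0.0, 0.0]]))
        targets = (np.array([[1.0, 0.0, 0.0]]),
                   np.array([[2.0, 0.0, 0.0]]),   # squared norm 4
                   np.array([[0.0, 0.0, 0.0]]))
        val = loss(preds, targets, LossConfig(w_n1=0.5, w_n2=0.0))
        assert val.item() == pytest.approx(3.0)

    def test_perfect_predictions_zero(self):
        t = np.random.default_rng(0).normal(size=(4, 3))
        assert loss(_preds(t), (t, None, None), LossConfig()).item() == 0.0

    def test_zero_weights_bit_identical_to_plain_mse(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = rng.normal(size=(7, 3))
            t = rng.normal(size=(7, 3))
            aux = (rng.normal(size=(7, 3)), rng.normal(size=(7, 3)))
            plain = loss(_preds(p), (t, None, None), LossConfig())
            reg = loss(_preds(p, aux=aux), (t, aux[0], aux[1]),
                       LossConfig(0.0, 0.0))
            assert plain.item() == reg.item()

    def test_batch_order_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.normal(size=(9, 3))
        t = rng.normal(size=(9, 3))
        perm = rng.permutation(9)
        a = loss(_preds(p), (t, None, None), LossConfig()).item()
        b = loss(_preds(p[perm]), (t[perm], None, None), LossConfig()).item()
        assert a == pytest.approx(b, rel=1e-12)

    def test_missing_aux_predictions_raise(self):
        with pytest.raises(ValueError):
            loss(_preds([[0.0, 0.0, 0.0]]),
                 (np.zeros((1, 3)), np.zeros((1, 3)), np.zeros((1, 3))),
                 LossConfig(w_n1=0.5))

    def test_weight_range_enforced(self):
        with pytest.raises(ValueError):
            LossConfig(w_n1=1.5)


class TestSplitRois:
    def test_full_scale_sizes(self):
        split = split_rois(range(40), n_test=5, n_val=5, seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == (30, 5, 5)

    def test_desk_scale_disjoint_cover(self):
        split = split_rois(range(8), n_test=2, n_val=2, seed=1)
        assert (len(split.train), len(split.val), len(split.test)) == (4, 2, 2)
        all_ids = set(split.train) | set(split.val) | set(split.test)
        assert all_ids == set(range(8))
        assert not (set(split.train) & set(split.val))
        assert not (set(split.train) & set(split.test))
        assert not (set(split.val) & set(split.test))

    def test_deterministic(self):
        assert split_rois(range(12), 3, 3, seed=5) == split_rois(range(12), 3, 3, seed=5)

    def test_too_few_rois(self):
        with pytest.raises(ValueError):
            split_rois(range(8), n_test=5, n_val=5, seed=0)


def _static_sequences(n, size=12, seed=0):
    rng = np.random.default_rng(seed)
    seqs = []
    for i in range(n):
        vol = rng.random((size, size, size)).astype(np.float32)
        vols = np.stack([vol] * 5)
        seqs.append(MotionSequence(volumes=vols, shifts=np.zeros((5, 3)),
                                   roi_id=i % 3))
    return seqs


class TestTrain:
    def test_overfits_single_batch(self):
        """Capacity sanity: a tiny net drives 4 sequences to ~zero loss."""
        rng = np.random.default_rng(3)
        seqs = []
        for i in range(4):
            vols = rng.random((5, 12, 12, 12)).astype(np.float32)
            shifts = np.zeros((5, 3))
            shifts[1:] = np.cumsum(rng.normal(0, 0.2, size=(4, 3)), axis=0)
            seqs.append(MotionSequence(volumes=vols, shifts=shifts, roi_id=0))
        model = build_model("two_path_3d", TINY, seed=3)
        tcfg = TrainConfig(epochs=300, batch_size=4, learning_rate=3e-3,
                           seed=3)
        res = train(model, seqs, tcfg, LossConfig())
        assert res.history.train_loss.iloc[-1] < 1e-3

    def test_history_length_and_determinism(self):
        seqs = _static_sequences(6)
        model = build_model("two_path_3d", TINY, seed=1)
        tcfg = TrainConfig(epochs=3, batch_size=3, learning_rate=1e-3, seed=1)
        res = train(model, seqs, tcfg, LossConfig())
        assert len(res.history) == 3
        model2 = build_model("two_path_3d", TINY, seed=1)
        res2 = train(model2, seqs, tcfg, LossConfig())
        np.testing.assert_array_equal(res.history.train_loss.values,
                                      res2.history.train_loss.values)

    def test_summed_two_path_learns_static_is_zero(self):
        """After training on static sequences the pairwise-sum prediction
        of an unseen static sequence is ~0 (within 0.05 mm)."""
        seqs = _static_sequences(6, seed=4)
        model = build_model("s_two_path_3d", TINY, seed=4)
        tcfg = TrainConfig(epochs=30, batch_size=3, learning_rate=3e-3, seed=4)
        train(model, seqs, tcfg, LossConfig())
        probe = _static_sequences(1, seed=99)[0]
        pred = model.predict_batch(probe.volumes[None])[0]
        assert np.all(np.abs(pred) < 0.05)

    def test_aux_weights_require_aux_model(self):
        seqs = _static_sequences(4)
        model = build_model("two_path_3d", TINY, seed=0)
        with pytest.raises(ValueError):
            train(model, seqs, TrainConfig(epochs=1, batch_size=2,
                                           learning_rate=1e-3),
                  LossConfig(w_n1=0.75, w_n2=0.75))

    def test_regularized_and_plain_both_run(self):
        seqs = _static_sequences(4)
        cfg_aux = ModelConfig(initial_channels=(2, 3, 4), aux_outputs=True)
        for lcfg in (LossConfig(0.75, 0.75), LossConfig(0.0, 0.0)):
            model = build_model("five_path_3d", cfg_aux, seed=0)
            res = train(model, seqs,
                        TrainConfig(epochs=2, batch_size=2, learning_rate=1e-3),
                        lcfg)
            assert np.isfinite(res.history.train_loss).all()

    def test_divergence_aborts(self):
        seqs = _static_sequences(4)
        model = build_model("two_path_3d", TINY, seed=0)
        # a poisoned weight produces a non-finite loss immediately
        model.heads.main.weight.data[:] = np.inf
        with pytest.raises(TrainingDiverged):
            train(model, seqs, TrainConfig(epochs=1, batch_size=2,
                                           learning_rate=1e-3), LossConfig())
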