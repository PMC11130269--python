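import numpy as np
import pytest

from naloxsim.emulators import (
    EmulatorSpec,
    TrainConfig,
    build_blackbox,
    build_emulator,
    build_semimechanistic,
    load_checkpoint,
    predict_vf,
    save_checkpoint,
    train,
)
from naloxsim.scenarios import EmulatorDataset, FeatureBounds

DIMS = (8, 10, 6)
T = 12


def _spec(arch, seed=0):
    return EmulatorSpec(arch, T, DIMS, dense_width=8, recurrent_width=6, seed=seed)


def _blocks(rng, n):
    return tuple(rng.random((n, d)) for d in DIMS)


def _toy_dataset(rng, n=20, targets=None):
    blocks = _blocks(rng, n)
    if targets is None:
        targets = rng.random((n, T))
    bounds = FeatureBounds(np.zeros((2, 8)), np.zeros((2, 10)), np.zeros((2, 6)))
    return EmulatorDataset(blocks[0], blocks[1], blocks[2], targets,
                           np.zeros((n, 2), int), np.arange(float(T)), bounds)


class TestArchitectures:
    @pytest.mark.parametrize("arch", ["blackbox", "semimechanistic"])
    def test_forward_shape_and_bounded_output(self, arch):
        rng = np.random.default_rng(0)
        model = build_emulator(_spec(arch))
        y = model.predict_occupancy(_blocks(rng, 5))
        assert y.shape == (5, T)
        assert np.all(y > 0) and np.all(y < 1)

    @pytest.mark.parametrize("arch", ["blackbox", "semimechanistic"])
    def test_seeded_initialization_is_deterministic(self, arch):
        rng = np.random.default_rng(1)
        blocks = _blocks(rng, 3)
        y1 = build_emulator(_spec(arch, seed=5)).predict_occupancy(blocks)
        y2 = build_emulator(_spec(arch, seed=5)).predict_occupancy(blocks)
        assert np.array_equal(y1, y2)
        y3 = build_emulator(_spec(arch, seed=6)).predict_occupancy(blocks)
        assert not np.array_equal(y1, y3)

    @pytest.mark.parametrize("arch", ["blackbox", "semimechanistic"])
    def test_boundary_inputs_stay_finite(self, arch):
        model = build_emulator(_spec(arch))
        for fill in (0.0, 1.0):
            blocks = tuple(np.full((2, d), fill) for d in DIMS)
            assert np.all(np.isfinite(model.predict_occupancy(blocks)))

    def test_build_rejects_mismatched_architecture(self):
        with pytest.raises(ValueError):
            build_blackbox(_spec("semimechanistic"))
        with pytest.raises(ValueError):
            build_semimechanistic(_spec("blackbox"))
        with pytest.raises(ValueError):
            EmulatorSpec("mlp", T, DIMS)

    def test_track_activations_shape(self):
        rng = np.random.default_rng(2)
        model = build_semimechanistic(_spec("semimechanistic"))
        tracks = model.track_activations(_blocks(rng, 4))
        assert tracks["opioid_track"].shape == (4, T, 6)
        assert tracks["naloxone_track"].shape == (4, T, 6)

    def test_track_separation_is_exact(self):
        """No parameter path connects naloxone inputs to the opioid track:
        perturbing one block leaves the other track bit-identical."""
        rng = np.random.default_rng(3)
        model = build_semimechanistic(_spec("semimechanistic"))
        x_op, x_nx, x_bind = _blocks(rng, 4)
        base = model.track_activations((x_op, x_nx, x_bind))
        perturbed = model.track_activations((x_op, rng.random(x_nx.shape), x_bind))
        assert np.array_equal(base["opioid_track"], perturbed["opioid_track"])
        assert not np.array_equal(base["naloxone_track"],
                                  perturbed["naloxone_track"])
        flipped = model.track_activations((rng.random(x_op.shape), x_nx, x_bind))
        assert np.array_equal(base["naloxone_track"], flipped["naloxone_track"])


class TestTraining:
    def test_one_epoch_record(self):
        rng = np.random.default_rng(4)
        ds = _toy_dataset(rng, n=10)
        model = build_emulator(_spec("blackbox"))
        rec = train(model, ds, TrainConfig(epochs=1, batch_size=4, seed=0))
        assert len(rec.train_errors) == 1 and len(rec.holdout_errors) == 1
        assert np.isfinite(rec.train_errors[0]) and np.isfinite(rec.holdout_errors[0])

    @pytest.mark.parametrize("arch", ["blackbox", "semimechanistic"])
    def test_constant_targets_are_learned(self, arch):
        """A constant trajectory is representable by the logistic output
        head, so per-point MSE must fall below 1e-3."""
        rng = np.random.default_rng(5)
        ds = _toy_dataset(rng, n=16, targets=np.full((16, T), 0.35))
        model = build_emulator(_spec(arch))
        rec = train(model, ds, TrainConfig(epochs=50, batch_size=8,
                                           learning_rate=2e-2, seed=0))
        per_point_mse = rec.train_errors[-1] / T
        assert per_point_mse < 1e-3

    def test_training_is_seed_reproducible(self):
        rng = np.random.default_rng(6)
        ds = _toy_dataset(rng, n=12)
        errs = []
        for _ in range(2):
            model = build_emulator(_spec("semimechanistic", seed=1))
            rec = train(model, ds, TrainConfig(epochs=3, batch_size=4, seed=9))
            errs.append(rec.holdout_errors)
        assert errs[0] == errs[1]

    def test_resume_continues_without_reinit(self):
        rng = np.random.default_rng(7)
        ds = _toy_dataset(rng, n=12)
        cfg = TrainConfig(epochs=2, batch_size=4, seed=2, lr_schedule="constant")
        m_split = build_emulator(_spec("blackbox", seed=3))
        train(m_split, ds, cfg)
        rec2 = train(m_split, ds, cfg)
        m_whole = build_emulator(_spec("blackbox", seed=3))
        rec4 = train(m_whole, ds, TrainConfig(epochs=4, batch_size=4, seed=2,
                                              lr_schedule="constant"))
        assert m_split.epochs_trained == m_whole.epochs_trained == 4
        assert rec2.holdout_errors[-1] == pytest.approx(rec4.holdout_errors[-1])

    def test_sequence_length_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        ds = _toy_dataset(rng, n=8, targets=rng.random((8, T + 1)))
        with pytest.raises(ValueError, match="sequence_length"):
            train(build_emulator(_spec("blackbox")), ds, TrainConfig(epochs=1))


class TestPredictVF:
    def test_pd_map_applied_pointwise(self):
        rng = np.random.default_rng(9)
        model = build_emulator(_spec("semimechanistic"))
        blocks = _blocks(rng, 3)
        r = model.predict_occupancy(blocks)
        np.testing.assert_allclose(predict_vf(model, blocks, alpha=1.0), 1.0 - r)
        np.testing.assert_allclose(predict_vf(model, blocks, alpha=0.0), 1.0)


def test_checkpoint_round_trip(tmp_path):
    rng = np.random.default_rng(10)
    ds = _toy_dataset(rng, n=10)
    model = build_emulator(_spec("semimechanistic", seed=4))
    train(model, ds, TrainConfig(epochs=2, batch_size=4, seed=1))
    path = tmp_path / "ckpt"
    save_checkpoint(model, path)
    back = load_checkpoint(path)
    blocks = _blocks(rng, 2)
    np.testing.assert_array_equal(back.predict_occupancy(blocks),
                                  model.predict_occupancy(blocks))
    assert back.epochs_trained == 2
    # resuming from the restored checkpoint matches resuming the original
    cfg = TrainConfig(epochs=1, batch_size=4, seed=1)
    r1 = train(model, ds, cfg)
    r2 = train(back, ds, cfg)
    assert r1.holdout_errors == pytest.approx(r2.holdout_errors)
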