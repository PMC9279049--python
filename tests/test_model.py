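"""DeepPsy fusion model: architecture contract, training mechanics."""

import dataclasses

import numpy as np
import pytest

from deeppsy import (
    DeepPsy,
    DeepPsySpec,
    activity_grid,
    build_deeppsy,
    deeppsy_param_count,
    make_dataset,
    train,
)
from deeppsy.bench import split_data
from deeppsy.cohort import StudentRecord
from deeppsy.model import TrainingError

rng = np.random.default_rng(1)


def _toy_data(n=24, n_weeks=2, d=6, seed=0, signal=0.0):
    r = np.random.default_rng(seed)
    labels = np.arange(n) % 2
    grids = r.random((n, n_weeks, 7, 24)) * 0.3
    feats = r.normal(size=(n, d))
    grids += signal * labels[:, None, None, None] * 0.3
    feats[:, 0] += signal * labels * 3.0
    return {"grids": grids, "features": feats, "labels": labels}


class TestArchitecture:
    def test_same_padding_preserves_spatial_dims(self):
        model = build_deeppsy(DeepPsySpec(seed=0))
        x = rng.random((3, 1, 7, 24))
        assert model.traj["conv1"].forward(x).shape == (3, 4, 7, 24)
        x2 = rng.random((3, 4, 4, 12))
        assert model.traj["conv2"].forward(x2).shape == (3, 32, 4, 12)

    def test_param_count_matches_closed_form(self):
        for spec in (
            DeepPsySpec(),
            DeepPsySpec(conv1_kernels=8, n_classes=4),
            DeepPsySpec(use_trajectory=False),
        ):
            model = DeepPsy(spec, grid_shape=(7, 24), n_features=6)
            assert model.param_count() == deeppsy_param_count(
                spec, (7, 24), 6
            ), spec

    def test_zero_params_zero_input_uniform_softmax(self):
        model = build_deeppsy(DeepPsySpec(seed=0))
        for p in model.params():
            p.value[...] = 0.0
        probs = model.predict_proba(np.zeros((2, 2, 7, 24)), np.zeros((2, 6)))
        assert np.allclose(probs, 0.5)

    def test_probabilities_sum_to_one(self):
        model = build_deeppsy(DeepPsySpec(seed=3))
        probs = model.predict_proba(rng.random((5, 2, 7, 24)), rng.normal(size=(5, 6)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicate_inputs_identical_outputs(self):
        model = build_deeppsy(DeepPsySpec(seed=3))
        g = np.repeat(rng.random((1, 2, 7, 24)), 4, axis=0)
        f = np.repeat(rng.normal(size=(1, 6)), 4, axis=0)
        probs = model.predict_proba(g, f)
        assert np.allclose(probs, probs[0])

    def test_four_class_mode(self):
        model = build_deeppsy(DeepPsySpec(n_classes=4, seed=0))
        probs = model.predict_proba(rng.random((3, 2, 7, 24)), rng.normal(size=(3, 6)))
        assert probs.shape == (3, 4)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DeepPsySpec(dropout=1.5)
        with pytest.raises(ValueError):
            DeepPsySpec(fusion_width=0)


class TestTraining:
    def test_both_branches_update_after_one_step(self):
        data = _toy_data(n=8, signal=1.0)
        spec = DeepPsySpec(epochs=1, seed=0)
        model = DeepPsy(spec, (7, 24), 6)
        before_traj = [p.value.copy() for p in model.trajectory_params()]
        before_basic = [p.value.copy() for p in model.basic_params()]
        train(model, data, spec=spec)
        assert any(
            not np.array_equal(b, p.value)
            for b, p in zip(before_traj, model.trajectory_params())
        )
        assert any(
            not np.array_equal(b, p.value)
            for b, p in zip(before_basic, model.basic_params())
        )

    def test_zero_learning_rate_freezes_parameters(self):
        data = _toy_data(n=8)
        # dropout off and full-batch so the only epoch-to-epoch change
        # could come from parameter updates
        spec = DeepPsySpec(epochs=3, lr=0.0, dropout=0.0, batch_size=8, seed=0)
        model = DeepPsy(spec, (7, 24), 6)
        train(model, data, spec=spec)
        before = [p.value.copy() for p in model.params()]
        _, log = train(model, data, spec=spec)
        assert all(
            np.array_equal(b, p.value) for b, p in zip(before, model.params())
        )
        losses = log.to_frame()["train_loss"].to_numpy()
        # constant up to summation order (samples are permuted per epoch)
        assert np.allclose(losses, losses[0], atol=1e-12)

    def test_training_deterministic(self):
        data = _toy_data(n=12, signal=0.5)
        spec = DeepPsySpec(epochs=3, seed=4)
        runs = []
        for _ in range(2):
            model = DeepPsy(spec, (7, 24), 6)
            _, log = train(model, data, spec=spec)
            runs.append((log.to_frame(), [p.value.copy() for p in model.params()]))
        assert runs[0][0].equals(runs[1][0])
        assert all(np.array_equal(a, b) for a, b in zip(runs[0][1], runs[1][1]))

    def test_single_class_rejected(self):
        data = _toy_data(n=8)
        data["labels"] = np.zeros(8, dtype=int)
        spec = DeepPsySpec(epochs=1)
        with pytest.raises(TrainingError):
            train(DeepPsy(spec, (7, 24), 6), data, spec=spec)

    def test_nonfinite_loss_raises(self):
        data = _toy_data(n=8)
        spec = DeepPsySpec(epochs=1, seed=0)
        model = DeepPsy(spec, (7, 24), 6)
        model.head["out"].w.value[...] = np.nan
        with pytest.raises(TrainingError):
            train(model, data, spec=spec)

    def test_epoch_log_length(self):
        data = _toy_data(n=8, signal=1.0)
        spec = DeepPsySpec(epochs=5, seed=0)
        _, log = train(DeepPsy(spec, (7, 24), 6), data, _toy_data(n=8, seed=9), spec)
        frame = log.to_frame()
        assert len(frame) == 5
        assert {"train_loss", "train_acc", "val_loss", "val_acc"} <= set(frame)


class TestCapacityAndCurve:
    @pytest.fixture(scope="class")
    def trained_on_separable(self, small_strong_cohort):
        data = make_dataset(small_strong_cohort, 60, seed=0)
        tr, val, te = split_data(len(data["labels"]), data["labels"], seed=0)
        sub = lambda idx: {k: data[k][idx] for k in ("grids", "features", "labels")}
        spec = DeepPsySpec(seed=0)
        model = DeepPsy(spec, data["grids"].shape[2:], data["features"].shape[1])
        model, log = train(model, sub(tr), sub(val), spec)
        return model, log

    def test_fits_separable_cohort(self, trained_on_separable):
        _, log = trained_on_separable
        assert log.to_frame()["train_acc"].iloc[-1] >= 0.95

    def test_loss_decreases_over_training(self, trained_on_separable):
        losses = trained_on_separable[1].to_frame()["train_loss"]
        assert np.median(losses[50:60]) < np.median(losses[0:10])


class TestFusionAblation:
    def test_zeroed_trajectory_ignores_grids(self):
        """Zeroing the trajectory branch reduces the model to a function
        of the tabular features only."""
        model = build_deeppsy(DeepPsySpec(seed=2))
        f = rng.normal(size=(4, 6))
        p1 = model.predict_proba(rng.random((4, 2, 7, 24)), f, zero_trajectory=True)
        p2 = model.predict_proba(rng.random((4, 2, 7, 24)), f, zero_trajectory=True)
        assert np.allclose(p1, p2)
        p3 = model.predict_proba(rng.random((4, 2, 7, 24)), f)
        assert not np.allclose(p1, p3)

    def test_basic_only_model_has_no_trajectory(self):
        model = build_deeppsy(DeepPsySpec(use_trajectory=False))
        assert not model.traj
        probs = model.predict_proba(None, rng.normal(size=(3, 6)))
        assert probs.shape == (3, 2)


class TestActivityGrid:
    def _record(self, sessions):
        return StudentRecord("S1", "junior", "F", [], sessions, [], 0, "none")

    def test_shape_and_values(self):
        # 90 minutes spanning 01:00-02:30 on day 0
        grid = activity_grid(self._record([(0, 60, 150)]), 14)
        assert grid.shape == (2, 7, 24)
        assert grid[0, 0, 1] == 1.0  # full hour 01:00-02:00
        assert grid[0, 0, 2] == pytest.approx(0.5)  # half of 02:00-03:00
        assert grid.sum() == pytest.approx(1.5)

    def test_entries_clipped_to_unit(self):
        grid = activity_grid(self._record([(0, 60, 120), (0, 61, 119)]), 7)
        assert grid.max() <= 1.0

    def test_days_beyond_window_ignored(self):
        grid = activity_grid(self._record([(13, 60, 120)]), 13)  # 1 week window
        assert grid.shape == (1, 7, 24)
        assert grid.sum() == 0.0


class TestSerialization:
    def test_checkpoint_roundtrip(self, tmp_path):
        data = _toy_data(n=8, signal=1.0)
        spec = DeepPsySpec(epochs=2, seed=0)
        model = DeepPsy(spec, (7, 24), 6)
        train(model, data, spec=spec)
        from deeppsy import load_model, save_model

        path = tmp_path / "ckpt.npz"
        save_model(model, path)
        back = load_model(path)
        p1 = back.predict_proba(data["grids"], data["features"])
        p2 = model.predict_proba(data["grids"], data["features"])
        assert np.array_equal(p1, p2)

    def test_grid_roundtrip(self, tmp_path):
        from deeppsy import load_grids, save_grids

        grids = rng.random((4, 2, 7, 24))
        save_grids(grids, tmp_path / "grids")
        assert np.array_equal(load_grids(tmp_path / "grids"), grids)
        assert (tmp_path / "grids.json").exists()


class TestMakeDataset:
    def test_shapes_and_columns(self, small_strong_cohort):
        data = make_dataset(small_strong_cohort, 60, seed=0)
        assert data["grids"].shape == (60, 8, 7, 24)
        assert data["features"].shape == (60, 6)
        assert set(data["labels"]) <= {0, 1}

    def test_column_subset(self, small_strong_cohort):
        data = make_dataset(
            small_strong_cohort, 60, seed=0, feature_columns=["gpa_avg"]
        )
        assert data["features"].shape == (60, 1)

    def test_severity_labels(self, small_strong_cohort):
        data = make_dataset(small_strong_cohort, 60, seed=0, binary=False)
        assert set(data["labels"]) <= {0, 1, 2, 3}
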