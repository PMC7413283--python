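"""The autoencoder: input preparation, forward pass, gradients, training,
imputation, and hyperparameter selection."""

import numpy as np
import pandas as pd
import pytest

from actimpute import (
    MissingMask,
    RecordSet,
    TrainConfig,
    ZIDCAE,
    clamped_tanh,
    corrupt_set,
    impute,
    impute_set,
    partial_rmse,
    prepare_input,
    rmse_loss,
)
from actimpute import nn
from actimpute.experiment import split_records
from actimpute.geometry import build_architecture
from actimpute.zidcae import select_best, train

from conftest import make_record


@pytest.fixture(scope="module")
def spec():
    return build_architecture(30, 60)


@pytest.fixture(scope="module")
def trained_model(spec):
    """A briefly trained model on a small synthetic set (shared, read-only)."""
    from actimpute import SynthParams, generate_dataset, preprocess

    record_set = preprocess(generate_dataset(SynthParams(n_subjects=30, days_per_subject=2, rng_seed=3)))
    labelled = split_records(record_set, 0.85, 0.15, 0)
    cfg = TrainConfig(max_epochs=4, batch_size=32, rng_seed=0)
    return train(labelled.split("train"), labelled.split("validation"), spec, cfg)


class TestPrepareInput:
    def test_scaling_token_and_clipping(self):
        values = np.array([0.0, 50.0, 100.0, 120.0])
        flags = np.array([False, True, False, False])
        out = prepare_input(values, flags, 100.0)
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0, 1.0])

    def test_masked_position_is_token_regardless_of_value(self):
        out = prepare_input(np.array([999.0]), np.array([True]), 100.0)
        assert out[0] == 0.5

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            prepare_input(np.zeros(3), None, 0.0)


class TestClampedTanh:
    def test_negative_maps_to_exact_zero(self):
        assert clamped_tanh(-3.0) == 0.0
        assert clamped_tanh(0.0) == 0.0

    def test_saturates_to_one(self):
        assert clamped_tanh(50.0) == pytest.approx(1.0, abs=1e-12)

    def test_range_bound(self, rng):
        x = rng.normal(scale=10, size=1000)
        y = clamped_tanh(x)
        assert np.all((y >= 0) & (y <= 1))


class TestRmseLoss:
    def test_identical_vectors(self, rng):
        x = rng.normal(size=720)
        assert rmse_loss(x, x) == 0.0

    def test_constant_offset(self, rng):
        x = rng.normal(size=720)
        assert rmse_loss(x + 0.25, x) == pytest.approx(0.25, rel=1e-12)

    def test_matches_elementwise_oracle(self, rng):
        a, b = rng.normal(size=720), rng.normal(size=720)
        brute = (sum((ai - bi) ** 2 for ai, bi in zip(a, b)) / 720) ** 0.5
        assert rmse_loss(a, b) == pytest.approx(brute, abs=1e-12)


class TestForward:
    def test_shapes_bounds_and_latent_length(self, spec, rng):
        model = ZIDCAE(spec, rng_seed=0)
        x = rng.uniform(0, 1, size=(3, 720))
        recon, latent = model.forward(x, training=True)
        assert recon.shape == (3, 720)
        assert latent.shape == (3, 128, 60)
        assert np.all((recon >= 0) & (recon <= 1))

    def test_output_bounded_for_arbitrary_weights(self, spec, rng):
        model = ZIDCAE(spec, rng_seed=1)
        for layer in model.net.layers:
            for name in layer.params:
                layer.params[name] = (rng.normal(scale=5.0, size=layer.params[name].shape)).astype(nn.DTYPE)
        recon, _ = model.forward(rng.uniform(0, 1, size=(2, 720)))
        assert np.all((recon >= 0) & (recon <= 1))
        assert np.all(np.isfinite(recon))

    def test_wrong_length_rejected(self, spec):
        with pytest.raises(ValueError):
            ZIDCAE(spec).forward(np.zeros((1, 700)))


class TestGradients:
    def test_backprop_matches_numeric_gradient(self, monkeypatch, rng):
        """Central-difference check of every parameter gradient on a tiny net."""
        monkeypatch.setattr(nn, "DTYPE", np.float64)
        layers = [
            nn.Conv1d(1, 2, 5, 2, rng), nn.BatchNorm1d(2), nn.Tanh(),
            nn.ConvTranspose1d(2, 1, 5, 2, rng), nn.ClampedTanh(),
        ]
        net = nn.Sequential(layers)
        x = rng.normal(size=(4, 1, 21))

        def loss():
            y = net.forward(x, training=True)
            return 0.5 * np.sum((y - 0.3) ** 2)

        y = net.forward(x, training=True)
        net.backward(y - 0.3)
        h = 1e-6
        for layer in layers:
            for name, p in layer.params.items():
                it = np.nditer(p, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = p[idx]
                    p[idx] = orig + h
                    lp = loss()
                    p[idx] = orig - h
                    lm = loss()
                    p[idx] = orig
                    num = (lp - lm) / (2 * h)
                    assert layer.grads[name][idx] == pytest.approx(num, rel=1e-5, abs=1e-7)


class TestTraining:
    def test_loss_decreases_and_history_recorded(self, trained_model):
        hist = trained_model.history["train_loss"]
        assert len(hist) >= 2
        assert hist[-1] < hist[0]
        assert trained_model.trained
        assert trained_model.scale_max > 0

    def test_same_seed_identical_training(self, spec):
        from actimpute import SynthParams, generate_dataset, preprocess

        record_set = preprocess(generate_dataset(SynthParams(n_subjects=12, days_per_subject=1, rng_seed=5)))
        labelled = split_records(record_set, 0.8, 0.2, 1)
        cfg = TrainConfig(max_epochs=2, batch_size=16, rng_seed=7)
        a = train(labelled.split("train"), labelled.split("validation"), spec, cfg)
        b = train(labelled.split("train"), labelled.split("validation"), spec, cfg)
        assert a.history["val_partial_rmse"] == b.history["val_partial_rmse"]
        for la, lb in zip(a.net.layers, b.net.layers):
            for name in la.params:
                np.testing.assert_array_equal(la.params[name], lb.params[name])

    def test_empty_training_set_rejected(self, spec):
        with pytest.raises(ValueError):
            train(RecordSet([]), RecordSet([]), spec, TrainConfig())


class TestImpute:
    def test_empty_mask_is_identity(self, trained_model, rng):
        rec = make_record(rng.integers(0, 500, 720).astype(float))
        out = impute(trained_model, rec, MissingMask.empty(720))
        np.testing.assert_array_equal(out.values, rec.values)

    def test_unmasked_cells_bit_identical_and_range(self, trained_model, rng):
        rec = make_record(rng.integers(0, 500, 720).astype(float))
        mask = MissingMask.from_interval(720, 100, 30)
        out = impute(trained_model, rec, mask)
        np.testing.assert_array_equal(out.values[~mask.flags], rec.values[~mask.flags])
        imputed = out.values[mask.flags]
        assert np.all((imputed >= 0) & (imputed <= trained_model.scale_max))

    def test_untrained_model_rejected(self, spec, rng):
        rec = make_record(rng.integers(0, 500, 720).astype(float))
        with pytest.raises(ValueError):
            impute(ZIDCAE(spec), rec, MissingMask.empty(720))

    def test_impute_set_matches_single_record_impute(self, trained_model, rng):
        records = [make_record(rng.integers(0, 500, 720).astype(float), subject=f"S{i}") for i in range(3)]
        masks = [MissingMask.from_interval(720, 50 + 10 * i, 30) for i in range(3)]
        batch = impute_set(trained_model, RecordSet(records, masks))
        for rec, mask, out in zip(records, masks, batch.records):
            single = impute(trained_model, rec, mask)
            np.testing.assert_allclose(out.values, single.values, atol=1e-4)


class TestCheckpoint:
    def test_save_load_round_trip(self, trained_model, tmp_path, rng):
        path = tmp_path / "model.npz"
        trained_model.save(path)
        loaded = ZIDCAE.load(path)
        assert loaded.scale_max == trained_model.scale_max
        x = rng.uniform(0, 1, size=(2, 720))
        a, _ = trained_model.forward(x)
        b, _ = loaded.forward(x)
        np.testing.assert_array_equal(a, b)


class TestGridSearch:
    def test_single_cell_grid_returns_it(self, windowed_set):
        from actimpute.zidcae import cv_grid_search

        cfg = TrainConfig(max_epochs=1, batch_size=32, rng_seed=0)
        best_m, best_k, table = cv_grid_search(windowed_set, ms=(30,), ks=(60,), folds=2, cfg=cfg)
        assert (best_m, best_k) == (30, 60)
        assert len(table) == 1
        # partition property: every record in exactly one validation fold
        assert table.filter(like="fold").notna().all().all()

    def test_published_cv_table_selects_30_60(self):
        """Injected per-cell mean RMSEs reproducing the published 10-fold grid."""
        table = pd.DataFrame(
            {
                "k": [40, 40, 60, 60, 80, 80],
                "m": [20, 30, 20, 30, 20, 30],
                "mean_rmse": [830.5, 838.0, 858.7, 788.4, 825.1, 831.0],
            }
        )
        assert select_best(table) == (30, 60)

    def test_empty_grid_rejected(self, windowed_set):
        from actimpute.zidcae import cv_grid_search

        with pytest.raises(ValueError):
            cv_grid_search(windowed_set, ms=(), ks=(60,), folds=2)

    def test_fold_partition_is_seeded_and_exhaustive(self, windowed_set):
        rng_a = np.random.default_rng(4)
        # the fold assignment logic: seeded permutation modulo folds
        n = len(windowed_set)
        perm = rng_a.permutation(n)
        fold_of = np.empty(n, int)
        for pos, idx in enumerate(perm):
            fold_of[idx] = pos % 5
        assert sorted(np.bincount(fold_of).tolist()) == sorted(
            [len(v) for v in np.array_split(np.arange(n), 5)]
        )
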