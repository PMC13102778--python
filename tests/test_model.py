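"""Architecture constants, split hygiene, training protocol, ensembling."""

import numpy as np
import pandas as pd
import pytest

from spherovia.model import (
    ModelConfig,
    TrainConfig,
    TrainedEnsemble,
    ViabilityRegressor,
    build_model,
    chronological_split,
    preprocess_images,
    train,
)

TINY = ModelConfig(backbone="tiny_test", channels=1, input_size=64,
                   dropout=0.0)


@pytest.fixture(scope="module")
def tiny_batch(render_batch):
    data = render_batch(96, seed0=3100)
    vs = np.array([v for v, _, _ in data])
    imgs = [img for _, img, _ in data]
    return vs, imgs


class TestArchitecture:
    def test_default_parameter_count_rounds_to_eleven_million(self):
        model = build_model()
        assert model.n_parameters == 11_196_129
        assert round(model.n_parameters / 1e6) == 11

    def test_head_parameter_count_by_direct_enumeration(self):
        # 512->32 (+bias), 3x 32->32 (+bias), 32->1 (+bias)
        expected = (512 * 32 + 32) + 3 * (32 * 32 + 32) + (32 * 1 + 1)
        assert expected == 19_617
        assert build_model().n_head_parameters == expected

    def test_tiny_backbone_forward_contract(self):
        model = build_model(TINY, seed=0)
        x = np.random.default_rng(0).random((2, 1, 64, 64))
        out = model.forward(x)
        assert out.shape == (2,)
        assert model.encode(x).shape == (2, 64)

    @pytest.mark.parametrize("backbone,latent", [
        ("resnet18_like", 512), ("efficientnet_small_like", 1280),
        ("vit_like", 192),
    ])
    def test_latent_dimensions_per_backbone(self, backbone, latent):
        cfg = ModelConfig(backbone=backbone, channels=1, input_size=64)
        model = build_model(cfg, seed=0)
        x = np.random.default_rng(1).random((2, 1, 64, 64))
        assert model.encode(x).shape == (2, latent)
        assert cfg.latent_dim == latent

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="unknown backbone"):
            ModelConfig(backbone="resnet50_like")

    def test_dropout_range_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(dropout=1.0)


class TestPreprocessing:
    def test_resize_replicate_standardize(self):
        imgs = [np.full((96, 96), 0.5), np.full((40, 52), 0.75)]
        cfg = ModelConfig(backbone="tiny_test", channels=3, input_size=64)
        x = preprocess_images(imgs, cfg)
        assert x.shape == (2, 3, 64, 64)
        assert x[0].max() == pytest.approx(0.0, abs=1e-9)   # (0.5-0.5)/0.25
        assert x[1].mean() == pytest.approx(1.0, abs=1e-6)  # (0.75-0.5)/0.25
        np.testing.assert_array_equal(x[0, 0], x[0, 2])

    def test_tiny_images_rejected(self):
        with pytest.raises(ValueError, match="crop minimum"):
            preprocess_images([np.zeros((2, 30))], TINY)


class TestChronologicalSplit:
    def _frame(self, studies):
        return pd.DataFrame({"Study": np.repeat(studies, 3),
                             "row": range(3 * len(studies))})

    def test_partition_by_cutoff_key(self):
        df = self._frame(["S1", "S2", "S3", "S4", "S5"])
        train_df, test_df = chronological_split(df, cutoff="S4")
        assert set(train_df["Study"]) == {"S1", "S2", "S3"}
        assert set(test_df["Study"]) == {"S4", "S5"}

    def test_partition_by_explicit_study_list(self):
        df = self._frame(["S1", "S2", "S3"])
        train_df, test_df = chronological_split(df, cutoff=["S1", "S3"])
        assert set(train_df["Study"]) == {"S1", "S3"}
        assert set(test_df["Study"]) == {"S2"}

    def test_study_order_mapping(self):
        df = self._frame(["A", "B", "C"])
        order = {"A": "2022-01-01", "B": "2022-09-01", "C": "2022-03-01"}
        train_df, test_df = chronological_split(df, cutoff="2022-07-28",
                                                study_order=order)
        assert set(train_df["Study"]) == {"A", "C"}
        assert set(test_df["Study"]) == {"B"}

    def test_no_study_leaks_across_sides(self):
        df = self._frame([f"S{i}" for i in range(8)])
        train_df, test_df = chronological_split(df, cutoff="S5")
        assert not set(train_df["Study"]) & set(test_df["Study"])

    def test_empty_test_set_warns(self):
        df = self._frame(["S1", "S2"])
        with pytest.warns(UserWarning, match="empty test"):
            chronological_split(df, cutoff="S9")

    def test_unknown_study_in_list_rejected(self):
        with pytest.raises(ValueError, match="unknown study"):
            chronological_split(self._frame(["S1"]), cutoff=["S1", "SX"])


class TestTraining:
    def test_default_seed_grid_yields_nine_models(self, tiny_batch):
        vs, imgs = tiny_batch
        tc = TrainConfig(learning_rate=1e-3, max_epochs=1)
        ens = train(TINY, imgs[:40], vs[:40], tc)
        assert len(ens.models) == 9
        assert tc.n_replicates == 9
        assert len({s for s in ens.seeds}) == 9

    def test_training_is_deterministic(self, tiny_batch):
        vs, imgs = tiny_batch
        tc = TrainConfig(learning_rate=1e-3, max_epochs=2, init_seeds=(1,),
                         split_seeds=(2,))
        h1 = train(TINY, imgs[:40], vs[:40], tc).histories[0]
        h2 = train(TINY, imgs[:40], vs[:40], tc).histories[0]
        assert h1["train_mse"].iloc[0] == h2["train_mse"].iloc[0]
        pd.testing.assert_frame_equal(h1, h2)

    def test_tiny_model_memorizes_small_dataset(self, tiny_batch):
        vs, imgs = tiny_batch
        tc = TrainConfig(learning_rate=1e-2, weight_decay=0.0,
                         max_epochs=150, early_stop_patience=150,
                         init_seeds=(0,), split_seeds=(0,), val_fraction=0.05)
        ens = train(TINY, imgs[:64], vs[:64], tc)
        assert ens.histories[0]["train_mse"].iloc[-1] < 0.01

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train(TINY, [], [])

    def test_history_records_schedule_state(self, tiny_batch):
        vs, imgs = tiny_batch
        tc = TrainConfig(learning_rate=1e-3, max_epochs=3, init_seeds=(0,),
                         split_seeds=(0,))
        h = train(TINY, imgs[:40], vs[:40], tc).history_frame()
        assert {"epoch", "train_mse", "val_mse", "lr", "plateau_counter",
                "stop_counter", "init_seed", "split_seed"} <= set(h.columns)


class TestEnsemble:
    @pytest.fixture(scope="class")
    def trained(self, tiny_batch):
        vs, imgs = tiny_batch
        tc = TrainConfig(learning_rate=5e-3, max_epochs=20,
                         early_stop_patience=20, init_seeds=(0, 1),
                         split_seeds=(0,))
        return train(TINY, imgs[:80], vs[:80], tc), imgs[80:], vs[80:]

    def test_single_model_ensemble_has_zero_sd(self, tiny_batch):
        vs, imgs = tiny_batch
        tc = TrainConfig(learning_rate=1e-3, max_epochs=1, init_seeds=(0,),
                         split_seeds=(0,))
        ens = train(TINY, imgs[:40], vs[:40], tc)
        _, sd = ens.predict(imgs[40:44])
        np.testing.assert_allclose(sd, 0.0)

    def test_duplicated_image_gets_identical_predictions(self, trained):
        ens, imgs, _ = trained
        mean, _ = ens.predict([imgs[0], imgs[0]])
        assert mean[0] == mean[1]

    def test_ensemble_mean_not_much_worse_than_best_member(self, trained):
        ens, imgs, vs = trained
        mean, _ = ens.predict(imgs)
        per = ens.predict_per_model(imgs)
        mse_mean = float(np.mean((mean - vs) ** 2))
        mse_best = min(float(np.mean((p - vs) ** 2)) for p in per)
        assert mse_mean <= 1.1 * mse_best

    def test_encode_matches_latent_dim_and_feeds_pca(self, trained):
        from spherovia.latent import pca_top_k

        ens, imgs, _ = trained
        z = ens.encode(imgs)
        assert z.shape == (len(imgs), 64)
        decomp = pca_top_k(z, k=5)
        assert decomp.scores.shape == (len(imgs), 5)

    def test_identical_images_encode_identically(self, trained):
        ens, imgs, _ = trained
        z = ens.encode([imgs[0], imgs[0]])
        np.testing.assert_array_equal(z[0], z[1])

    def test_save_load_round_trip(self, trained, tmp_path):
        ens, imgs, _ = trained
        model = ens.models[0]
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = ViabilityRegressor.load(path)
        x = preprocess_images(imgs[:4], TINY)
        np.testing.assert_allclose(loaded.predict(x), model.predict(x),
                                   atol=1e-12)
        assert loaded.config_hash == model.config_hash
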