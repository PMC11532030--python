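import numpy as np
import pytest

from kcatpred import (
    CNNSearchSpace,
    FeatureBlock,
    FeatureStore,
    generate_linear_problem,
    random_search_cnn,
    sample_cnn_config,
    stack_feature_blocks,
    train_cnn,
)
from kcatpred.errors import ArchitectureError, ParameterError, SelectionError, ShapeError

SMALL_CONFIG = {
    "filters": (4, 6, 8),
    "kernels": (3, 3, 3),
    "fc_neurons": 32,
    "optimizer": "adam",
    "batch_size": 16,
    "dropout_rate": 0.0,
    "learning_rate": 0.01,
}


class TestSampleConfig:
    def test_thousand_samples_respect_ranges_and_odd_kernels(self):
        space = CNNSearchSpace()
        for seed in range(1000):
            cfg = sample_cnn_config(space, seed)
            for (lo, hi), f in zip(space.filters, cfg["filters"]):
                assert lo <= f <= hi and (f - lo) % 2 == 0
            for (lo, hi), k in zip(space.kernels, cfg["kernels"]):
                assert lo <= k <= hi and k % 2 == 1
            assert cfg["fc_neurons"] in (16, 32, 64, 128, 256)
            assert cfg["optimizer"] in ("nadam", "adam", "rmsprop")
            assert 8 <= cfg["batch_size"] <= 128
            assert 0.0 <= cfg["dropout_rate"] <= 0.5

    def test_same_seed_identical_config(self):
        space = CNNSearchSpace()
        assert sample_cnn_config(space, 5) == sample_cnn_config(space, 5)


class TestStackFeatureBlocks:
    def _store(self, n=4):
        ids = [f"s{i}" for i in range(n)]
        rng = np.random.default_rng(0)
        store = FeatureStore(sample_ids=ids)
        store.add(FeatureBlock("emb_base", rng.standard_normal((n, 1280)), ids))
        store.add(
            FeatureBlock(
                "fp_structural", rng.integers(0, 2, (n, 4096)).astype(np.uint8), ids
            )
        )
        store.add(
            FeatureBlock(
                "fp_differential", rng.integers(0, 2, (n, 2048)).astype(np.uint8), ids
            )
        )
        return store

    def test_single_block_shape(self):
        t = stack_feature_blocks(self._store(), ["fp_differential"])
        assert t.shape == (4, 1, 2048)

    def test_mixed_dims_pad_with_zeros(self):
        t = stack_feature_blocks(
            self._store(), ["fp_structural", "fp_differential", "emb_base"]
        )
        assert t.shape == (4, 3, 4096)
        assert (t[:, 1, 2048:] == 0).all()  # padded tail of the 2048 block
        assert (t[:, 2, 1280:] == 0).all()  # padded tail of the 1280 block

    def test_unknown_block_rejected(self):
        with pytest.raises(SelectionError, match="nope"):
            stack_feature_blocks(self._store(), ["nope"])


class TestTrainCnn:
    def test_constant_target_reaches_variance_floor(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((80, 1, 32))
        y = np.full(80, 2.5)
        model = train_cnn(X, y, SMALL_CONFIG, seed=1, max_epochs=30)
        assert min(model.training_log) <= np.var(y) + 1e-6

    def test_beats_mean_predictor_on_linear_signal(self):
        Xf, y, _ = generate_linear_problem(400, n_features=32, noise_sd=0.1, seed=2)
        model = train_cnn(
            Xf[:, None, :], y, SMALL_CONFIG, seed=2, max_epochs=150, patience=30
        )
        assert min(model.training_log) < np.var(y)

    def test_early_stopping_halts_on_pure_noise(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 1, 32))
        y = rng.standard_normal(60)
        model = train_cnn(X, y, SMALL_CONFIG, seed=3, max_epochs=200, patience=3)
        assert len(model.training_log) < 200

    def test_kernel_longer_than_input_is_architecture_error(self):
        cfg = dict(SMALL_CONFIG, kernels=(31, 3, 3))
        with pytest.raises(ArchitectureError):
            train_cnn(np.zeros((20, 1, 16)), np.zeros(20), cfg, seed=0)

    def test_batch_larger_than_samples_rejected(self):
        cfg = dict(SMALL_CONFIG, batch_size=64)
        with pytest.raises(ParameterError):
            train_cnn(np.zeros((10, 1, 32)), np.zeros(10), cfg, seed=0)

    def test_training_reproducible_given_seed(self):
        Xf, y, _ = generate_linear_problem(120, n_features=24, seed=4)
        m1 = train_cnn(Xf[:, None, :], y, SMALL_CONFIG, seed=7, max_epochs=8)
        m2 = train_cnn(Xf[:, None, :], y, SMALL_CONFIG, seed=7, max_epochs=8)
        assert m1.training_log == m2.training_log
        assert np.array_equal(m1.predict(Xf[:, None, :]), m2.predict(Xf[:, None, :]))

    def test_predict_contract(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 2, 24))
        model = train_cnn(X, rng.standard_normal(40), SMALL_CONFIG, seed=5, max_epochs=3)
        assert model.predict(X[:0]).shape == (0,)
        out = model.predict(np.tile(X[:1], (5, 1, 1)))
        assert np.ptp(out) < 1e-9  # pure function of the input row
        with pytest.raises(ShapeError):
            model.predict(np.zeros((3, 2, 99)))

    @pytest.mark.parametrize("optimizer", ["nadam", "adam", "rmsprop"])
    def test_all_optimizers_reduce_loss(self, optimizer):
        Xf, y, _ = generate_linear_problem(200, n_features=32, noise_sd=0.0, seed=6)
        cfg = dict(SMALL_CONFIG, optimizer=optimizer)
        model = train_cnn(Xf[:, None, :], y, cfg, seed=6, max_epochs=80, patience=20)
        assert min(model.training_log) < model.training_log[0]


class TestRandomSearchCnn:
    def _data(self):
        Xf, y, _ = generate_linear_problem(100, n_features=64, seed=7)
        return Xf[:, None, :], y

    def test_single_trial_log(self):
        X, y = self._data()
        space = CNNSearchSpace(batch_size=(8, 32), kernels=((3, 5), (3, 5), (3, 5)))
        log, ranked = random_search_cnn(X, y, space, n_trials=1, seed=8, max_epochs=3)
        assert len(log.trials) == 1 and len(ranked) == 1

    def test_ranked_losses_nondecreasing_and_top_k(self):
        X, y = self._data()
        space = CNNSearchSpace(batch_size=(8, 32), kernels=((3, 5), (3, 5), (3, 5)))
        log, ranked = random_search_cnn(X, y, space, n_trials=4, seed=9, max_epochs=3)
        finite = sorted(l for l in log.losses if np.isfinite(l))
        ranked_losses = [
            log.losses[i] for i in log.ranked() if np.isfinite(log.losses[i])
        ]
        assert ranked_losses == finite
        assert len(ranked) == len(finite)
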