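import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kcatpred import (
    EnsembleWeights,
    PredictionPanel,
    PredictionPanelSpec,
    generate_prediction_panel,
    optimize_weights,
    select_top_models,
    weighted_average,
)
from kcatpred.errors import DataError, ParameterError, ShapeError

from _oracles import grid_search_weights


def _random_panel(seed, n=200, m=3):
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(n)
    sigmas = tuple(rng.uniform(0.2, 2.0, m))
    bias = tuple(rng.uniform(-0.5, 0.5, m))
    return generate_prediction_panel(
        y, PredictionPanelSpec(n=n, sigmas=sigmas, rho=0.2, bias=bias, seed=seed)
    )


class TestOptimizeWeights:
    def test_single_member_gets_weight_one(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(50)
        panel = PredictionPanel(
            preds=(y + rng.normal(0, 0.5, 50))[:, None],
            model_ids=["only"],
            y_true=y,
        )
        w = optimize_weights(panel)
        assert w.w.tolist() == [1.0]
        assert w.loss_at_optimum == pytest.approx(panel.member_losses()[0])

    def test_inverse_variance_recovery(self):
        y = np.zeros(10000)
        panel = generate_prediction_panel(
            y, PredictionPanelSpec(n=10000, sigmas=(1.0, 2.0), rho=0.0, seed=1)
        )
        w = optimize_weights(panel)
        assert abs(w.w[0] - 0.8) < 0.05 and abs(w.w[1] - 0.2) < 0.05
        # agreement with the brute-force grid oracle on the same panel
        w_grid, loss_grid = grid_search_weights(panel.preds, panel.y_true, step=0.001)
        assert np.abs(w.w - w_grid).max() < 0.05
        assert w.loss_at_optimum <= loss_grid + 1e-4

    def test_perfect_member_dominates(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(100)
        preds = np.column_stack([y, y + rng.normal(0, 1, 100)])
        panel = PredictionPanel(preds=preds, model_ids=["exact", "noisy"], y_true=y)
        w = optimize_weights(panel)
        assert w.w[0] >= 0.999
        assert w.loss_at_optimum <= 1e-8

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(5, 120),
        m=st.integers(1, 5),
    )
    def test_dominance_over_members_and_uniform_mean(self, seed, n, m):
        panel = _random_panel(seed, n=n, m=m)
        w = optimize_weights(panel)
        assert w.loss_at_optimum <= panel.member_losses().min() + 1e-12
        uniform = np.full(panel.n_models, 1 / panel.n_models)
        uniform_loss = np.mean((panel.preds @ uniform - panel.y_true) ** 2)
        assert w.loss_at_optimum <= uniform_loss + 1e-12

    @pytest.mark.parametrize("m", [2, 3])
    def test_matches_simplex_grid_oracle(self, m):
        panel = _random_panel(seed=10 + m, n=300, m=m)
        w = optimize_weights(panel)
        _, loss_grid = grid_search_weights(panel.preds, panel.y_true, step=0.001)
        assert w.loss_at_optimum <= loss_grid + 1e-4

    def test_column_permutation_permutes_weights(self):
        panel = _random_panel(seed=20)
        w = optimize_weights(panel).w
        perm = [2, 0, 1]
        permuted = PredictionPanel(
            preds=panel.preds[:, perm],
            model_ids=[panel.model_ids[i] for i in perm],
            y_true=panel.y_true,
        )
        w_perm = optimize_weights(permuted).w
        assert np.allclose(w_perm, w[perm], atol=1e-6)

    def test_deterministic_given_panel(self):
        panel = _random_panel(seed=30)
        assert np.array_equal(optimize_weights(panel).w, optimize_weights(panel).w)

    def test_non_finite_panel_rejected(self):
        with pytest.raises(DataError):
            PredictionPanel(
                preds=np.array([[np.inf]]), model_ids=["m"], y_true=np.zeros(1)
            )

    def test_unsupported_loss_rejected(self):
        with pytest.raises(ParameterError):
            optimize_weights(_random_panel(seed=40), loss="mae")


class TestEnsembleWeightsInvariants:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            EnsembleWeights(w=np.array([0.6, 0.6]), loss_at_optimum=0.0)

    def test_weights_must_be_within_unit_interval(self):
        with pytest.raises(ValueError):
            EnsembleWeights(w=np.array([1.5, -0.5]), loss_at_optimum=0.0)


class TestWeightedAverage:
    def test_uniform_weights_reduce_to_mean(self):
        preds = np.random.default_rng(0).standard_normal((10, 4))
        out = weighted_average(preds, np.full(4, 0.25))
        assert np.allclose(out, preds.mean(axis=1))

    def test_one_hot_selects_member(self):
        preds = np.random.default_rng(1).standard_normal((10, 3))
        out = weighted_average(preds, np.array([0.0, 1.0, 0.0]))
        assert np.array_equal(out, preds[:, 1])

    def test_hand_computed_combination(self):
        preds = np.array([[0.0, 4.0], [2.0, 6.0]])
        out = weighted_average(preds, np.array([0.25, 0.75]))
        assert np.allclose(out, [3.0, 5.0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            weighted_average(np.zeros((5, 2)), np.array([1.0, 0.0, 0.0]))


class TestSelectTopModels:
    def test_k_equals_m_returns_all(self):
        assert set(select_top_models([0.3, 0.1, 0.2], k=3)) == {0, 1, 2}

    def test_smallest_k_losses(self):
        assert set(select_top_models([0.5, 0.3, 0.9, 0.7], k=3)) == {1, 0, 3}

    def test_tie_breaks_to_lower_index(self):
        assert select_top_models([0.5, 0.5, 0.9], k=1) == [0]

    def test_invalid_k_rejected(self):
        with pytest.raises(ParameterError):
            select_top_models([0.1], k=0)
        with pytest.raises(ParameterError):
            select_top_models([0.1], k=2)
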