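"""Shapley axioms on analytic games, estimator convergence, aggregation."""

import numpy as np
import pytest

import ecgfusion as ef
from ecgfusion.interpretability import (
    MaskingScheme,
    exact_lead_shapley,
    lead_importance,
    per_class_importance,
    sampled_lead_shapley,
)

SIG = np.random.default_rng(0).normal(0, 1, size=(40, 12))


def additive_game(weights):
    """v(S) = sum over included leads of w_l * mean(lead_l)."""
    w = np.asarray(weights)

    def value_fn(batch):
        return (batch.mean(axis=1) * w).sum(axis=1)

    return value_fn


def interaction_game():
    """Nonlinear game with pairwise interactions (for estimator tests)."""

    def value_fn(batch):
        m = batch.mean(axis=1)
        return np.tanh(m[:, 0] + 0.5 * m[:, 3] * m[:, 7] + 0.3 * m[:, 11])

    return value_fn


class TestExactShapley:
    def test_additivity_axiom_recovers_coefficients(self):
        w = np.linspace(-1, 1, 12)
        phi = exact_lead_shapley(additive_game(w), SIG)
        expected = SIG.mean(axis=0) * w  # contribution of each lead alone
        assert np.allclose(phi, expected, atol=1e-9)

    def test_dummy_axiom_single_relevant_lead(self):
        value_fn = additive_game(np.eye(12)[1])  # depends only on lead II
        phi = exact_lead_shapley(value_fn, SIG)
        assert np.allclose(np.delete(phi, 1), 0.0, atol=1e-12)
        v_all = value_fn(SIG[None])[0]
        v_none = value_fn(np.zeros_like(SIG)[None])[0]
        assert phi[1] == pytest.approx(v_all - v_none)

    def test_null_player_constant_model(self):
        phi = exact_lead_shapley(lambda b: np.ones(b.shape[0]), SIG)
        assert np.allclose(phi, 0.0)

    def test_efficiency_on_nonlinear_game(self):
        value_fn = interaction_game()
        phi = exact_lead_shapley(value_fn, SIG)
        v_all = value_fn(SIG[None])[0]
        v_none = value_fn(np.zeros_like(SIG)[None])[0]
        assert abs(phi.sum() - (v_all - v_none)) < 1e-6

    def test_wrong_lead_count_rejected(self):
        with pytest.raises(ValueError):
            exact_lead_shapley(interaction_game(), np.zeros((40, 5)))

    def test_mean_baseline_scheme(self):
        baseline = SIG.mean(axis=0, keepdims=True) * np.ones_like(SIG)
        scheme = MaskingScheme(baseline="mean", baseline_signal=baseline)
        value_fn = interaction_game()
        phi = exact_lead_shapley(value_fn, SIG, scheme=scheme)
        v_all = value_fn(SIG[None])[0]
        v_none = value_fn(baseline[None] if baseline.ndim == 2 else baseline)[0]
        assert abs(phi.sum() - (v_all - v_none)) < 1e-6


class TestSampledShapley:
    def test_seeded_determinism(self):
        fn = interaction_game()
        a = sampled_lead_shapley(fn, SIG, n_permutations=20, seed=5)
        b = sampled_lead_shapley(fn, SIG, n_permutations=20, seed=5)
        assert np.array_equal(a, b)

    def test_invalid_permutation_count(self):
        with pytest.raises(ValueError):
            sampled_lead_shapley(interaction_game(), SIG, n_permutations=0)

    def test_convergence_to_exact_oracle(self):
        fn = interaction_game()
        exact = exact_lead_shapley(fn, SIG)
        errors = []
        for n_perm in (10, 100, 1500):
            est = sampled_lead_shapley(fn, SIG, n_permutations=n_perm, seed=0)
            errors.append(np.abs(est - exact).mean())
        assert errors[-1] < 0.01  # MAE at the largest setting
        assert errors[-1] < errors[0]

    def test_single_relevant_lead_within_mc_error(self):
        fn = additive_game(np.eye(12)[4])
        exact = exact_lead_shapley(fn, SIG)
        est = sampled_lead_shapley(fn, SIG, n_permutations=50, seed=1)
        # additive game: every permutation gives the same marginal, so the
        # estimate is exact up to float error
        assert np.allclose(est, exact, atol=1e-9)


class TestLeadImportance:
    def test_single_sample_identity(self):
        phi = np.eye(12)[0][None]
        li = lead_importance(phi)
        assert np.array_equal(li.importance, np.eye(12)[0])
        assert li.n_samples == 1

    def test_sign_symmetry(self):
        phi = np.random.default_rng(2).normal(size=(1, 12))
        both = lead_importance(np.vstack([phi, -phi]))
        one = lead_importance(phi)
        assert np.allclose(both.importance, one.importance)

    def test_matches_bruteforce_mean_absolute(self):
        mat = np.random.default_rng(3).normal(size=(100, 12))
        li = lead_importance(mat)
        brute = np.abs(mat).mean(axis=0)
        assert np.allclose(li.importance, brute)

    def test_sum_to_one_normalization(self):
        mat = np.random.default_rng(4).normal(size=(10, 12))
        li = lead_importance(mat, normalization="sum-to-one")
        assert li.importance.sum() == pytest.approx(1.0, abs=1e-9)
        assert (li.importance >= 0).all()

    def test_signed_mean_option(self):
        mat = np.random.default_rng(5).normal(size=(10, 12))
        li = lead_importance(mat, signed=True)
        assert np.allclose(li.importance, mat.mean(axis=0))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            lead_importance(np.empty((0, 12)))


class TestPerClassImportance:
    def test_constant_model_gives_zero_importance(self, binary_corpus):
        scenario = ef.binary_superclass("MI")
        parts = ef.materialize(binary_corpus, scenario)
        ds = parts["test"] if len(parts["test"]) else parts["train"]
        model = ef.build_model(
            ef.ModelConfig("custom_cnn", 1000, 2, use_demographics=False,
                           seed=0)
        )
        final = model.head.layers[-1]
        final.params["W"][:] = 0.0
        final.params["b"][:] = 0.0
        out = per_class_importance(model, ds, n_permutations=2, seed=0,
                                   max_records_per_class=2)
        for li in out:
            assert np.allclose(li.importance, 0.0, atol=1e-7)

    def test_missing_class_warns_and_is_omitted(self, binary_corpus):
        scenario = ef.binary_superclass("MI")
        parts = ef.materialize(binary_corpus, scenario)
        only_norm = ef.LabeledDataset(
            records=[(r, y) for r, y in parts["train"].records if y == 0],
            partition="train", scenario=scenario,
        )
        model = ef.build_model(
            ef.ModelConfig("custom_cnn", 1000, 2, use_demographics=False,
                           seed=0)
        )
        with pytest.warns(RuntimeWarning, match="no records"):
            out = per_class_importance(model, only_norm, n_permutations=1,
                                       seed=0, max_records_per_class=1)
        assert [li.class_label for li in out] == ["NORM"]
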