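"""Deep CCA: branch forward contracts, training behaviour and projections."""

import numpy as np
import pytest

from cardicca import DCCAHyperparams, DeepCCA, branch_forward, linear_cca, project, train_dcca
from cardicca.cca import CCAResult
from cardicca.exceptions import ConfigurationError, ValidationError
from cardicca.preprocessing import LatentMatrix, View


@pytest.fixture(scope="module")
def self_pair_model(rng):
    """DCCA trained on exact view copies — the alignment sanity task."""
    r = np.random.default_rng(10)
    x = r.normal(size=(30, 6, 12))
    model = DeepCCA(k_dcca=3, learning_rate=0.01, epochs=150, seed=0)
    model.fit((x, x.copy()))
    return x, model


class TestBranchForward:
    def test_zero_input_zero_biases_gives_zero(self):
        # biases initialize at zero, so ReLU/pool propagate an all-zero matrix
        from cardicca import nn
        branch = nn.build_branch(2, np.random.default_rng(0))
        out = branch.forward(np.zeros((1, 1, 6, 12)))
        np.testing.assert_array_equal(out, 0.0)

    def test_deterministic_across_runs(self, self_pair_model):
        x, model = self_pair_model
        m = LatentMatrix(x[0], View.view1, "s0")
        a = branch_forward(model, m, View.view1)
        b = branch_forward(model, m, View.view1)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (3,) and np.all(np.isfinite(a))

    def test_linear_probe_is_affine_in_temporal_means(self, rng):
        x = rng.normal(size=(10, 4, 25))
        model = DeepCCA(k_dcca=2, learning_rate=0.001, epochs=2,
                        linear_probe=True, seed=1).fit((x, x.copy()))
        w, b = model.branch1_.params  # (k, d, 1, 1) and (k,)
        means = x.mean(axis=2)  # (n, d)
        expected = means @ w[:, :, 0, 0].T + b
        got = model.branch1_.forward(model._branch_input(x))
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestTrainDCCA:
    def test_self_pair_reaches_near_perfect_correlation(self, self_pair_model):
        _, model = self_pair_model
        assert model.objective_ >= 0.95 * 3

    def test_objective_bounded_and_trending_up(self, self_pair_model):
        _, model = self_pair_model
        curve = model.training_curve_
        assert np.all(curve >= -1e-9) and np.all(curve <= 3 + 1e-9)
        assert np.median(curve[-50:]) >= np.median(curve[:50])

    def test_seeded_determinism(self):
        r = np.random.default_rng(4)
        x1 = r.normal(size=(12, 4, 10))
        x2 = r.normal(size=(12, 4, 10))
        a = DeepCCA(k_dcca=2, epochs=10, seed=7).fit((x1, x2))
        b = DeepCCA(k_dcca=2, epochs=10, seed=7).fit((x1, x2))
        assert a.objective_ == b.objective_
        np.testing.assert_array_equal(a.training_curve_, b.training_curve_)

    def test_linear_regime_matches_closed_form_cca(self, rng):
        n, d, T = 100, 4, 25
        z = rng.normal(size=(n, 3))
        x1m = z @ rng.normal(size=(3, d)) + 0.5 * rng.normal(size=(n, d))
        x2m = z @ rng.normal(size=(3, d)) + 0.5 * rng.normal(size=(n, d))
        tn1 = rng.normal(size=(n, d, T))
        tn1 -= tn1.mean(axis=2, keepdims=True)
        tn2 = rng.normal(size=(n, d, T))
        tn2 -= tn2.mean(axis=2, keepdims=True)
        X1 = x1m[:, :, None] + tn1
        X2 = x2m[:, :, None] + tn2
        oracle = linear_cca(x1m, x2m, k=2, reg=1e-4).correlations.sum()
        model = DeepCCA(k_dcca=2, learning_rate=0.01, epochs=300,
                        linear_probe=True, seed=0).fit((X1, X2))
        assert model.objective_ == pytest.approx(oracle, abs=0.02)

    def test_train_dcca_wrapper_accepts_matrix_pairs(self, rng):
        pairs = [(LatentMatrix(rng.normal(size=(4, 10)), View.view1, f"s{i}"),
                  LatentMatrix(rng.normal(size=(4, 10)), View.view2, f"s{i}"))
                 for i in range(6)]
        model = train_dcca(pairs, DCCAHyperparams(k_dcca=2, epochs=3, seed=1))
        assert model.post_cca_.k == 2

    def test_too_few_pairs_raises(self, rng):
        x = rng.normal(size=(2, 4, 10))
        with pytest.raises(ValidationError):
            DeepCCA(k_dcca=2, epochs=1).fit((x, x))

    def test_minibatch_rank_cap_enforced(self, rng):
        x = rng.normal(size=(20, 4, 10))
        with pytest.raises(ConfigurationError, match="batch_size"):
            DeepCCA(k_dcca=10, epochs=1, batch_size=10,
                    minibatch_loss=True).fit((x, x))

    def test_minibatch_mode_trains(self, rng):
        x = rng.normal(size=(20, 4, 10))
        model = DeepCCA(k_dcca=2, epochs=3, batch_size=10,
                        minibatch_loss=True, seed=0).fit((x, x.copy()))
        assert np.all(np.isfinite(model.training_curve_))


class TestProject:
    def test_training_projections_have_unit_regularized_variance(self, self_pair_model):
        x, model = self_pair_model
        v1 = model.transform_view(x, View.view1)
        reg_var = v1.var(axis=0, ddof=1) + model.post_cca_.reg * (
            model.post_cca_.projection_1 ** 2).sum(axis=0)
        np.testing.assert_allclose(reg_var, 1.0, atol=1e-3)

    def test_identity_post_cca_reduces_to_branch_forward(self, self_pair_model):
        x, model = self_pair_model
        k = model.k_dcca
        patched = DeepCCA(**model.get_params())
        patched.branch1_, patched.branch2_ = model.branch1_, model.branch2_
        patched.post_cca_ = CCAResult(
            projection_1=np.eye(k), projection_2=np.eye(k),
            mean_1=np.zeros(k), mean_2=np.zeros(k),
            correlations=np.ones(k), reg=0.0)
        m = LatentMatrix(x[3], View.view1, "s3")
        np.testing.assert_allclose(project(patched, m, View.view1),
                                   branch_forward(patched, m, View.view1),
                                   atol=1e-12)

    def test_view_tag_mismatch_raises(self, self_pair_model):
        x, model = self_pair_model
        m = LatentMatrix(x[0], View.view1, "s0")
        with pytest.raises(ValidationError, match="view"):
            project(model, m, View.view2)

    def test_heldout_cross_view_correlation_on_noiseless_cohort(self):
        """Shared-signal-only cohort: projections of unseen subjects stay aligned."""
        from cardicca import CohortConfig, generate_cohort
        from cardicca.evaluation import cohort_to_arrays
        cfg = CohortConfig(n_subjects=160, prevalence=0.5, d_shared=2,
                           q_discriminative=0, effect_size=0.0,
                           d_view1=6, d_view2=6,
                           noise_sd_view1=0.0, noise_sd_view2=0.0,
                           native_frames_view1=(12, 20),
                           native_frames_view2=(18, 30), seed=21)
        x1, x2, _, _ = cohort_to_arrays(generate_cohort(cfg))
        tr, te = np.arange(120), np.arange(120, 160)
        model = DeepCCA(k_dcca=5, learning_rate=0.01, epochs=60,
                        seed=2).fit((x1[tr], x2[tr]))
        v1 = model.transform_view(x1[te], View.view1)
        v2 = model.transform_view(x2[te], View.view2)
        for i in range(cfg.d_shared):
            assert np.corrcoef(v1[:, i], v2[:, i])[0, 1] >= 0.9


def test_hyperparams_grid_mode_validation():
    with pytest.raises(ConfigurationError):
        DCCAHyperparams(k_dcca=7, grid_mode=True)
    with pytest.raises(ConfigurationError):
        DCCAHyperparams(learning_rate=0.5, grid_mode=True)
    DCCAHyperparams(k_dcca=25, learning_rate=0.01, grid_mode=True)
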