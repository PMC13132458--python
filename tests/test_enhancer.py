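"""Contrastive enhancement: heads, similarity, InfoNCE and training."""

import numpy as np
import pytest

from ddacl import enhancer as enh
from ddacl.errors import ConfigurationError, InputError, TrainingError


class TestHeads:
    def test_projection_output_dim_and_determinism(self):
        head = enh.ProjectionHead(12, 5, seed=3)
        x = np.random.default_rng(0).normal(size=(4, 12))
        y1, y2 = head.forward(x), head.forward(x)
        assert y1.shape == (4, 5)
        assert np.array_equal(y1, y2)

    def test_zero_input_gives_documented_constant(self):
        # layer norm of an all-equal row is all zeros, so the output is beta
        head = enh.ProjectionHead(6, 4, seed=0)
        out = head.project(np.zeros(6))
        assert np.allclose(out, head.params["beta"])

    def test_dimension_mismatch_raises(self):
        head = enh.ProjectionHead(6, 4, seed=0)
        with pytest.raises(ConfigurationError):
            head.forward(np.ones((2, 7)))

    def test_interaction_depends_only_on_concatenation(self):
        head = enh.InteractionHead(proj_dim=3, seed=1)
        a, b = np.arange(3.0), np.arange(3.0, 6.0)
        direct = head.interact(a, b)
        batch = head.forward(a.reshape(1, -1), b.reshape(1, -1))[0]
        assert np.allclose(direct, batch)

    def test_interaction_asymmetric_under_swap(self):
        head = enh.InteractionHead(proj_dim=4, seed=2)
        a = np.random.default_rng(1).normal(size=4)
        b = np.random.default_rng(2).normal(size=4)
        assert not np.allclose(head.interact(a, b), head.interact(b, a))

    def test_zero_inputs_through_relu_affine_zero_bias(self):
        head = enh.InteractionHead(proj_dim=3, seed=0)
        assert np.allclose(head.interact(np.zeros(3), np.zeros(3)), 0.0)

    def test_backward_matches_numerical_gradient(self):
        head = enh.ProjectionHead(5, 4, seed=9)
        rng = np.random.default_rng(4)
        X = rng.normal(size=(3, 5))
        G = rng.normal(size=(3, 4))  # upstream gradient

        def loss(params):
            saved = {k: v.copy() for k, v in head.params.items()}
            head.params.update(params)
            out = float((head.forward(X) * G).sum())
            head.params.update(saved)
            return out

        head.forward(X, train=True)
        head.zero_grad()
        head.backward(G)
        eps = 1e-6
        for key in ("W1", "b2", "gamma"):
            p = head.params[key]
            flat_idx = np.unravel_index(1 % p.size, p.shape)
            bumped = {k: v.copy() for k, v in head.params.items()}
            bumped[key][flat_idx] += eps
            num = (loss(bumped) - loss({k: v.copy() for k, v in head.params.items()})) / eps
            assert head.grads[key][flat_idx] == pytest.approx(num, rel=1e-3, abs=1e-5)


class TestAssembly:
    def test_block_dims_sum_to_total(self):
        f = enh.assemble_enhanced(np.ones(384), np.ones(128), np.ones(128),
                                  np.ones(128), np.ones(128))
        assert f.block_dims == (384, 128, 128, 128, 128)
        assert f.values.shape == (896,)

    def test_split_round_trip(self):
        rng = np.random.default_rng(0)
        blocks = [rng.normal(size=d) for d in (6, 3, 2, 2, 2)]
        f = enh.assemble_enhanced(*blocks)
        for orig, back in zip(blocks, f.split()):
            assert np.array_equal(orig, back)

    def test_contrastive_free_ablation_has_two_blocks(self):
        f = enh.assemble_enhanced(np.ones(384), np.ones(128))
        assert f.block_dims == (384, 128)

    def test_partial_projected_triple_is_error(self):
        with pytest.raises(InputError, match="z_disease"):
            enh.assemble_enhanced(np.ones(4), np.ones(4), zd=np.ones(4))


class TestSimilarityAndLoss:
    def test_identity_rows_with_quarter_tau(self):
        Z = np.eye(2)
        S = enh.similarity_matrix(Z, Z, tau=0.25)
        assert np.allclose(S.values, [[4.0, 0.0], [0.0, 4.0]])

    def test_orthonormal_rows_tau_one(self):
        Z = np.eye(3)
        assert np.allclose(enh.similarity_matrix(Z, Z, 1.0).values, np.eye(3))

    def test_doubling_tau_halves_entries(self):
        rng = np.random.default_rng(0)
        Zd, Zi = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        s1 = enh.similarity_matrix(Zd, Zi, 0.5).values
        s2 = enh.similarity_matrix(Zd, Zi, 1.0).values
        assert np.allclose(s1, 2 * s2)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ConfigurationError):
            enh.similarity_matrix(np.eye(2), np.eye(2), 0.0)

    def test_singleton_batch_loss_is_zero(self):
        S = enh.SimMatrix(values=np.array([[3.7]]), tau=1.0)
        assert enh.infonce_loss(S).value == pytest.approx(0.0)

    def test_two_by_two_hand_value(self):
        S = enh.similarity_matrix(np.eye(2), np.eye(2), 1.0)
        loss = enh.infonce_loss(S)
        assert loss.value == pytest.approx(0.31326168751822286, abs=1e-12)

    def test_uniform_row_gives_log_b(self):
        B = 6
        S = enh.SimMatrix(values=np.zeros((B, B)), tau=1.0)
        assert enh.infonce_loss(S, [(0, 0)]).value == pytest.approx(np.log(B))

    def test_row_shift_invariance(self):
        rng = np.random.default_rng(3)
        V = rng.normal(size=(5, 5))
        base = enh.infonce_loss(enh.SimMatrix(V, 1.0)).value
        shifted = V + rng.normal(size=(5, 1)) * 10  # constant per row
        assert enh.infonce_loss(enh.SimMatrix(shifted, 1.0)).value == pytest.approx(base)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        V = rng.normal(size=(6, 6))
        perm = rng.permutation(6)
        base = enh.infonce_loss(enh.SimMatrix(V, 1.0)).value
        permuted = enh.infonce_loss(enh.SimMatrix(V[np.ix_(perm, perm)], 1.0)).value
        assert permuted == pytest.approx(base)


def _toy_aligned_problem(n=60, dim=10, seed=0):
    """Drug/disease vectors sharing a latent coordinate per positive pair."""
    rng = np.random.default_rng(seed)
    latents = rng.normal(size=(n, dim))
    drug = latents + 0.1 * rng.normal(size=(n, dim))
    dis = latents + 0.1 * rng.normal(size=(n, dim))
    pairs = [(k, k) for k in range(n)]
    return pairs, drug, dis


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        pairs, drug, dis = _toy_aligned_problem()
        cfg = enh.EnhancerConfig(proj_dim=16, batch_size=30, epochs=12, seed=0)
        trained = enh.train_enhancer(pairs, drug, dis, cfg)
        assert trained.loss_history[-1] < trained.loss_history[0]

    def test_fixed_seed_reproduces_history(self):
        pairs, drug, dis = _toy_aligned_problem()
        cfg = enh.EnhancerConfig(proj_dim=8, batch_size=20, epochs=5, seed=4)
        h1 = enh.train_enhancer(pairs, drug, dis, cfg).loss_history
        h2 = enh.train_enhancer(pairs, drug, dis, cfg).loss_history
        assert h1 == h2

    def test_no_positives_is_training_error(self):
        with pytest.raises(TrainingError):
            enh.train_enhancer([], np.ones((2, 3)), np.ones((2, 3)),
                               enh.EnhancerConfig(proj_dim=4))

    def test_enhanced_batch_width(self):
        pairs, drug, dis = _toy_aligned_problem(n=30)
        cfg = enh.EnhancerConfig(proj_dim=8, batch_size=15, epochs=2, seed=1)
        trained = enh.train_enhancer(pairs, drug, dis, cfg)
        X = trained.enhance_batch(drug[:5], dis[:5])
        assert X.shape == (5, 10 + 10 + 8 + 8 + 8)
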