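"""The VAE: loss primitives, encoder/decoder contracts, training behaviour."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from conftest import train
from pathvae.knowledge import PathwayGeneMatrix
from pathvae.model import (
    EncoderOutput,
    PathwayVAE,
    TrainConfig,
    kl_divergence,
    knowledge_penalty,
    reconstruction_loss,
    reparameterize,
    total_loss,
)


def small_adjacency(P=2, G=4):
    A = np.zeros((P, G))
    A[0, :2] = 1
    A[1, 2:] = 1
    return PathwayGeneMatrix(
        A, [f"PW{p}" for p in range(P)], [f"G{j}" for j in range(G)]
    )


class TestReparameterize:
    def test_zero_noise_returns_mean(self):
        out = EncoderOutput(np.ones((3, 2)), np.zeros((3, 2)))
        np.testing.assert_array_equal(
            reparameterize(out, np.zeros((3, 2))), out.mu
        )

    def test_clamped_minimum_variance_collapses_to_mean(self):
        out = EncoderOutput(np.full((2, 2), 3.0), np.full((2, 2), -10.0))
        z = reparameterize(out, np.full((2, 2), 5.0))
        np.testing.assert_allclose(z, out.mu, atol=1e-1)

    def test_sample_mean_converges_to_mu(self):
        rng = np.random.default_rng(0)
        out = EncoderOutput(np.array([[1.5, -2.0]]), np.array([[0.3, -0.7]]))
        draws = np.stack(
            [reparameterize(out, rng.standard_normal((1, 2))) for _ in range(10**5)]
        )
        sigma = np.exp(0.5 * out.log_var)
        err = 4 * sigma / np.sqrt(10**5)
        np.testing.assert_allclose(draws.mean(axis=0), out.mu, atol=err.max())


class TestKL:
    def test_standard_normal_posterior_has_zero_kl(self):
        out = EncoderOutput(np.zeros((5, 3)), np.zeros((5, 3)))
        assert kl_divergence(out) == 0.0

    def test_closed_form_value(self):
        out = EncoderOutput(np.array([[1.0]]), np.array([[0.0]]))
        assert kl_divergence(out) == pytest.approx(0.5)

    def test_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            out = EncoderOutput(
                rng.normal(size=(4, 3)), rng.uniform(-2, 2, size=(4, 3))
            )
            assert kl_divergence(out) >= 0.0

    def test_agrees_with_monte_carlo_estimate(self):
        """Closed form vs E_q[log q(z) - log p(z)] over 1e5 draws."""
        rng = np.random.default_rng(7)
        n_draws = 10**5
        for _ in range(20):
            mu = rng.normal(scale=1.5, size=(1, 3))
            log_var = rng.uniform(-2.0, 1.5, size=(1, 3))
            sigma = np.exp(0.5 * log_var)
            z = mu + sigma * rng.standard_normal((n_draws, 3))
            log_q = -0.5 * (
                ((z - mu) / sigma) ** 2 + log_var + np.log(2 * np.pi)
            ).sum(axis=1)
            log_p = -0.5 * (z**2 + np.log(2 * np.pi)).sum(axis=1)
            diffs = log_q - log_p
            mc = diffs.mean()
            se = diffs.std(ddof=1) / np.sqrt(n_draws)
            closed = kl_divergence(EncoderOutput(mu, log_var))
            assert abs(closed - mc) < 3 * se + 1e-9


class TestReconstruction:
    def test_perfect_reconstruction_is_zero(self):
        x = np.random.default_rng(0).normal(size=(3, 4))
        assert reconstruction_loss(x, x) == 0.0

    def test_hand_sum(self):
        assert reconstruction_loss(
            np.array([[0.0, 0.0]]), np.array([[1.0, 1.0]])
        ) == pytest.approx(2.0)

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(1)
        x, xp = rng.normal(size=(5, 6)), rng.normal(size=(5, 6))
        base = reconstruction_loss(x, xp)
        scaled = reconstruction_loss(x, x + 3.0 * (xp - x))
        assert scaled == pytest.approx(9.0 * base)


class TestKnowledgePenalty:
    def test_l2_distance_zero_iff_weights_equal_prior(self):
        A = small_adjacency()
        assert knowledge_penalty(A.matrix.copy(), A, "l2") == 0.0
        assert knowledge_penalty(A.matrix + 0.1, A, "l2") > 0.0

    def test_l1_counts_prior_mass_at_zero_weights(self):
        A = small_adjacency()  # 4 ones
        assert knowledge_penalty(np.zeros_like(A.matrix), A, "l1") == 4.0

    def test_literal_hadamard_l1_with_binary_weights(self):
        A = small_adjacency()
        w = np.ones_like(A.matrix)
        assert knowledge_penalty(w, A, "literal_hadamard_l1") == 4.0

    def test_mask_modes_contribute_nothing(self):
        A = small_adjacency()
        w = np.random.default_rng(0).normal(size=A.matrix.shape)
        for mode in ("mask_decoder", "mask_both", "none"):
            assert knowledge_penalty(w, A, mode) == 0.0

    def test_shape_mismatch_is_error(self):
        with pytest.raises(ValueError, match="shape"):
            knowledge_penalty(np.zeros((3, 3)), small_adjacency(), "l2")


class TestTotalLoss:
    def test_components_sum_to_total(self):
        rng = np.random.default_rng(2)
        A = small_adjacency()
        x, xp = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        out = EncoderOutput(rng.normal(size=(3, 2)), rng.normal(size=(3, 2)))
        w = rng.normal(size=(2, 4))
        cfg = TrainConfig(lambda_k=0.7, beta_kl=1.3)
        comps = total_loss(x, xp, out, w, A, cfg)
        assert comps["total"] == pytest.approx(
            comps["reconstruction"] + 1.3 * comps["kl"] + 0.7 * comps["knowledge"]
        )

    def test_zero_weights_reduce_to_reconstruction(self):
        rng = np.random.default_rng(2)
        A = small_adjacency()
        x, xp = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        out = EncoderOutput(rng.normal(size=(3, 2)), rng.normal(size=(3, 2)))
        cfg = TrainConfig(lambda_k=0.0, beta_kl=0.0)
        comps = total_loss(x, xp, out, rng.normal(size=(2, 4)), A, cfg)
        assert comps["total"] == comps["reconstruction"]


class TestEncodeDecode:
    def test_encode_shapes_and_determinism(self, model_l2, processed):
        batch = processed.obs["batch"].to_numpy()
        out1 = model_l2.encode(processed, batch)
        out2 = model_l2.encode(processed, batch)
        P = model_l2.n_pathways
        assert out1.mu.shape == (processed.n_obs, P)
        assert out1.log_var.shape == (processed.n_obs, P)
        np.testing.assert_array_equal(out1.mu, out2.mu)

    def test_gene_order_mismatch_is_error(self, model_l2, processed):
        permuted = processed[:, ::-1]
        with pytest.raises(ValueError, match="gene order"):
            model_l2.encode(permuted, processed.obs["batch"].to_numpy())

    def test_unseen_batch_category(self, model_l2, processed):
        labels = ["nonesuch"] * processed.n_obs
        with pytest.raises(ValueError, match="unseen batch"):
            model_l2.encode(processed, labels)
        out = model_l2.encode(processed, labels, allow_unseen_batch=True)
        assert np.isfinite(out.mu).all()

    def test_decode_hand_matrix_product(self):
        A = PathwayGeneMatrix(np.array([[1.0, 1.0]]), ["PW0"], ["G0", "G1"])
        model = PathwayVAE(A, TrainConfig(epochs=0))
        model.batch_categories = ["b0"]
        model._init_params(1, np.random.default_rng(0))
        model.params["Wd"] = np.array([[1.0, 2.0]])
        model.params["bg"][:] = 0.0
        xp = model.decode(np.array([[3.0]]), ["b0"])
        np.testing.assert_allclose(xp, [[3.0, 6.0]])

    def test_zero_latent_decodes_to_batch_offset(self):
        A = small_adjacency()
        model = PathwayVAE(A, TrainConfig(epochs=0))
        model.batch_categories = ["b0", "b1"]
        model._init_params(2, np.random.default_rng(0))
        model.params["bg"][:] = 0.0
        model.params["O"] = np.arange(8.0).reshape(2, 4)
        xp = model.decode(np.zeros((1, 2)), ["b1"])
        np.testing.assert_allclose(xp, [[4.0, 5.0, 6.0, 7.0]])

    def test_masked_gradient_is_structurally_zero(self, adjacency, processed):
        model = train(adjacency, processed, "mask_decoder", epochs=5)
        off = adjacency.matrix == 0
        assert np.all(model.decoder_weights[off] == 0.0)


class TestFit:
    def test_zero_epochs_returns_initialized_model(self, adjacency, processed):
        model = train(adjacency, processed, "l2", epochs=0)
        assert model.loss_history == []
        assert "Wd" in model.params

    def test_loss_history_finite_and_complete(self, model_l2):
        hist = model_l2.loss_history
        assert len(hist) == model_l2.config.epochs
        for row in hist:
            assert all(np.isfinite(v) for v in row.values())

    def test_training_reduces_total_loss(self, model_l2):
        assert (
            model_l2.loss_history[-1]["total"]
            < model_l2.loss_history[0]["total"]
        )

    def test_same_seed_reproduces_training(self, adjacency, processed):
        m1 = train(adjacency, processed, "l2", epochs=3)
        m2 = train(adjacency, processed, "l2", epochs=3)
        np.testing.assert_array_equal(m1.params["Wd"], m2.params["Wd"])

    def test_transform_columns_are_pathway_names(self, model_l2, processed):
        emb = model_l2.transform(processed)
        assert list(emb.columns) == model_l2.pathway_names
        assert emb.shape == (processed.n_obs, model_l2.n_pathways)

    def test_identical_cells_embed_identically(self, model_l2, processed):
        x = np.asarray(processed.X[:1])
        doubled = np.vstack([x, x])
        out = model_l2.encode(doubled, ["batch0", "batch0"])
        np.testing.assert_array_equal(out.mu[0], out.mu[1])

    def test_checkpoint_round_trip_is_bit_exact(self, model_l2, processed,
                                                tmp_path):
        path = tmp_path / "model.npz"
        model_l2.save(path)
        loaded = PathwayVAE.load(path)
        emb1 = model_l2.transform(processed)
        emb2 = loaded.transform(processed)
        np.testing.assert_array_equal(emb1.to_numpy(), emb2.to_numpy())


class TestScientificProperties:
    def test_prior_recovers_true_gene_pathway_structure(self, model_l2, a_true):
        """Ranking gene-pathway pairs by |w_D| recovers the generative
        adjacency."""
        auroc = roc_auc_score(
            a_true.ravel(), np.abs(model_l2.decoder_weights).ravel()
        )
        assert auroc > 0.8

    def test_prior_does_not_slow_convergence(self, model_l2, model_none):
        """Epochs until reconstruction loss stays within 5% of its final
        value: with the prior <= without."""
        def settle(hist):
            rec = np.array([h["reconstruction"] for h in hist])
            ok = np.abs(rec - rec[-1]) <= 0.05 * abs(rec[-1])
            for i in range(len(rec)):
                if ok[i:].all():
                    return i
            return len(rec) - 1

        assert settle(model_l2.loss_history) <= settle(model_none.loss_history)

    def test_embedding_mixes_batches_better_than_raw(
        self, embedding_l2, processed
    ):
        from pathvae.metrics import silhouette_per_cell

        raw = np.asarray(processed.X)
        batch = processed.obs["batch"].to_numpy()
        s_raw = silhouette_per_cell(raw, batch).mean()
        s_emb = silhouette_per_cell(embedding_l2.to_numpy(), batch).mean()
        assert s_raw > 0.1  # batches do separate before integration
        assert s_emb < s_raw
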