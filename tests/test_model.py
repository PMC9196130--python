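import numpy as np
import pytest

from danrlca import (
    CommunityAssignment,
    DANRLCA,
    TrainConfig,
    WalkConfig,
    toy_fixture,
    train,
)
from danrlca.model import (
    ae_gradients,
    autoencoder_loss,
    decode,
    encode,
    init_params,
    reg_loss,
    sg_gradients,
    sgns_loss,
    total_loss,
)
from danrlca.preprocess import build_reconstruction
from danrlca.model import _normalize_rows


@pytest.fixture
def six_node_setup():
    """Two triangles, CSM reconstruction, a d=2 tower, and a tiny pair batch."""
    G = toy_fixture("two_triangles")
    P = CommunityAssignment.from_labels([0, 0, 0, 1, 1, 1])
    recon, pen = build_reconstruction(G, P, variant="csm", chi=3.0)
    R = _normalize_rows(recon.R)
    params = init_params([6, 4, 2], n_nodes=6, seed=0)
    centers = np.array([0, 1, 2, 3, 4, 5, 0, 3])
    contexts = np.array([1, 2, 0, 4, 5, 3, 2, 5])
    rng = np.random.default_rng(0)
    negs = rng.integers(0, 6, size=(8, 3))
    return G, R, pen.B, params, centers, contexts, negs


class TestEncodeDecode:
    def test_zero_input_zero_biases_gives_zero(self):
        params = init_params([4, 3, 2], n_nodes=4, seed=0)
        np.testing.assert_array_equal(encode(np.zeros(4), params), np.zeros(2))

    def test_single_layer_identity_closed_form(self):
        params = init_params([2, 1], n_nodes=2, seed=0)
        params.enc_W[0] = np.array([[1.0], [0.0]])
        params.enc_b[0] = np.zeros(1)
        assert encode(np.array([0.5, -0.5]), params)[0] == pytest.approx(np.tanh(0.5))

    def test_outputs_bounded_by_tanh(self):
        params = init_params([5, 3], n_nodes=5, seed=1)
        y = encode(np.random.default_rng(0).normal(scale=5, size=(10, 5)), params)
        assert (np.abs(y) < 1).all()

    def test_decode_roundtrip_shapes(self):
        params = init_params([7, 4, 3], n_nodes=7, seed=2)
        x = np.random.default_rng(1).random(7)
        assert decode(encode(x, params), params).shape == x.shape

    def test_shape_mismatch_errors(self):
        params = init_params([4, 2], n_nodes=4, seed=0)
        with pytest.raises(ValueError):
            encode(np.zeros(5), params)
        with pytest.raises(ValueError):
            decode(np.zeros(3), params)

    def test_tower_must_decrease(self):
        with pytest.raises(ValueError, match="decrease"):
            init_params([4, 4, 2], n_nodes=4)


class TestLosses:
    def test_perfect_reconstruction_is_zero(self):
        R = np.random.default_rng(0).random((3, 3))
        assert autoencoder_loss(R, R, np.ones_like(R)) == 0.0

    def test_error_on_zero_entry_weighted_one(self):
        assert autoencoder_loss([[0, 1]], [[1, 1]], [[1, 2]]) == pytest.approx(1.0)

    def test_error_on_nonzero_entry_weighted_chi(self):
        assert autoencoder_loss([[1, 0]], [[0, 0]], [[2, 1]]) == pytest.approx(4.0)

    def test_chi_one_reduces_to_plain_squared_error(self):
        rng = np.random.default_rng(3)
        R, R_hat = rng.random((4, 4)), rng.random((4, 4))
        plain = ((R_hat - R) ** 2).sum()
        assert autoencoder_loss(R, R_hat, np.ones_like(R)) == pytest.approx(plain)

    def test_sgns_zero_parameters_is_log2_per_term(self):
        H = np.zeros((5, 2))
        y = np.zeros((1, 2))
        loss = sgns_loss(y, [0], [[1, 2, 3, 4, 0, 1, 2, 3, 4, 0]], H)
        assert loss == pytest.approx(11 * np.log(2))

    def test_sgns_saturated_scores_vanish(self):
        H = np.zeros((2, 1))
        H[0, 0] = 1e3
        H[1, 0] = -1e3
        loss = sgns_loss(np.ones((1, 1)), [0], [[1]], H)
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_sgns_unit_scores_closed_form(self):
        # score +1 for the positive, -1 for the single negative
        H = np.array([[1.0], [-1.0]])
        loss = sgns_loss(np.ones((1, 1)), [0], [[1]], H)
        assert loss == pytest.approx(2 * -np.log(1 / (1 + np.exp(-1))), rel=1e-6)
        assert loss == pytest.approx(0.6265, abs=1e-4)

    def test_reg_single_weight(self):
        params = init_params([2, 1], n_nodes=2, seed=0)
        for W in params.enc_W + params.dec_W:
            W[:] = 0.0
        params.enc_W[0][0, 0] = 2.0
        assert reg_loss(params) == pytest.approx(2.0)

    def test_reg_homogeneity_doubling_quadruples(self):
        params = init_params([3, 2], n_nodes=3, seed=4)
        before = reg_loss(params)
        for W in params.enc_W + params.dec_W:
            W *= 2.0
        assert reg_loss(params) == pytest.approx(4 * before)

    def test_total_loss_arithmetic(self):
        assert total_loss(1.0, 2.0, 3.0, 0.5, 0.1) == pytest.approx(2.3)
        assert total_loss(5.0, 2.0, 3.0, 0.0, 0.0) == 5.0
        assert total_loss(0.0, 0.0, 0.0, 1.0, 1.0) == 0.0


def numeric_grad(fun, arr, h=1e-6):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + h
        fp = fun()
        arr[idx] = orig - h
        fm = fun()
        arr[idx] = orig
        g[idx] = (fp - fm) / (2 * h)
    return g


def assert_grad_close(analytic, numeric, rel=1e-4):
    scale = max(np.abs(numeric).max(), 1e-8)
    assert np.abs(analytic - numeric).max() / scale < rel


class TestGradients:
    def test_autoencoder_gradients_match_finite_differences(self, six_node_setup):
        _, R, B, params, *_ = six_node_setup

        def loss():
            return autoencoder_loss(R, decode(encode(R, params), params), B)

        _, g = ae_gradients(params, R, B)
        for k in range(len(params.enc_W)):
            assert_grad_close(g["enc_W"][k], numeric_grad(loss, params.enc_W[k]))
            assert_grad_close(g["enc_b"][k], numeric_grad(loss, params.enc_b[k]))
        for k in range(len(params.dec_W)):
            assert_grad_close(g["dec_W"][k], numeric_grad(loss, params.dec_W[k]))
            assert_grad_close(g["dec_b"][k], numeric_grad(loss, params.dec_b[k]))

    def test_sgns_gradients_match_finite_differences(self, six_node_setup):
        _, R, _, params, centers, contexts, negs = six_node_setup

        def loss():
            return sgns_loss(encode(R[centers], params), contexts, negs, params.H)

        _, g = sg_gradients(params, R, centers, contexts, negs)
        for k in range(len(params.enc_W)):
            assert_grad_close(g["enc_W"][k], numeric_grad(loss, params.enc_W[k]))
            assert_grad_close(g["enc_b"][k], numeric_grad(loss, params.enc_b[k]))
        assert_grad_close(g["H"], numeric_grad(loss, params.H))

    def test_reg_gradient_is_the_weight_itself(self, six_node_setup):
        *_, params, _, _, _ = six_node_setup
        for W in params.enc_W + params.dec_W:
            assert_grad_close(W, numeric_grad(lambda: reg_loss(params), W))

    def test_sgns_full_batch_descent_is_monotone(self, six_node_setup):
        # plain gradient descent with a small step decreases the loss each step
        _, R, _, params, centers, contexts, negs = six_node_setup
        lr = 1e-3
        losses = []
        for _ in range(6):
            l, g = sg_gradients(params, R, centers, contexts, negs)
            losses.append(l)
            for k in range(len(params.enc_W)):
                params.enc_W[k] -= lr * g["enc_W"][k]
                params.enc_b[k] -= lr * g["enc_b"][k]
            params.H -= lr * g["H"]
        assert all(a > b for a, b in zip(losses, losses[1:]))


def tiny_config(**kw):
    defaults = dict(
        variant="csm",
        epochs=8,
        batch_size=4,
        sg_batch_size=64,
        learning_rate=5e-3,
        chi=3.0,
        walk=WalkConfig(walks_per_node=3, walk_length=8, window=2, num_negatives=3, seed=0),
    )
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestTraining:
    def test_loss_decreases_from_initialization(self, two_triangles):
        P = CommunityAssignment.from_labels([0, 0, 0, 1, 1, 1])
        emb, params, state = train(
            two_triangles, P, tiny_config(), layer_sizes=[6, 4, 2], return_state=True
        )
        assert state["history"][-1] < state["history"][0]
        assert emb.Y.shape == (6, 2)

    def test_same_seed_reproducible(self, two_triangles):
        P = CommunityAssignment.from_labels([0, 0, 0, 1, 1, 1])
        a = train(two_triangles, P, tiny_config(), layer_sizes=[6, 4, 2])
        b = train(two_triangles, P, tiny_config(), layer_sizes=[6, 4, 2])
        np.testing.assert_allclose(a.Y, b.Y, atol=1e-12)

    def test_automorphic_nodes_embed_close(self, two_triangles):
        # the two triangles are exchangeable; automorphic images should sit
        # closer than the average node pair
        P = CommunityAssignment.from_labels([0, 0, 0, 1, 1, 1])
        emb = train(
            two_triangles, P, tiny_config(epochs=30), layer_sizes=[6, 4, 2]
        )
        Y = emb.Y
        within = np.mean(
            [np.linalg.norm(Y[i] - Y[j]) for i in range(3) for j in range(i + 1, 3)]
        )
        all_pairs = np.mean(
            [np.linalg.norm(Y[i] - Y[j]) for i in range(6) for j in range(i + 1, 6)]
        )
        assert within < all_pairs

    def test_estimator_params_protocol(self):
        est = DANRLCA(dim=16, alpha=2.0)
        assert est.get_params()["alpha"] == 2.0
        est.set_params(alpha=3.0)
        assert est.alpha == 3.0

    def test_estimator_fit_sets_attributes(self, two_triangles):
        est = DANRLCA(
            variant="csm",
            dim=2,
            hidden_layers=(4,),
            epochs=3,
            community_method="lpa",
            walks_per_node=2,
            walk_length=5,
            window=2,
            num_negatives=2,
            sg_batch_size=32,
            seed=0,
        )
        est.fit(two_triangles)
        assert est.embedding_.shape == (6, 2)
        assert est.community_.l >= 1
        assert len(est.loss_history_) >= 1

    def test_dim_not_smaller_than_n_errors(self, two_triangles):
        with pytest.raises(ValueError, match="dim"):
            DANRLCA(dim=6).fit(two_triangles)

    def test_nonnegative_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(alpha=-1.0)
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
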