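"""The spatially regularized DGI model: encoder, losses, gradients, training."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from spatialflow import dgi
from spatialflow.dgi import (
    ModelState,
    TrainConfig,
    all_pairs,
    dgi_loss,
    discriminate,
    gcn_encode,
    normalize_adjacency,
    sample_pairs,
    spatial_regularization,
    summary,
    train,
)
from spatialflow.spatial_graph import SpatialExpressionGraph, build_graph
from spatialflow.preprocess import preprocess as run_preprocess


def make_state(g, nf, rng=None, zero=False):
    if zero:
        return ModelState(
            W1=np.zeros((g, nf)), W2=np.zeros((nf, nf)),
            prelu1_slope=0.25, prelu2_slope=0.25,
            Theta=np.zeros((nf, nf)), latent_dim=nf,
        )
    return ModelState.init(g, nf, rng or np.random.default_rng(0))


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------

class TestGcnEncode:
    def test_zero_weights_give_zero_embeddings(self, rng):
        X = rng.normal(size=(6, 4))
        A = sp.csr_matrix(np.ones((6, 6)) - np.eye(6))
        H = gcn_encode(X, A, make_state(4, 3, zero=True))
        np.testing.assert_array_equal(H, np.zeros((6, 3)))

    def test_isolated_node_reduces_to_mlp(self, rng):
        # one node, no edges: A^ = [1], so the GCN is a plain two-layer MLP
        state = make_state(3, 2, rng)
        x = rng.normal(size=(1, 3))
        H = gcn_encode(x, sp.csr_matrix((1, 1)), state)

        def prelu(z, a):
            return np.where(z > 0, z, a * z)

        expected = prelu(
            prelu(x @ state.W1, state.prelu1_slope) @ state.W2,
            state.prelu2_slope,
        )
        np.testing.assert_allclose(H, expected, rtol=1e-12)

    def test_two_node_path_hand_computation(self):
        # 2-node path: A+I degrees are 2, so A^ = [[.5,.5],[.5,.5]].
        # X = [1, -3]': A^X = [-1,-1]' -> PReLU(0.25) -> [-0.25,-0.25]'
        # A^ H1 = [-0.25,-0.25]' -> PReLU -> [-0.0625, -0.0625]'
        A = sp.csr_matrix(np.array([[0, 1], [1, 0]]))
        state = ModelState(
            W1=np.array([[1.0]]), W2=np.array([[1.0]]),
            prelu1_slope=0.25, prelu2_slope=0.25,
            Theta=np.array([[1.0]]), latent_dim=1,
        )
        H = gcn_encode(np.array([[1.0], [-3.0]]), A, state)
        np.testing.assert_allclose(H, [[-0.0625], [-0.0625]], rtol=1e-12)

    def test_propagation_matrix_symmetric_normalization(self):
        A = sp.csr_matrix(np.array([[0, 1], [1, 0]]))
        np.testing.assert_allclose(
            normalize_adjacency(A).toarray(), [[0.5, 0.5], [0.5, 0.5]]
        )


class TestSummaryAndDiscriminator:
    def test_summary_of_zeros_is_half(self):
        np.testing.assert_allclose(summary(np.zeros((5, 3))), 0.5)

    def test_summary_constant_rows(self):
        h = np.array([0.3, -1.2, 4.0])
        s = summary(np.tile(h, (7, 1)))
        np.testing.assert_allclose(s, 1 / (1 + np.exp(-h)), rtol=1e-12)

    def test_summary_random_recompute(self, rng):
        H = rng.normal(size=(11, 4))
        expected = 1 / (1 + np.exp(-H.mean(axis=0)))
        np.testing.assert_allclose(summary(H), expected, rtol=1e-10)

    def test_discriminator_zero_theta(self, rng):
        h, s = rng.normal(size=3), rng.normal(size=3)
        assert discriminate(h, s, np.zeros((3, 3))) == pytest.approx(0.5)

    def test_discriminator_orthogonal_identity(self):
        assert discriminate([1.0, 0.0], [0.0, 1.0], np.eye(2)) == pytest.approx(0.5)

    def test_discriminator_hand_value(self):
        # h . s = 1*0.5 + 2*0.25 = 1.0 -> sigmoid(1) = 0.731058...
        val = discriminate([1.0, 2.0], [0.5, 0.25], np.eye(2))
        assert val == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-6)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

class TestDgiLoss:
    def test_zero_theta_gives_log2_exactly(self, rng):
        H = rng.normal(size=(9, 4))
        Ht = rng.normal(size=(9, 4))
        loss = dgi_loss(H, Ht, summary(H), np.zeros((4, 4)))
        assert loss == pytest.approx(np.log(2.0), abs=1e-12)

    def test_perfect_discrimination_limit(self):
        H, Ht = np.array([[1.0]]), np.array([[-1.0]])
        loss = dgi_loss(H, Ht, np.array([1.0]), np.array([[50.0]]))
        assert 0.0 < loss < 1e-6

    def test_two_node_hand_computation(self, rng):
        H = np.array([[1.0, 0.0], [0.0, 1.0]])
        Ht = np.array([[0.5, 0.5], [-1.0, 0.2]])
        s = np.array([0.6, 0.4])
        Theta = np.array([[1.0, -0.5], [0.2, 2.0]])
        ts = Theta @ s
        sig = lambda x: 1 / (1 + np.exp(-x))
        expected = -(
            np.log(sig(H[0] @ ts)) + np.log(sig(H[1] @ ts))
            + np.log(1 - sig(Ht[0] @ ts)) + np.log(1 - sig(Ht[1] @ ts))
        ) / 4.0
        assert dgi_loss(H, Ht, s, Theta) == pytest.approx(expected, rel=1e-10)


class TestSpatialRegularization:
    def test_coincident_cells_zero(self, rng):
        coords = np.zeros((5, 2))
        H = rng.normal(size=(5, 3))
        assert spatial_regularization(coords, H, all_pairs(5)) == 0.0

    def test_two_cells_forced_zero(self, rng):
        coords = rng.normal(size=(2, 2))
        H = rng.normal(size=(2, 3))
        i = np.array([0, 1])
        j = np.array([1, 0])
        assert spatial_regularization(coords, H, (i, j)) == pytest.approx(0.0)

    def test_three_cell_brute_force(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        H = np.array([[0.0], [1.0], [1.0]])
        total = 0.0
        for a in range(3):
            for b in range(3):
                ds = abs(coords[a, 0] - coords[b, 0]) / 3.0  # max spatial = 3
                dz = abs(H[a, 0] - H[b, 0]) / 1.0  # max embedding = 1
                total += ds * (1.0 - dz)
        expected = total / 9.0
        got = spatial_regularization(coords, H, all_pairs(3))
        assert got == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 2 ** 16),
        n=st.integers(2, 20),
        dim=st.integers(1, 5),
    )
    def test_bounded_in_unit_interval(self, seed, n, dim):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(n, 2)) * rng.choice([0.0, 1.0, 100.0])
        H = rng.normal(size=(n, dim))
        val = spatial_regularization(coords, H, all_pairs(n))
        assert 0.0 <= val <= 1.0


class TestSamplePairs:
    def test_two_cells_support(self):
        i, j = sample_pairs(2, 40, np.random.default_rng(0))
        assert set(zip(i.tolist(), j.tolist())) <= {(0, 1), (1, 0)}
        assert np.all(i != j)

    def test_uniform_over_ordered_pairs(self):
        n, draws = 10, 100_000
        i, j = sample_pairs(n, draws, np.random.default_rng(42))
        counts = np.zeros((n, n))
        np.add.at(counts, (i, j), 1)
        assert counts.diagonal().sum() == 0
        p = 1.0 / (n * (n - 1))
        sigma = np.sqrt(draws * p * (1 - p))
        off = counts[~np.eye(n, dtype=bool)]
        assert np.all(np.abs(off - draws * p) < 5 * sigma)

    def test_rng_state_determinism(self):
        a = sample_pairs(8, 100, np.random.default_rng(9))
        b = sample_pairs(8, 100, np.random.default_rng(9))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

class TestGradients:
    """Analytic backward pass vs central finite differences."""

    def setup_case(self, seed=0, n=7, g=4, nf=3):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, g))
        Xp = X[rng.permutation(n)]
        coords = rng.normal(size=(n, 2))
        A = sp.random(n, n, density=0.5, random_state=np.random.RandomState(1))
        A = sp.csr_matrix(((A + A.T) > 0).astype(np.int8))
        A.setdiag(0)
        A.eliminate_zeros()
        state = ModelState.init(g, nf, rng)
        return X, Xp, coords, normalize_adjacency(A), state

    @pytest.mark.parametrize("pair_mode", ["all", "sampled"])
    def test_finite_differences(self, pair_mode):
        X, Xp, coords, A_hat, state = self.setup_case()
        gamma = 0.3
        if pair_mode == "all":
            pairs, coords_d = None, cdist(coords, coords)
        else:
            pairs = sample_pairs(7, 30, np.random.default_rng(3))
            coords_d = np.linalg.norm(coords[pairs[0]] - coords[pairs[1]], axis=1)

        def total(st):
            ld, lr, _ = dgi._losses_and_grads(X, Xp, A_hat, st, gamma,
                                              coords_d, pairs)
            return ld + gamma * lr

        _, _, grads = dgi._losses_and_grads(X, Xp, A_hat, state, gamma,
                                            coords_d, pairs)
        eps = 1e-6
        for name in ("W1", "W2", "Theta", "prelu1_slope", "prelu2_slope"):
            p = getattr(state, name)
            if np.isscalar(p):
                s_hi, s_lo = state.copy(), state.copy()
                setattr(s_hi, name, p + eps)
                setattr(s_lo, name, p - eps)
                num = (total(s_hi) - total(s_lo)) / (2 * eps)
                assert grads[name] == pytest.approx(num, rel=1e-5, abs=1e-9)
            else:
                flat_idx = [(0, 0), (p.shape[0] - 1, p.shape[1] - 1), (0, p.shape[1] - 1)]
                for idx in flat_idx:
                    s_hi, s_lo = state.copy(), state.copy()
                    q = s_hi.__dict__[name].copy()
                    q[idx] += eps
                    setattr(s_hi, name, q)
                    q = s_lo.__dict__[name].copy()
                    q[idx] -= eps
                    setattr(s_lo, name, q)
                    num = (total(s_hi) - total(s_lo)) / (2 * eps)
                    assert grads[name][idx] == pytest.approx(num, rel=1e-4, abs=1e-9)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def make_seg(tissue, max_cells=None):
    fm, filt = run_preprocess(tissue.dataset, min_genes_per_cell=10)
    return build_graph(fm, filt.coords)


class TestTrain:
    def test_gamma_zero_skips_regularizer(self, small_tissue):
        seg = make_seg(small_tissue)
        cfg = TrainConfig(gamma=0.0, max_epochs=20, min_epochs=5, patience=3,
                          latent_dim=8, seed=0)
        res = train(seg, cfg)
        assert res.loss_log["reg_loss"].isna().all()
        np.testing.assert_allclose(
            res.loss_log["total_loss"], res.loss_log["dgi_loss"]
        )

    def test_seed_reproducibility_bitwise(self, small_tissue):
        seg = make_seg(small_tissue)
        cfg = TrainConfig(gamma=0.1, max_epochs=15, min_epochs=5, patience=3,
                          latent_dim=8, seed=11)
        H1 = train(seg, cfg).embeddings.H
        H2 = train(seg, cfg).embeddings.H
        assert np.array_equal(H1, H2)

    def test_training_reduces_losses(self):
        from spatialflow.synthetic import simulate_layered_tissue

        tissue = simulate_layered_tissue(n_layers=3, cells_per_layer=167,
                                         seed=2)
        seg = make_seg(tissue)
        cfg = TrainConfig(gamma=0.1, max_epochs=150, min_epochs=50,
                          patience=50, seed=2)
        res = train(seg, cfg)
        log = res.loss_log
        assert log["total_loss"].iloc[-1] < log["total_loss"].iloc[0]

        # post hoc, gamma=0-trained embeddings should carry a HIGHER spatial
        # penalty than the regularized ones
        cfg0 = TrainConfig(gamma=0.0, max_epochs=150, min_epochs=50,
                           patience=50, seed=2)
        res0 = train(seg, cfg0)
        pairs = all_pairs(seg.n_nodes)
        reg_regularized = spatial_regularization(seg.coords, res.embeddings.H,
                                                 pairs)
        reg_plain = spatial_regularization(seg.coords, res0.embeddings.H, pairs)
        assert reg_regularized < reg_plain

    def test_summary_vector_in_unit_interval(self, small_tissue):
        seg = make_seg(small_tissue)
        cfg = TrainConfig(gamma=0.1, max_epochs=10, min_epochs=5, patience=3,
                          latent_dim=8, seed=0)
        s = train(seg, cfg).embeddings.s
        assert np.all((s > 0) & (s < 1))
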