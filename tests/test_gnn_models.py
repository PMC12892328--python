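"""Layer equations against literal dense oracles; forward-pass contracts."""

import numpy as np
import pytest

from pkagraph.gnn_models import (
    LEAKY_SLOPE,
    ModelConfig,
    gat_attention,
    gat_layer,
    gcn_layer,
    gin_layer,
    global_pool,
    init_parameters,
    model_forward,
)
from pkagraph.graph_builder import N_FEATURES, ResidueGraph
from pkagraph.structure_io import ResidueKey


# ---------------------------------------------------------------------------
# Literal (loop-based) evaluations of the three update equations
# ---------------------------------------------------------------------------

def gcn_oracle(H, A, W):
    n = H.shape[0]
    deg = A.sum(axis=1)  # closed neighborhood (unit diagonal)
    out = np.zeros((n, W.shape[1]))
    for i in range(n):
        for j in range(n):
            if A[i, j]:
                out[i] += (W.T @ H[j]) / np.sqrt(deg[i] * deg[j])
    return np.maximum(out, 0.0)


def gin_oracle(H, A, eps, mlp):
    n = H.shape[0]
    agg = np.zeros_like(H)
    for i in range(n):
        agg[i] = (1 + eps) * H[i]
        for j in range(n):
            if j != i and A[i, j]:
                agg[i] += H[j]
    return mlp(agg)


def leaky(x):
    return np.where(x > 0, x, LEAKY_SLOPE * x)


def gat_attention_oracle(H, A, Ws, Wt, a):
    n = H.shape[0]
    alpha = np.zeros((n, n))
    for i in range(n):
        scores = {}
        for j in range(n):
            if A[i, j]:
                scores[j] = float(a @ leaky(Ws.T @ H[i] + Wt.T @ H[j]))
        m = max(scores.values())
        z = {j: np.exp(s - m) for j, s in scores.items()}
        total = sum(z.values())
        for j, v in z.items():
            alpha[i, j] = v / total
    return alpha


def gat_layer_oracle(H, A, head_params):
    outs = []
    for Ws, Wt, a in head_params:
        alpha = gat_attention_oracle(H, A, Ws, Wt, a)
        n = H.shape[0]
        out = np.zeros((n, Ws.shape[1]))
        for i in range(n):
            out[i] = alpha[i, i] * (Ws.T @ H[i])
            for j in range(n):
                if j != i and A[i, j]:
                    out[i] += alpha[i, j] * (Wt.T @ H[j])
        outs.append(out)
    return np.concatenate(outs, axis=1)


def random_graph(rng, max_nodes=6, d=4):
    n = int(rng.integers(1, max_nodes + 1))
    A = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                A[i, j] = A[j, i] = 1
    H = rng.normal(size=(n, d))
    return H, A


class TestEquationOracles:
    def test_gcn_matches_dense_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            H, A = random_graph(rng)
            W = rng.normal(size=(4, 3))
            np.testing.assert_allclose(
                gcn_layer(H, A, W), gcn_oracle(H, A, W), atol=1e-6
            )

    def test_gin_matches_dense_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            H, A = random_graph(rng)
            eps = float(rng.normal())
            W1, b1 = rng.normal(size=(4, 5)), rng.normal(size=5)
            W2, b2 = rng.normal(size=(5, 2)), rng.normal(size=2)

            def mlp(x):
                return np.maximum(x @ W1 + b1, 0) @ W2 + b2

            np.testing.assert_allclose(
                gin_layer(H, A, eps, mlp), gin_oracle(H, A, eps, mlp),
                atol=1e-6,
            )

    def test_gat_attention_matches_dense_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            H, A = random_graph(rng)
            Ws, Wt = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
            a = rng.normal(size=3)
            alpha = gat_attention(H, A, Ws, Wt, a)
            np.testing.assert_allclose(
                alpha, gat_attention_oracle(H, A, Ws, Wt, a), atol=1e-7
            )
            # rows sum to 1 over the closed neighborhood; zeros elsewhere
            np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(alpha[A == 0] == 0)

    def test_gat_layer_matches_dense_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            H, A = random_graph(rng)
            heads = [
                (rng.normal(size=(4, 2)), rng.normal(size=(4, 2)),
                 rng.normal(size=2))
                for _ in range(int(rng.integers(1, 4)))
            ]
            np.testing.assert_allclose(
                gat_layer(H, A, heads), gat_layer_oracle(H, A, heads),
                atol=1e-6,
            )


class TestLayerSpecialCases:
    def test_gcn_single_node_identity(self):
        H = np.array([[0.5, 2.0]])
        out = gcn_layer(H, np.eye(1), np.eye(2))
        np.testing.assert_allclose(out, H)

    def test_gcn_zero_features_zero_output(self):
        A = np.ones((3, 3))
        out = gcn_layer(np.zeros((3, 4)), A, np.random.default_rng(0).normal(size=(4, 2)))
        np.testing.assert_array_equal(out, 0.0)

    def test_gcn_shape_mismatch(self):
        with pytest.raises(ValueError):
            gcn_layer(np.zeros((2, 3)), np.eye(2), np.zeros((4, 1)))

    def test_gin_isolated_node_identity_mlp(self):
        H = np.array([[1.0, -2.0]])
        out = gin_layer(H, np.eye(1), 0.0, lambda x: x)
        np.testing.assert_allclose(out, H)

    def test_gin_two_node_edge_sums(self):
        H = np.array([[1.0, 0.0], [0.0, 2.0]])
        A = np.ones((2, 2))
        out = gin_layer(H, A, 0.0, lambda x: x)
        np.testing.assert_allclose(out, [[1.0, 2.0], [1.0, 2.0]])

    def test_gat_single_node_self_attention(self):
        H = np.array([[1.0, 2.0]])
        alpha = gat_attention(H, np.eye(1), np.ones((2, 2)),
                              np.ones((2, 2)), np.ones(2))
        np.testing.assert_allclose(alpha, [[1.0]])

    def test_gat_identical_features_uniform(self):
        H = np.ones((2, 2))
        A = np.ones((2, 2))
        W = np.ones((2, 3))
        alpha = gat_attention(H, A, W, W, np.ones(3))
        np.testing.assert_allclose(alpha, 0.5)

    @pytest.mark.parametrize("heads", [4, 6, 8])
    def test_gat_output_width(self, heads):
        rng = np.random.default_rng(heads)
        H, A = np.ones((3, 4)), np.eye(3)
        params = [
            (rng.normal(size=(4, 5)), rng.normal(size=(4, 5)),
             rng.normal(size=5))
            for _ in range(heads)
        ]
        assert gat_layer(H, A, params).shape == (3, heads * 5)

    def test_pool_identities(self):
        rng = np.random.default_rng(7)
        H = rng.normal(size=(5, 3))
        np.testing.assert_allclose(global_pool(H, "mean"), H.mean(axis=0))
        np.testing.assert_allclose(
            global_pool(H, "add"), 5 * global_pool(H, "mean"), atol=1e-12
        )
        v = np.array([1.0, -2.0, 3.0])
        np.testing.assert_allclose(
            global_pool(np.tile(v, (4, 1)), "mean"), v
        )


def _random_residue_graph(rng, n=8):
    A = np.eye(n)
    for i in range(n - 1):
        A[i, i + 1] = A[i + 1, i] = 1
    X = rng.normal(size=(n, N_FEATURES))
    return ResidueGraph(
        key=ResidueKey("A", 1, "ASP"), node_features=X, adjacency=A,
        label=4.0, radius=9.0,
    )


class TestModelForward:
    @pytest.mark.parametrize("arch", ["GCN", "GIN", "GAT"])
    def test_zero_parameters_zero_prediction(self, arch):
        rng = np.random.default_rng(0)
        g = _random_residue_graph(rng)
        cfg = ModelConfig(architecture=arch, hidden_channels=4, n_heads=2)
        params = {k: np.zeros_like(v)
                  for k, v in init_parameters(cfg).items()}
        assert model_forward(g, cfg, params) == 0.0

    @pytest.mark.parametrize("arch", ["GCN", "GIN", "GAT"])
    def test_eval_deterministic(self, arch):
        rng = np.random.default_rng(1)
        g = _random_residue_graph(rng)
        cfg = ModelConfig(architecture=arch, hidden_channels=4, n_heads=2,
                          dropout_rate=0.4)
        params = init_parameters(cfg)
        assert model_forward(g, cfg, params) == model_forward(g, cfg, params)

    @pytest.mark.parametrize("arch", ["GCN", "GIN", "GAT"])
    def test_permutation_invariance(self, arch):
        rng = np.random.default_rng(2)
        g = _random_residue_graph(rng)
        cfg = ModelConfig(architecture=arch, hidden_channels=4, n_heads=2)
        params = init_parameters(cfg)
        base = model_forward(g, cfg, params)
        for _ in range(5):
            perm = rng.permutation(g.n_nodes)
            gp = ResidueGraph(
                key=g.key,
                node_features=g.node_features[perm],
                adjacency=g.adjacency[np.ix_(perm, perm)],
                label=g.label, radius=g.radius,
            )
            assert model_forward(gp, cfg, params) == pytest.approx(
                base, abs=1e-8
            )

    def test_feature_width_enforced(self):
        rng = np.random.default_rng(3)
        g = _random_residue_graph(rng)
        cfg = ModelConfig(architecture="GCN")
        params = init_parameters(cfg)
        bad = np.hstack([g.node_features, np.zeros((g.n_nodes, 1))])
        from pkagraph._autodiff import as_var
        from pkagraph.gnn_models import forward_var

        with pytest.raises(ValueError):
            forward_var(as_var(bad), as_var(g.adjacency), cfg,
                        {k: as_var(v) for k, v in params.items()})

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(hidden_channels=0)
        with pytest.raises(ValueError):
            ModelConfig(dropout_rate=1.0)
        with pytest.raises(ValueError):
            ModelConfig(architecture="MPNN")
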