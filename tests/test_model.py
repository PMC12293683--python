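"""Forward-pass semantics: layers, pooling, fusion, heads, whole networks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import brainsage as bs
from brainsage.autodiff import constant, parameter
from brainsage.graph import build_graph
from brainsage.model import (
    ModelConfig,
    aux_head_forward,
    build_baseline,
    fuse,
    gcn_matrix,
    init_params,
    mean_agg_matrix,
    model_forward,
    roi_aware_pool,
    sage_layer_forward,
)


def _graph(a):
    return build_graph(np.asarray(a, dtype=float), edge_eps=1e-12)


def _single_node_graph():
    return _graph(np.zeros((1, 1)))


class TestSageLayer:
    def test_isolated_node_identity(self):
        g = _single_node_graph()
        out = sage_layer_forward(np.array([[1.0, 2.0]]), g, np.eye(2), leaky_slope=1.0)
        np.testing.assert_allclose(out.data, [[1.0, 2.0]])

    def test_two_connected_nodes_smooth_in_one_step(self):
        g = _graph([[0.0, 1.0], [1.0, 0.0]])
        x = np.array([[2.0, 0.0], [0.0, 2.0]])
        out = sage_layer_forward(x, g, np.eye(2), leaky_slope=0.01)
        np.testing.assert_allclose(out.data, [[1.0, 1.0], [1.0, 1.0]])

    def test_leaky_branch_on_negative_value(self):
        g = _single_node_graph()
        out = sage_layer_forward(np.array([[-1.0]]), g, np.array([[1.0]]), 0.01)
        np.testing.assert_allclose(out.data, [[-0.01]])

    def test_concat_self_variant_shapes(self):
        g = _graph([[0.0, 1.0], [1.0, 0.0]])
        w = np.random.default_rng(0).standard_normal((4, 3))
        out = sage_layer_forward(np.ones((2, 2)), g, w, sage_self="concat")
        assert out.shape == (2, 3)

    def test_dimension_mismatch_raises(self):
        g = _graph([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            sage_layer_forward(np.ones((2, 2)), g, np.ones((3, 3)))


class TestROIAwarePool:
    def test_uniform_logits_give_column_mean(self):
        x = np.array([[1.0, 3.0], [3.0, 5.0]])
        out = roi_aware_pool(x, np.zeros((2, 1)))
        np.testing.assert_allclose(out.data, [2.0, 4.0])

    def test_saturated_softmax_selects_node(self):
        x = np.array([[1.0, 3.0], [7.0, 9.0]])
        out = roi_aware_pool(x, np.array([[50.0], [-50.0]]))
        np.testing.assert_allclose(out.data, x[0], atol=1e-10)

    def test_matches_independent_softmax_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((3, 4))
        logits = rng.standard_normal((3, 2))
        out = roi_aware_pool(x, logits).data
        e = np.exp(logits - logits.max(axis=0))
        att = e / e.sum(axis=0)
        expected = np.concatenate([att[:, h] @ x for h in range(2)])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_attention_distributions_normalized(self, seed):
        rng = np.random.default_rng(seed)
        logits = rng.standard_normal((7, 3)) * rng.uniform(0.1, 30)
        att = constant(logits).softmax(axis=0).data
        np.testing.assert_allclose(att.sum(axis=0), np.ones(3), atol=1e-6)

    def test_zero_heads_rejected(self):
        with pytest.raises(ValueError):
            roi_aware_pool(np.ones((2, 2)), np.zeros((2, 0)))


class TestFusion:
    def test_concat(self):
        out = fuse([constant([1.0, 2.0]), constant([3.0, 4.0])], "concatenation")
        np.testing.assert_array_equal(out.data, [1.0, 2.0, 3.0, 4.0])

    def test_mean(self):
        out = fuse([constant([1.0, 2.0]), constant([3.0, 4.0])], "mean")
        np.testing.assert_allclose(out.data, [2.0, 3.0])

    def test_weighted_sum_uniform_logits(self):
        params = {"fusion.logits": parameter(np.zeros(2))}
        out = fuse([constant([1.0, 2.0]), constant([3.0, 4.0])], "weighted_sum", params)
        np.testing.assert_allclose(out.data, [2.0, 3.0])

    def test_max_and_sum(self):
        zs = [constant([1.0, 5.0]), constant([3.0, 4.0])]
        np.testing.assert_allclose(fuse(zs, "max").data, [3.0, 5.0])
        np.testing.assert_allclose(fuse(zs, "sum").data, [4.0, 9.0])

    @pytest.mark.parametrize("method", ["mean", "max", "sum", "weighted_sum", "attention", "concatenation"])
    def test_single_layer_fusion_is_identity(self, method):
        """With r=1 every fusion method must return Z(1) unchanged."""
        rng = np.random.default_rng(4)
        z = rng.standard_normal((5, 6))
        params = {
            "fusion.logits": parameter(np.zeros(1)),
            "fusion.v": parameter(rng.standard_normal((6, 1))),
            "fusion.c": parameter(np.zeros(1)),
        }
        out = fuse([constant(z)], method, params)
        np.testing.assert_allclose(out.data, z, atol=1e-12)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            fuse([constant([1.0])], "median")


class TestHeads:
    def test_zero_weights_give_zero(self):
        params = {
            "aux0.W1": parameter(np.zeros((3, 4))),
            "aux0.b1": parameter(np.zeros(4)),
            "aux0.W2": parameter(np.zeros((4, 1))),
            "aux0.b2": parameter(np.zeros(1)),
        }
        out = aux_head_forward(np.array([[1.0, 2.0, 3.0]]), params, "aux0")
        np.testing.assert_array_equal(out.data, [0.0])

    def test_constructed_weights_sum_inputs(self):
        params = {
            "aux0.W1": parameter(np.eye(3)),
            "aux0.b1": parameter(np.zeros(3)),
            "aux0.W2": parameter(np.ones((3, 1))),
            "aux0.b2": parameter(np.zeros(1)),
        }
        out = aux_head_forward(np.array([[1.0, 2.0, 3.0]]), params, "aux0", slope=1.0)
        np.testing.assert_allclose(out.data, [6.0])

    def test_matches_matrix_arithmetic_oracle(self):
        rng = np.random.default_rng(5)
        w1, b1 = rng.standard_normal((4, 6)), rng.standard_normal(6)
        w2, b2 = rng.standard_normal((6, 1)), rng.standard_normal(1)
        z = rng.standard_normal((3, 4))
        params = {
            "h.W1": parameter(w1), "h.b1": parameter(b1),
            "h.W2": parameter(w2), "h.b2": parameter(b2),
        }
        got = aux_head_forward(z, params, "h", slope=0.01).data
        pre = z @ w1 + b1
        hidden = np.where(pre > 0, pre, 0.01 * pre)
        np.testing.assert_allclose(got, (hidden @ w2 + b2).ravel(), atol=1e-12)


def _fusion_setup(n=6, r=3, seed=0, fusion="concatenation", sage_self="concat"):
    rng = np.random.default_rng(seed)
    a = (rng.random((n, n)) < 0.4).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    g = _graph(a)
    cfg = ModelConfig(n_nodes=n, n_layers=r, hidden_dim=5, n_heads=2,
                      fusion_method=fusion, sage_self=sage_self)
    params = init_params(cfg, seed=seed)
    feats = rng.standard_normal((4, n, 2))
    return g, cfg, params, feats


class TestModelForward:
    @pytest.mark.parametrize("sage_self", ["include", "concat"])
    def test_literal_pipeline_equivalence(self, sage_self):
        """Independent plain-NumPy re-implementation of the layer loop:
        aggregate -> linear -> LeakyReLU -> pool -> aux head, concat fusion,
        final regressor."""
        g, cfg, params, feats = _fusion_setup(sage_self=sage_self)
        pred = model_forward(feats, g, params, cfg)

        p = {k: v.data for k, v in params.items()}
        adj = g.adjacency()
        if sage_self == "include":
            m = adj + np.eye(cfg.n_nodes)
        else:
            m = adj.copy()
        deg = m.sum(axis=1, keepdims=True)
        deg[deg == 0] = 1.0
        m = m / deg

        def leaky(x, s=0.01):
            return np.where(x > 0, x, s * x)

        def mlp(z, pre):
            h = leaky(z @ p[f"{pre}.W1"] + p[f"{pre}.b1"])
            return (h @ p[f"{pre}.W2"] + p[f"{pre}.b2"]).ravel()

        x = feats
        pooled, aux = [], []
        for l in range(cfg.n_layers):
            agg = np.einsum("nm,bmf->bnf", m, x)
            if sage_self == "concat":
                agg = np.concatenate([x, agg], axis=-1)
            x = leaky(agg @ p[f"layer{l}.W"])
            logits = p[f"pool{l}.logits"]
            e = np.exp(logits - logits.max(axis=0))
            att = e / e.sum(axis=0)
            z = np.einsum("nh,bnf->bhf", att, x).reshape(len(x), -1)
            pooled.append(z)
            aux.append(mlp(z, f"aux{l}"))
        y = mlp(np.concatenate(pooled, axis=1), "regressor")

        np.testing.assert_allclose(pred.y_hat.data, y, atol=1e-9)
        for got, want in zip(pred.y_aux, aux):
            np.testing.assert_allclose(got.data, want, atol=1e-9)

    def test_inference_ignores_dropout_rate(self):
        g, cfg, params, feats = _fusion_setup(seed=1)
        lo = model_forward(feats, g, params, cfg, training=False)
        cfg_hi = ModelConfig(**{**cfg.__dict__, "dropout": 0.9})
        hi = model_forward(feats, g, params, cfg_hi, training=False)
        np.testing.assert_array_equal(lo.y_hat.data, hi.y_hat.data)

    def test_subject_permutation_equivariance(self):
        g, cfg, params, feats = _fusion_setup(seed=2)
        perm = np.random.default_rng(0).permutation(len(feats))
        base = model_forward(feats, g, params, cfg).y_hat.data
        permuted = model_forward(feats[perm], g, params, cfg).y_hat.data
        np.testing.assert_allclose(permuted, base[perm], atol=1e-12)

    def test_roi_permutation_covariance(self):
        """Relabelling ROIs (features, edges and pooling logits together)
        leaves predictions unchanged."""
        g, cfg, params, feats = _fusion_setup(seed=3)
        n = cfg.n_nodes
        perm = np.random.default_rng(1).permutation(n)
        a = g.adjacency()[np.ix_(perm, perm)]
        g2 = _graph(a)
        params2 = {}
        for k, v in params.items():
            if k.startswith("pool"):
                params2[k] = parameter(v.data[perm])
            else:
                params2[k] = parameter(v.data.copy())
        base = model_forward(feats, g, params, cfg).y_hat.data
        moved = model_forward(feats[:, perm, :], g2, params2, cfg).y_hat.data
        np.testing.assert_allclose(moved, base, atol=1e-9)

    def test_inference_deterministic(self):
        g, cfg, params, feats = _fusion_setup(seed=4)
        a = model_forward(feats, g, params, cfg).y_hat.data
        b = model_forward(feats, g, params, cfg).y_hat.data
        np.testing.assert_array_equal(a, b)

    def test_prediction_contract(self):
        g, cfg, params, feats = _fusion_setup(seed=5)
        pred = model_forward(feats, g, params, cfg)
        assert len(pred.y_aux) == cfg.n_layers
        assert len(pred.layer_embeddings) == cfg.n_layers
        assert all(np.all(np.isfinite(a.data)) for a in pred.y_aux)

    def test_two_node_hand_pipeline_r1(self):
        """r=1, uniform pooling, summing heads: computable by hand."""
        g = _graph([[0.0, 1.0], [1.0, 0.0]])
        cfg = ModelConfig(n_nodes=2, n_layers=1, hidden_dim=2, n_heads=1,
                          in_features=2, leaky_slope=1.0, sage_self="include")
        params = init_params(cfg, seed=0)
        params["layer0.W"] = parameter(np.eye(2))
        params["pool0.logits"] = parameter(np.zeros((2, 1)))
        for pre in ("aux0", "regressor"):
            params[f"{pre}.W1"] = parameter(np.eye(2))
            params[f"{pre}.b1"] = parameter(np.zeros(2))
            params[f"{pre}.W2"] = parameter(np.ones((2, 1)))
            params[f"{pre}.b2"] = parameter(np.zeros(1))
        x = np.array([[[2.0, 0.0], [0.0, 2.0]]])
        pred = model_forward(x, g, params, cfg)
        # both nodes smooth to [1,1]; uniform pool keeps [1,1]; heads sum -> 2
        np.testing.assert_allclose(pred.y_hat.data, [2.0])
        np.testing.assert_allclose(pred.y_aux[0].data, [2.0])


class TestBaselines:
    @pytest.mark.parametrize("variant", ["FCNN", "GCN", "GraphSAGE", "GAT", "GIN"])
    def test_all_variants_emit_finite_scalars(self, variant):
        g, cfg, _, feats = _fusion_setup(seed=6)
        bcfg = build_baseline(variant, cfg)
        params = init_params(bcfg, seed=0)
        pred = model_forward(feats, g, params, bcfg)
        assert pred.y_hat.data.shape == (len(feats),)
        assert np.all(np.isfinite(pred.y_hat.data))

    def test_unknown_variant_rejected(self):
        cfg = ModelConfig(n_nodes=4)
        with pytest.raises(ValueError):
            build_baseline("Transformer", cfg)

    def test_gcn_operator_preserves_constants_on_ring(self, ring_graph):
        """On a 2-regular ring the symmetric-normalised operator is doubly
        stochastic, so constant features are fixed points."""
        op = gcn_matrix(ring_graph)
        c = np.full((6, 3), 2.5)
        np.testing.assert_allclose(op @ c, c, atol=1e-12)
        np.testing.assert_allclose(op.sum(axis=1), np.ones(6), atol=1e-12)

    def test_fcnn_constructed_weights(self):
        g = _graph(np.zeros((2, 2)))
        cfg = ModelConfig(n_nodes=2, n_layers=1, hidden_dim=4, in_features=2,
                          arch="fcnn", leaky_slope=1.0)
        params = init_params(cfg, seed=0)
        params["fc0.W"] = parameter(np.ones((4, 4)))
        params["fc0.b"] = parameter(np.zeros(4))
        params["regressor.W1"] = parameter(np.eye(4))
        params["regressor.b1"] = parameter(np.zeros(4))
        params["regressor.W2"] = parameter(np.ones((4, 1)) / 4.0)
        params["regressor.b2"] = parameter(np.zeros(1))
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])  # flattens to [1,2,3,4]
        pred = model_forward(x, g, params, cfg)
        np.testing.assert_allclose(pred.y_hat.data, [10.0])

    def test_mean_agg_matrix_isolated_node(self):
        g = _graph(np.zeros((3, 3)))
        m = mean_agg_matrix(g, include_self=True)
        np.testing.assert_array_equal(m, np.eye(3))
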