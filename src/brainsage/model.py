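"""Brain-age graph networks: the fusion architecture and baseline stacks.

The main architecture predicts age from a fixed anatomical ROI graph whose
nodes carry two features (standardized GM and WM volume). It cascades r
GraphSAGE layers with a mean aggregator,

    x_v' = LeakyReLU( [ x_v ; mean_{u in N(v)} x_u ] · W ),

(a separate learnable path for the node's own vector beside the neighbour
mean; a config switch folds the node into the mean instead), and after
every layer applies a multi-head ROI-aware pooling: each head h
owns a learnable logit per ROI, softmaxed over the N nodes into an
attention distribution a_h, and pools z_h = Σ_i a_{ih} x_i; the heads are
concatenated into a per-layer graph embedding Z^(l). Each Z^(l) feeds an
independent auxiliary regression head (two-layer perceptron) whose losses
provide deep supervision during training. The per-layer embeddings are
fused (concatenation by default; mean/max/sum/weighted-sum/attention are
available) and a final two-layer perceptron regressor outputs age.

Baselines with the same predict-age contract — FCNN on flattened features,
and GCN / plain GraphSAGE / GAT / GIN stacks with a single global mean
pool — are built on the same autodiff core for the comparison harness.

All model state lives in an ordered name -> Tensor dict so optimisation,
serialisation and re-initialisation are trivially deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .autodiff import Tensor, concat, constant, parameter, stack

__all__ = [
    "ModelConfig",
    "Prediction",
    "init_params",
    "model_forward",
    "sage_layer_forward",
    "roi_aware_pool",
    "fuse",
    "aux_head_forward",
    "regressor_forward",
    "build_baseline",
    "BrainAgeGNN",
]

FUSION_METHODS = ("mean", "max", "sum", "weighted_sum", "attention", "concatenation")
ARCHITECTURES = ("fusion_sage", "plain_mean", "fcnn", "gcn", "sage", "gat", "gin")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``n_layers`` (r), ``dropout`` (rho) and the two-feature input follow the
    reference setting; ``n_heads``, ``hidden_dim`` and ``leaky_slope`` are
    engineering defaults exposed here because no canonical value exists.
    ``sage_self`` selects the GraphSAGE self-handling: ``"concat"``
    (default) keeps a separate learnable root path — the node's own
    vector concatenated beside the neighbour mean, the form mainstream
    graph libraries implement for the mean aggregator — while
    ``"include"`` folds the node into the mean itself (the inductive-GCN
    reading). The separate root path is what lets deep stacks retain
    node-distinct embeddings.
    """

    n_nodes: int
    n_layers: int = 4
    in_features: int = 2
    hidden_dim: int = 64
    n_heads: int = 4
    dropout: float = 0.15
    leaky_slope: float = 0.01
    fusion_method: str = "concatenation"
    sage_self: str = "concat"
    arch: str = "fusion_sage"

    def __post_init__(self):
        if self.n_layers < 1 or self.n_heads < 1 or self.n_nodes < 1:
            raise ValueError("n_layers, n_heads and n_nodes must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.fusion_method not in FUSION_METHODS:
            raise ValueError(f"unknown fusion method {self.fusion_method!r}")
        if self.sage_self not in ("include", "concat"):
            raise ValueError(f"unknown sage_self {self.sage_self!r}")
        if self.arch not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.arch!r}")

    @property
    def pooled_dim(self) -> int:
        return self.n_heads * self.hidden_dim

    @property
    def fused_dim(self) -> int:
        if self.fusion_method == "concatenation":
            return self.n_layers * self.pooled_dim
        return self.pooled_dim


@dataclass
class Prediction:
    """Forward-pass output: final and per-layer auxiliary age predictions.

    ``layer_embeddings`` holds the post-activation node embeddings of every
    layer (B, N, F arrays) for Dirichlet-energy analysis; ``pooled`` the
    per-layer graph embeddings.
    """

    y_hat: Tensor
    y_aux: list
    layer_embeddings: list
    pooled: list


# --------------------------------------------------------------------------
# parameter initialisation
# --------------------------------------------------------------------------

def _uniform(rng, fan_in, shape):
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


def _init_mlp(rng, params, prefix, d_in, d_hidden, d_out=1):
    params[f"{prefix}.W1"] = parameter(_uniform(rng, d_in, (d_in, d_hidden)))
    params[f"{prefix}.b1"] = parameter(_uniform(rng, d_in, (d_hidden,)))
    params[f"{prefix}.W2"] = parameter(_uniform(rng, d_hidden, (d_hidden, d_out)))
    params[f"{prefix}.b2"] = parameter(_uniform(rng, d_hidden, (d_out,)))


def init_params(config: ModelConfig, seed: int) -> dict:
    """Fan-in-scaled uniform initialisation, deterministic in the seed."""
    rng = np.random.default_rng(seed)
    p: dict = {}
    f_in = config.in_features
    h = config.hidden_dim
    if config.arch == "fcnn":
        d = config.n_nodes * config.in_features
        p["fc0.W"] = parameter(_uniform(rng, d, (d, h)))
        p["fc0.b"] = parameter(_uniform(rng, d, (h,)))
        for l in range(1, config.n_layers):
            p[f"fc{l}.W"] = parameter(_uniform(rng, h, (h, h)))
            p[f"fc{l}.b"] = parameter(_uniform(rng, h, (h,)))
        _init_mlp(rng, p, "regressor", h, h)
        return p

    for l in range(config.n_layers):
        d_in = f_in if l == 0 else h
        if config.arch == "fusion_sage" and config.sage_self == "concat":
            d_in = 2 * d_in
        if config.arch == "sage":  # classic GraphSAGE concatenates self || neighbour mean
            d_in = 2 * (f_in if l == 0 else h)
        p[f"layer{l}.W"] = parameter(_uniform(rng, d_in, (d_in, h)))
        if config.arch == "gat":
            p[f"layer{l}.a_src"] = parameter(_uniform(rng, h, (h, 1)))
            p[f"layer{l}.a_dst"] = parameter(_uniform(rng, h, (h, 1)))
        if config.arch == "gin":
            p[f"layer{l}.W2"] = parameter(_uniform(rng, h, (h, h)))
    if config.arch == "fusion_sage":
        for l in range(config.n_layers):
            p[f"pool{l}.logits"] = parameter(
                _uniform(rng, config.n_nodes, (config.n_nodes, config.n_heads))
            )
            _init_mlp(rng, p, f"aux{l}", config.pooled_dim, h)
        if config.fusion_method == "weighted_sum":
            p["fusion.logits"] = parameter(np.zeros(config.n_layers))
        elif config.fusion_method == "attention":
            p["fusion.v"] = parameter(_uniform(rng, config.pooled_dim, (config.pooled_dim, 1)))
            p["fusion.c"] = parameter(np.zeros(1))
        _init_mlp(rng, p, "regressor", config.fused_dim, h)
    else:
        _init_mlp(rng, p, "regressor", h, h)
    return p


# --------------------------------------------------------------------------
# propagation operators derived from the graph
# --------------------------------------------------------------------------

def mean_agg_matrix(graph, include_self: bool) -> np.ndarray:
    """Row-stochastic aggregation operator; isolated nodes keep themselves."""
    a = graph.adjacency()
    if include_self:
        a = a + np.eye(graph.n_nodes)
    deg = a.sum(axis=1, keepdims=True)
    deg[deg == 0] = 1.0  # isolated node without self-loop: zero aggregate
    return a / deg


def gcn_matrix(graph) -> np.ndarray:
    """Symmetric-normalised operator D^-1/2 (A + I) D^-1/2."""
    a = graph.adjacency() + np.eye(graph.n_nodes)
    d = a.sum(axis=1)
    inv = 1.0 / np.sqrt(d)
    return a * inv[:, None] * inv[None, :]


# --------------------------------------------------------------------------
# layer-level operations
# --------------------------------------------------------------------------

def sage_layer_forward(x, graph_or_matrix, w, leaky_slope=0.01, sage_self="include"):
    """One mean-aggregation GraphSAGE layer.

    ``x`` is (N, F) or batched (B, N, F); accepts a graph object or a
    precomputed aggregation matrix. ``sage_self="include"`` averages over
    the node plus its neighbours; ``"concat"`` concatenates the node's own
    vector with the neighbour mean before the linear map.
    """
    x = x if isinstance(x, Tensor) else constant(x)
    w = w if isinstance(w, Tensor) else constant(w)
    if isinstance(graph_or_matrix, np.ndarray):
        m = graph_or_matrix
    else:
        m = mean_agg_matrix(graph_or_matrix, include_self=(sage_self == "include"))
    agg = constant(m) @ x
    if sage_self == "concat":
        agg = concat([x, agg], axis=-1)
    return (agg @ w).leaky_relu(leaky_slope)


def roi_aware_pool(x, logits) -> Tensor:
    """Multi-head soft attention over ROIs -> graph-level vector.

    Each column of ``logits`` (N x H) is softmaxed over the N nodes into an
    attention distribution; head h pools z_h = Σ_i a_{ih} x_i and the heads
    are concatenated, giving length H*F (batched: (B, H*F)).
    """
    x = x if isinstance(x, Tensor) else constant(x)
    logits = logits if isinstance(logits, Tensor) else constant(logits)
    n, h = logits.shape
    if h < 1:
        raise ValueError("need at least one attention head")
    att = logits.softmax(axis=0)  # (N, H), columns sum to 1
    pooled = att.transpose((1, 0)) @ x  # (H, N) @ (..., N, F) -> (..., H, F)
    if x.data.ndim == 3:
        b = x.shape[0]
        return pooled.reshape(b, h * x.shape[-1])
    return pooled.reshape(h * x.shape[-1])


def _mlp(z, params, prefix, slope):
    hline = (z @ params[f"{prefix}.W1"] + params[f"{prefix}.b1"]).leaky_relu(slope)
    return hline @ params[f"{prefix}.W2"] + params[f"{prefix}.b2"]


def aux_head_forward(z, params, prefix="aux0", slope=0.01) -> Tensor:
    """Two-layer perceptron head: linear -> LeakyReLU -> linear(1)."""
    z = z if isinstance(z, Tensor) else constant(z)
    out = _mlp(z, params, prefix, slope)
    return out.reshape(*out.shape[:-1]) if out.shape[-1] == 1 else out


regressor_forward = aux_head_forward  # same contract, different parameters


def fuse(pooled, method: str, params=None) -> Tensor:
    """Combine per-layer graph embeddings into one vector per subject."""
    if method not in FUSION_METHODS:
        raise ValueError(f"unknown fusion method {method!r}")
    pooled = [z if isinstance(z, Tensor) else constant(z) for z in pooled]
    if method == "concatenation":
        return concat(pooled, axis=-1)
    zs = stack(pooled, axis=0)  # (r, ..., D)
    if method == "mean":
        return zs.mean(axis=0)
    if method == "sum":
        return zs.sum(axis=0)
    if method == "max":
        return zs.max(axis=0)
    r = len(pooled)
    if method == "weighted_sum":
        w = params["fusion.logits"].softmax(axis=0)  # (r,)
        w = w.reshape(r, *([1] * (zs.data.ndim - 1)))
        return (zs * w).sum(axis=0)
    # attention: data-dependent scalar score per layer, softmaxed across layers
    scores = [
        (z @ params["fusion.v"] + params["fusion.c"]).reshape(*z.shape[:-1])
        for z in pooled
    ]
    s = stack(scores, axis=-1).softmax(axis=-1)  # (..., r)
    # move layer axis last to broadcast scores, then weighted-sum over layers
    zs_last = zs.transpose(tuple(range(1, zs.data.ndim)) + (0,))  # (..., D, r)
    weighted = zs_last * s.reshape(*s.shape[:-1], 1, len(pooled))
    return weighted.sum(axis=-1)


# --------------------------------------------------------------------------
# full forward passes
# --------------------------------------------------------------------------

def _dropout(x: Tensor, rate: float, rng) -> Tensor:
    if rate <= 0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * constant(mask)


def model_forward(
    features: np.ndarray,
    graph,
    params: dict,
    config: ModelConfig,
    training: bool = False,
    dropout_rng=None,
) -> Prediction:
    """Run the configured architecture on a batch.

    ``features`` is (B, N, F) standardized node features. In training mode
    inverted dropout is applied after each activation (graph architectures)
    using ``dropout_rng``; inference is deterministic.
    """
    feats = np.asarray(features, dtype=float)
    if feats.ndim == 2:
        feats = feats[None]
    b, n, f = feats.shape
    if n != config.n_nodes or f != config.in_features:
        raise ValueError(
            f"batch shape ({n} nodes, {f} features) does not match config "
            f"({config.n_nodes}, {config.in_features})"
        )
    if training and config.dropout > 0 and dropout_rng is None:
        raise ValueError("training-mode dropout needs an RNG")
    slope = config.leaky_slope

    if config.arch == "fcnn":
        h = constant(feats.reshape(b, n * f))
        for l in range(config.n_layers):
            h = (h @ params[f"fc{l}.W"] + params[f"fc{l}.b"]).leaky_relu(slope)
            if training:
                h = _dropout(h, config.dropout, dropout_rng)
        y = regressor_forward(h, params, "regressor", slope)
        return Prediction(y_hat=y, y_aux=[], layer_embeddings=[], pooled=[])

    if config.arch == "fusion_sage":
        m = mean_agg_matrix(graph, include_self=(config.sage_self == "include"))
        h = constant(feats)
        pooled, aux, embeddings = [], [], []
        for l in range(config.n_layers):
            h = sage_layer_forward(h, m, params[f"layer{l}.W"], slope, config.sage_self)
            embeddings.append(h.data.copy())
            if training:
                h = _dropout(h, config.dropout, dropout_rng)
            z = roi_aware_pool(h, params[f"pool{l}.logits"])
            pooled.append(z)
            aux.append(aux_head_forward(z, params, f"aux{l}", slope))
        fused = fuse(pooled, config.fusion_method, params)
        y = regressor_forward(fused, params, "regressor", slope)
        return Prediction(y_hat=y, y_aux=aux, layer_embeddings=embeddings, pooled=pooled)

    # message-passing baselines: stack -> global mean pool -> regressor
    if config.arch == "plain_mean":
        op = constant(mean_agg_matrix(graph, include_self=True))
    elif config.arch == "gcn":
        op = constant(gcn_matrix(graph))
    elif config.arch == "sage":
        op = constant(mean_agg_matrix(graph, include_self=False))
    elif config.arch == "gin":
        op = constant(graph.adjacency() + np.eye(graph.n_nodes))  # (1+eps)x + sum, eps=0
    elif config.arch == "gat":
        adj_mask = graph.adjacency() + np.eye(graph.n_nodes)
        neg_mask = constant(np.where(adj_mask > 0, 0.0, -1e9))

    h = constant(feats)
    embeddings = []
    for l in range(config.n_layers):
        if config.arch in ("gcn", "plain_mean"):
            h = ((op @ h) @ params[f"layer{l}.W"]).leaky_relu(slope)
        elif config.arch == "sage":
            nbr = op @ h
            h = (concat([h, nbr], axis=-1) @ params[f"layer{l}.W"]).leaky_relu(slope)
        elif config.arch == "gin":
            pre = (op @ h) @ params[f"layer{l}.W"]
            h = (pre.leaky_relu(slope) @ params[f"layer{l}.W2"]).leaky_relu(slope)
        elif config.arch == "gat":
            hw = h @ params[f"layer{l}.W"]  # (B, N, H)
            s_src = hw @ params[f"layer{l}.a_src"]  # (B, N, 1)
            s_dst = hw @ params[f"layer{l}.a_dst"]
            e = (s_src + s_dst.transpose((0, 2, 1))).leaky_relu(0.2) + neg_mask
            alpha = e.softmax(axis=-1)
            h = (alpha @ hw).leaky_relu(slope)
        embeddings.append(h.data.copy())
        if training:
            h = _dropout(h, config.dropout, dropout_rng)
    pooled_vec = h.mean(axis=1)  # global mean pool over nodes
    y = regressor_forward(pooled_vec, params, "regressor", slope)
    return Prediction(y_hat=y, y_aux=[], layer_embeddings=embeddings, pooled=[pooled_vec])


def build_baseline(variant: str, config: ModelConfig) -> ModelConfig:
    """Config for a named baseline with the same predict-age contract."""
    mapping = {"FCNN": "fcnn", "GCN": "gcn", "GraphSAGE": "sage", "GAT": "gat", "GIN": "gin"}
    key = mapping.get(variant, variant.lower())
    if key not in ARCHITECTURES:
        raise ValueError(f"unknown baseline variant {variant!r}")
    return replace(config, arch=key)


# --------------------------------------------------------------------------
# statsmodels-style model object (fit/cross_validate live in training.py and
# are attached there to avoid a circular import)
# --------------------------------------------------------------------------

class BrainAgeGNN:
    """Brain-age regression model bound to a cohort table and an ROI graph.

    Construct from a *standardized* :class:`~brainsage.io.ROIVolumeTable`
    and an :class:`~brainsage.graph.AnatomicalGraph`; ``fit`` trains with
    the hybrid (main + auxiliary) loss and returns a
    :class:`~brainsage.training.FitResults`, and ``cross_validate`` runs
    k-fold CV returning a :class:`~brainsage.training.CVReport`.
    """

    def __init__(self, table, graph, config: Optional[ModelConfig] = None):
        if not table.standardized:
            raise ValueError("table must be standardized before modelling")
        if graph.n_nodes != table.n_rois:
            raise ValueError("graph node count does not match table ROIs")
        if config is None:
            config = ModelConfig(n_nodes=table.n_rois)
        if config.n_nodes != table.n_rois:
            raise ValueError("config.n_nodes does not match table")
        self.table = table
        self.graph = graph
        self.config = config

    @classmethod
    def from_raw_table(cls, raw_table, graph=None, config=None, lasso_config=None):
        """Convenience constructor: normalise, standardise and (optionally)
        learn the graph from the same table."""
        from .graph import LassoConfig, learn_graph
        from .io import apply_standardizer, fit_standardizer, normalize_by_tiv

        norm = normalize_by_tiv(raw_table)
        std = apply_standardizer(norm, fit_standardizer(norm))
        if graph is None:
            graph = learn_graph(std, lasso_config or LassoConfig())
        return cls(std, graph, config)

    def forward(self, params, features=None, training=False, dropout_rng=None):
        feats = self.table.node_features() if features is None else features
        return model_forward(feats, self.graph, params, self.config, training, dropout_rng)

    # fit / cross_validate are attached by brainsage.training at import time
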