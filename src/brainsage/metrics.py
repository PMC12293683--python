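"""Regression metrics and the degree-normalised Dirichlet energy.

The Dirichlet energy quantifies oversmoothing in message-passing networks:
for node features x at some layer and graph degrees d,

    E(x) = sum_i sum_{j in N(i)} || x_i/sqrt(1+d_i) - x_j/sqrt(1+d_j) ||^2

(each edge contributes in both directions). Low energy means neighbouring
embeddings have collapsed toward each other — the smooth, non-informative
regime deep mean-aggregation stacks drift into.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "mae",
    "pcc",
    "rmse",
    "dirichlet_energy",
    "energy_profile",
    "plain_aggregation_profile",
]


def _pair(y_hat, y):
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if y_hat.shape != y.shape:
        raise ValueError("prediction/target length mismatch")
    return y_hat, y


def mae(y_hat, y) -> float:
    """Mean absolute error, in years for age targets."""
    y_hat, y = _pair(y_hat, y)
    return float(np.mean(np.abs(y_hat - y)))


def rmse(y_hat, y) -> float:
    y_hat, y = _pair(y_hat, y)
    return float(np.sqrt(np.mean((y_hat - y) ** 2)))


def pcc(y_hat, y) -> float:
    """Pearson correlation (sample covariance convention)."""
    y_hat, y = _pair(y_hat, y)
    if y_hat.size < 2:
        raise ValueError("PCC needs at least 2 points")
    sy, st = y_hat.std(ddof=1), y.std(ddof=1)
    if sy == 0 or st == 0:
        raise ValueError("PCC undefined for zero-variance input")
    c = np.cov(y_hat, y, ddof=1)[0, 1]
    return float(c / (sy * st))


def dirichlet_energy(x, graph) -> float:
    """Degree-normalised Dirichlet energy of one subject's node features."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != graph.n_nodes:
        raise ValueError(
            f"features have {x.shape[0]} rows but graph has {graph.n_nodes} nodes"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite features")
    xn = x / np.sqrt(1.0 + graph.degrees)[:, None]
    if not graph.edges:
        return 0.0
    ii = np.array([e[0] for e in graph.edges])
    jj = np.array([e[1] for e in graph.edges])
    sq = np.sum((xn[ii] - xn[jj]) ** 2, axis=1)
    return float(2.0 * sq.sum())  # both directions of the double sum


def energy_profile(layer_embeddings, graph) -> np.ndarray:
    """Per-layer energy averaged over subjects.

    ``layer_embeddings`` is a sequence of (B, N, F) arrays, one per layer,
    as retained by a model forward pass.
    """
    out = []
    for emb in layer_embeddings:
        emb = np.asarray(emb, dtype=float)
        out.append(np.mean([dirichlet_energy(emb[b], graph) for b in range(emb.shape[0])]))
    return np.asarray(out)


def plain_aggregation_profile(features, graph, depth: int) -> np.ndarray:
    """Energy profile of an unparameterised include-self mean-aggregation stack.

    Applies x <- row_normalize(A + I) x repeatedly and records the energy
    after each application, averaged over subjects. This is the null model
    against which a trained network's energy retention is compared.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 2:
        x = x[None]
    m = graph.adjacency() + np.eye(graph.n_nodes)
    m /= m.sum(axis=1, keepdims=True)
    prof = []
    for _ in range(depth):
        x = m @ x
        prof.append(np.mean([dirichlet_energy(x[b], graph) for b in range(x.shape[0])]))
    return np.asarray(prof)
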