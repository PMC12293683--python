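"""Hybrid-loss training, cross-validation, prediction and checkpointing.

The training objective combines the final head's mean squared error with
deep supervision from the per-layer auxiliary heads,

    L = MSE(y_hat, y) + alpha * (1/r) * sum_l MSE(y_aux^(l), y),

optimised with Adam over shuffled mini-batches. The learning rate is
reduced on plateau of the monitored MAE and training stops early when it
stops improving. Every stochastic choice (initialisation, batch order,
dropout masks) derives from the seed in :class:`TrainConfig`, so a run is
a pure function of (data, graph, configs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor, constant
from .metrics import energy_profile, mae, pcc, rmse
from .model import BrainAgeGNN, ModelConfig, init_params, model_forward
from .io import make_folds

__all__ = [
    "TrainConfig",
    "hybrid_loss",
    "Adam",
    "FitResults",
    "CVReport",
    "fit",
    "cross_validate",
    "predict_table",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings.

    alpha, lr, batch_size and dropout (in ModelConfig) follow the reference
    protocol; the plateau scheduler (factor 0.5, patience 10, floor 1e-5),
    300-epoch cap and early stopping (patience 30) are engineering defaults.
    """

    alpha: float = 0.30
    lr: float = 0.01
    batch_size: int = 16
    epochs: int = 300
    seed: int = 0
    k_folds: int = 5
    plateau_patience: int = 10
    plateau_factor: float = 0.5
    min_lr: float = 1e-5
    early_stopping_patience: int = 30

    def __post_init__(self):
        if self.alpha < 0 or self.lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("invalid training configuration")


def hybrid_loss(y_hat, y_aux, y, alpha: float):
    """MSE of the final head plus alpha times the mean auxiliary MSE.

    Accepts plain arrays (returns float) or autodiff tensors (returns a
    scalar Tensor suitable for backward()).
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty batch")
    symbolic = isinstance(y_hat, Tensor)
    loss = ad.mse(y_hat if symbolic else constant(np.asarray(y_hat, float)), y)
    if y_aux:
        aux_terms = [
            ad.mse(a if isinstance(a, Tensor) else constant(np.asarray(a, float)), y)
            for a in y_aux
        ]
        aux = aux_terms[0]
        for t in aux_terms[1:]:
            aux = aux + t
        loss = loss + aux * (alpha / len(y_aux))
    return loss if symbolic else float(loss.data)


class Adam:
    """Adam over an ordered name -> Tensor parameter dict."""

    def __init__(self, params: dict, lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


# --------------------------------------------------------------------------
# results objects
# --------------------------------------------------------------------------

@dataclass
class FitResults:
    """Trained parameters plus provenance and diagnostics.

    ``params`` maps parameter names to NumPy arrays; ``history`` is a
    DataFrame with one row per epoch (lr, train loss, monitored MAE).
    """

    params: dict
    model_config: ModelConfig
    train_config: TrainConfig
    history: pd.DataFrame
    graph_fingerprint: str
    graph: object

    def _tensors(self):
        from .autodiff import parameter

        return {k: parameter(v) for k, v in self.params.items()}

    def predict(self, table) -> pd.DataFrame:
        """Per-subject predictions and brain-age gap (predicted - actual)."""
        if not table.standardized:
            raise ValueError("predict on a table standardized with the training scaler")
        pred = model_forward(
            table.node_features(), self.graph, self._tensors(), self.model_config
        )
        y_hat = np.atleast_1d(pred.y_hat.data)
        return pd.DataFrame(
            {
                "subject_id": table.subject_ids,
                "age": table.ages,
                "predicted_age": y_hat,
                "brain_age_gap": y_hat - table.ages,
            }
        )

    def evaluate(self, table) -> dict:
        df = self.predict(table)
        return {
            "mae": mae(df.predicted_age, df.age),
            "pcc": pcc(df.predicted_age, df.age),
            "rmse": rmse(df.predicted_age, df.age),
            "n": len(df),
        }

    def energy_profile(self, table) -> np.ndarray:
        """Per-layer Dirichlet energy of the trained network on a table
        (inference mode, averaged over subjects)."""
        pred = model_forward(
            table.node_features(), self.graph, self._tensors(), self.model_config
        )
        return energy_profile(pred.layer_embeddings, self.graph)

    def summary(self, table=None) -> str:
        cfg = self.model_config
        lines = [
            "Brain-age graph network fit",
            "=" * 42,
            f"architecture      {cfg.arch}",
            f"layers / hidden   {cfg.n_layers} / {cfg.hidden_dim}",
            f"pooling heads     {cfg.n_heads}",
            f"fusion            {cfg.fusion_method}",
            f"aux loss weight   {self.train_config.alpha}",
            f"epochs run        {len(self.history)}",
            f"final train loss  {self.history.train_loss.iloc[-1]:.4f}",
            f"graph fingerprint {self.graph_fingerprint}",
        ]
        if table is not None:
            ev = self.evaluate(table)
            lines += [
                "-" * 42,
                f"MAE  {ev['mae']:.3f} years   PCC  {ev['pcc']:.3f}   "
                f"RMSE {ev['rmse']:.3f} years   (n={ev['n']})",
            ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history.epoch, self.history.train_loss, label="train loss")
        ax.plot(self.history.epoch, self.history.monitor_mae, label="monitored MAE")
        ax.set_xlabel("epoch")
        ax.legend()
        return ax

    def plot_predictions(self, table, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.predict(table)
        ax.scatter(df.age, df.predicted_age, s=12, alpha=0.7)
        lo, hi = df.age.min(), df.age.max()
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_xlabel("chronological age (years)")
        ax.set_ylabel("predicted brain age (years)")
        return ax


@dataclass
class CVReport:
    """k-fold cross-validation metrics and out-of-fold predictions."""

    per_fold: pd.DataFrame  # fold, mae, pcc, rmse, n_val
    predictions: pd.DataFrame  # subject_id, age, predicted_age, gap, fold

    @property
    def mean_mae(self) -> float:
        return float(self.per_fold.mae.mean())

    @property
    def mean_pcc(self) -> float:
        return float(self.per_fold.pcc.mean())

    @property
    def mean_rmse(self) -> float:
        return float(self.per_fold.rmse.mean())

    def summary(self) -> str:
        f = self.per_fold
        lines = [
            f"{len(f)}-fold cross-validation",
            "=" * 46,
            "fold    MAE (y)     PCC       RMSE (y)   n",
        ]
        for _, row in f.iterrows():
            lines.append(
                f"{int(row.fold):>4}  {row.mae:9.3f}  {row.pcc:8.3f}  {row.rmse:9.3f}  {int(row.n_val):>4}"
            )
        lines.append("-" * 46)
        lines.append(
            f"mean  {f.mae.mean():9.3f}  {f.pcc.mean():8.3f}  {f.rmse.mean():9.3f}"
        )
        lines.append(
            f"  sd  {f.mae.std(ddof=1):9.3f}  {f.pcc.std(ddof=1):8.3f}  {f.rmse.std(ddof=1):9.3f}"
        )
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "per_fold": self.per_fold.to_dict(orient="records"),
            "mean": {"mae": self.mean_mae, "pcc": self.mean_pcc, "rmse": self.mean_rmse},
            "sd": {
                "mae": float(self.per_fold.mae.std(ddof=1)),
                "pcc": float(self.per_fold.pcc.std(ddof=1)),
                "rmse": float(self.per_fold.rmse.std(ddof=1)),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# --------------------------------------------------------------------------
# training loops
# --------------------------------------------------------------------------

def _epoch_monitor(model, params, table) -> float:
    pred = model_forward(table.node_features(), model.graph, params, model.config)
    return mae(pred.y_hat.data, table.ages)


def fit(model: BrainAgeGNN, train_config: TrainConfig = TrainConfig(), val_table=None) -> FitResults:
    """Train ``model`` on its bound table; monitor ``val_table`` if given.

    Without a validation table the scheduler and early stopping monitor the
    training-set MAE. Raises on NaN loss, naming the epoch.
    """
    cfg = train_config
    table = model.table
    feats = table.node_features()
    y = table.ages
    m = table.n_subjects

    params = init_params(model.config, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)  # batch order + dropout
    opt = Adam(params, lr=cfg.lr)

    monitor_table = val_table if val_table is not None else table
    best = np.inf
    best_params = None
    since_improve = 0
    since_plateau = 0
    rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(m)
        losses = []
        for start in range(0, m, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            pred = model_forward(
                feats[idx], model.graph, params, model.config,
                training=True, dropout_rng=rng,
            )
            loss = hybrid_loss(pred.y_hat, pred.y_aux, y[idx], cfg.alpha)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        monitor = _epoch_monitor(model, params, monitor_table)
        rows.append(
            {"epoch": epoch, "lr": opt.lr, "train_loss": float(np.mean(losses)),
             "monitor_mae": monitor}
        )
        if monitor < best - 1e-6:
            best = monitor
            best_params = {k: p.data.copy() for k, p in params.items()}
            since_improve = 0
            since_plateau = 0
        else:
            since_improve += 1
            since_plateau += 1
        if since_plateau > cfg.plateau_patience and opt.lr > cfg.min_lr:
            opt.lr = max(opt.lr * cfg.plateau_factor, cfg.min_lr)
            since_plateau = 0
        if since_improve > cfg.early_stopping_patience:
            break
    final = best_params if best_params is not None else {
        k: p.data.copy() for k, p in params.items()
    }
    return FitResults(
        params=final,
        model_config=model.config,
        train_config=cfg,
        history=pd.DataFrame(rows),
        graph_fingerprint=model.graph.fingerprint(),
        graph=model.graph,
    )


def cross_validate(model: BrainAgeGNN, train_config: TrainConfig = TrainConfig()) -> CVReport:
    """k-fold CV on the model's table: train on k-1 folds, score the held fold."""
    cfg = train_config
    table = model.table
    folds = make_folds(table, cfg.k_folds, seed=cfg.seed)
    fold_rows = []
    pred_frames = []
    for f in range(cfg.k_folds):
        tr = table.take(np.where(folds != f)[0])
        va = table.take(np.where(folds == f)[0])
        sub = BrainAgeGNN(tr, model.graph, model.config)
        res = fit(sub, cfg, val_table=va)
        df = res.predict(va)
        df["fold"] = f
        pred_frames.append(df)
        fold_rows.append(
            {
                "fold": f,
                "mae": mae(df.predicted_age, df.age),
                "pcc": pcc(df.predicted_age, df.age),
                "rmse": rmse(df.predicted_age, df.age),
                "n_val": len(df),
            }
        )
    return CVReport(
        per_fold=pd.DataFrame(fold_rows),
        predictions=pd.concat(pred_frames, ignore_index=True),
    )


def predict_table(results: FitResults, table, graph) -> pd.DataFrame:
    """Apply a trained checkpoint to a new standardized table.

    Refuses to run when the graph fingerprint differs from the one the
    checkpoint was trained with.
    """
    fp = graph.fingerprint()
    if fp != results.graph_fingerprint:
        raise ValueError(
            f"graph fingerprint {fp} does not match checkpoint "
            f"{results.graph_fingerprint}; predictions would not be comparable"
        )
    return results.predict(table)


# --------------------------------------------------------------------------
# checkpoint I/O
# --------------------------------------------------------------------------

def save_checkpoint(results: FitResults, directory, standardizer=None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "params.npz", **results.params)
    sidecar = {
        "model_config": asdict(results.model_config),
        "train_config": asdict(results.train_config),
        "graph_fingerprint": results.graph_fingerprint,
    }
    (directory / "config.json").write_text(json.dumps(sidecar, indent=1))
    results.history.to_csv(directory / "history.csv", index=False)
    if standardizer is not None:
        standardizer.to_json(directory / "standardizer.json")


def load_checkpoint(directory, graph) -> FitResults:
    directory = Path(directory)
    sidecar = json.loads((directory / "config.json").read_text())
    model_config = ModelConfig(**sidecar["model_config"])
    train_config = TrainConfig(**sidecar["train_config"])
    with np.load(directory / "params.npz") as npz:
        params = {k: npz[k].copy() for k in npz.files}
    history_path = directory / "history.csv"
    history = pd.read_csv(history_path) if history_path.exists() else pd.DataFrame()
    return FitResults(
        params=params,
        model_config=model_config,
        train_config=train_config,
        history=history,
        graph_fingerprint=sidecar["graph_fingerprint"],
        graph=graph,
    )


# attach the statsmodels-style methods to the model class
BrainAgeGNN.fit = lambda self, train_config=TrainConfig(), val_table=None: fit(
    self, train_config, val_table
)
BrainAgeGNN.cross_validate = lambda self, train_config=TrainConfig(): cross_validate(
    self, train_config
)
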