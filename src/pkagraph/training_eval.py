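"""Model fitting, cross-validation, grid search and the evaluation suite.

The central objects follow the fit/results pattern:

* :class:`PkaGNN` — a model built from a list of residue graphs and a
  :class:`~pkagraph.gnn_models.ModelConfig`; ``fit()`` runs seeded
  mini-batch Adam with early stopping and returns
* :class:`PkaGNNResults` — fitted parameters, training history,
  ``predict()`` and a ``summary()`` table.

On top of those sit ``cross_validate`` (10-fold CV with pooled
validation predictions) and ``grid_search`` (Cartesian hyperparameter
sweep), plus the evaluation suite: MAE/RMSE, the quantile segmentation
of |experimental pKa shift|, the null model that predicts each residue
type's reference pKa, and the Pearson correlation of predicted versus
experimental shifts.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._autodiff import Var, as_var
from .constants import REFERENCE_PKA
from .gnn_models import ModelConfig, forward_var, init_parameters
from .graph_builder import ResidueGraph
from .structure_io import ResidueKey

__all__ = [
    "PkaGNN",
    "PkaGNNResults",
    "FoldResult",
    "EvalReport",
    "CrossValidationResult",
    "loss_value",
    "train_model",
    "cross_validate",
    "grid_search",
    "null_model_predict",
    "compute_metrics",
    "quantile_report",
    "shift_correlation",
    "evaluate_predictions",
    "DEFAULT_QUANTILE_BOUNDARIES",
]

DEFAULT_QUANTILE_BOUNDARIES: tuple[float, ...] = (0.2, 0.5, 1.0)
DEFAULT_MAX_EPOCHS = 500
DEFAULT_PATIENCE = 20
SMOOTH_L1_BETA = 0.5


# ---------------------------------------------------------------------------
# Losses and metrics
# ---------------------------------------------------------------------------

def loss_value(
    pred: np.ndarray, target: np.ndarray, kind: str,
    beta: float = SMOOTH_L1_BETA,
) -> float:
    """Mean loss over a prediction vector: 'mse', 'l1' or 'smooth_l1'."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.size == 0 or pred.shape != target.shape:
        raise ValueError("pred and target must be equal-length, non-empty")
    e = pred - target
    if kind == "mse":
        return float(np.mean(e**2))
    if kind == "l1":
        return float(np.mean(np.abs(e)))
    if kind == "smooth_l1":
        ae = np.abs(e)
        per = np.where(ae < beta, e**2 / (2 * beta), ae - beta / 2)
        return float(np.mean(per))
    raise ValueError(f"unknown loss kind {kind!r}")


def _loss_var(pred: Var, target: np.ndarray, kind: str,
              beta: float = SMOOTH_L1_BETA) -> Var:
    e = pred - target
    if kind == "mse":
        return (e * e).mean()
    if kind == "l1":
        return e.abs().mean()
    if kind == "smooth_l1":
        # piecewise switch on the current error magnitudes
        small = (np.abs(e.value) < beta).astype(float)
        quad = e * e * (1.0 / (2 * beta))
        lin = e.abs() - beta / 2
        return (quad * small + lin * (1.0 - small)).mean()
    raise ValueError(f"unknown loss kind {kind!r}")


def compute_metrics(
    pairs: Sequence[tuple[float, float]]
) -> tuple[float, float]:
    """(MAE, RMSE) over (predicted, experimental) pairs."""
    if not len(pairs):
        raise ValueError("compute_metrics requires at least one pair")
    arr = np.asarray(pairs, dtype=float)
    err = arr[:, 0] - arr[:, 1]
    return float(np.mean(np.abs(err))), float(np.sqrt(np.mean(err**2)))


def null_model_predict(residue_type: str) -> float:
    """Baseline: the reference pKa of the residue type (Asp 3.7, Glu 4.2,
    His 6.5, Lys 10.4)."""
    try:
        return REFERENCE_PKA[residue_type.upper()]
    except KeyError:
        raise ValueError(
            f"unsupported residue type {residue_type!r}; "
            f"supported: {sorted(REFERENCE_PKA)}"
        ) from None


def quantile_report(
    pairs: Sequence[tuple[float, float]],
    residue_types: Sequence[str],
    boundaries: Sequence[float] = DEFAULT_QUANTILE_BOUNDARIES,
) -> list[dict]:
    """Segment pairs by |experimental pKa shift| and score each segment.

    Intervals are left-closed/right-open on the given strictly increasing
    cut points, with an open-topped last interval (nothing is dropped).
    Returns one dict per interval: lo, hi, count, mae, rmse.
    """
    bounds = list(boundaries)
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("boundaries must be strictly increasing")
    edges = [0.0] + bounds + [np.inf]
    buckets: list[list[tuple[float, float]]] = [
        [] for _ in range(len(edges) - 1)
    ]
    for (pred, exp), rtype in zip(pairs, residue_types):
        shift = abs(exp - null_model_predict(rtype))
        for q in range(len(buckets)):
            if edges[q] <= shift < edges[q + 1]:
                buckets[q].append((pred, exp))
                break
    report = []
    for q, bucket in enumerate(buckets):
        entry = {
            "lo": edges[q], "hi": edges[q + 1], "count": len(bucket),
            "mae": np.nan, "rmse": np.nan,
        }
        if bucket:
            entry["mae"], entry["rmse"] = compute_metrics(bucket)
        report.append(entry)
    return report


def shift_correlation(
    pairs: Sequence[tuple[float, float]], residue_types: Sequence[str]
) -> float:
    """Pearson R between predicted and experimental pKa shifts."""
    if len(pairs) < 3:
        raise ValueError("shift correlation requires at least 3 pairs")
    refs = np.array([null_model_predict(t) for t in residue_types])
    arr = np.asarray(pairs, dtype=float)
    pred_shift = arr[:, 0] - refs
    exp_shift = arr[:, 1] - refs
    if np.std(pred_shift) == 0 or np.std(exp_shift) == 0:
        raise ValueError("zero variance in shifts: correlation undefined")
    return float(np.corrcoef(pred_shift, exp_shift)[0, 1])


@dataclass
class EvalReport:
    """Pooled evaluation: overall, per-type and per-quantile MAE/RMSE."""

    n: int
    mae: float
    rmse: float
    per_type: dict[str, tuple[float, float]]
    quantiles: list[dict]
    q_ratio_mae: float
    q_ratio_rmse: float
    shift_r: float | None

    def summary(self) -> str:
        lines = [
            f"n = {self.n}   MAE = {self.mae:.3f}   RMSE = {self.rmse:.3f}",
        ]
        if self.shift_r is not None:
            lines[0] += f"   shift R = {self.shift_r:.3f}"
        for rtype, (mae, rmse) in sorted(self.per_type.items()):
            lines.append(f"  {rtype}: MAE {mae:.3f}  RMSE {rmse:.3f}")
        for q, entry in enumerate(self.quantiles, start=1):
            hi = "inf" if np.isinf(entry["hi"]) else f"{entry['hi']:.2f}"
            lines.append(
                f"  Q{q} |dpKa| in [{entry['lo']:.2f}, {hi}): "
                f"n={entry['count']}  MAE {entry['mae']:.3f}  "
                f"RMSE {entry['rmse']:.3f}"
            )
        lines.append(
            f"  Q{len(self.quantiles)}/Q1 ratios: "
            f"MAE {self.q_ratio_mae:.2f}  RMSE {self.q_ratio_rmse:.2f}"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n": self.n, "mae": self.mae, "rmse": self.rmse,
            "per_type": {k: list(v) for k, v in self.per_type.items()},
            "quantiles": self.quantiles,
            "q_ratio_mae": self.q_ratio_mae,
            "q_ratio_rmse": self.q_ratio_rmse,
            "shift_r": self.shift_r,
        }


def evaluate_predictions(
    pairs: Sequence[tuple[float, float]],
    residue_types: Sequence[str],
    boundaries: Sequence[float] = DEFAULT_QUANTILE_BOUNDARIES,
) -> EvalReport:
    """Full evaluation report over pooled (predicted, experimental) pairs."""
    mae, rmse = compute_metrics(pairs)
    per_type: dict[str, tuple[float, float]] = {}
    for rtype in sorted(set(residue_types)):
        sub = [p for p, t in zip(pairs, residue_types) if t == rtype]
        per_type[rtype] = compute_metrics(sub)
    quantiles = quantile_report(pairs, residue_types, boundaries)
    first, last = quantiles[0], quantiles[-1]
    ratio_mae = (
        last["mae"] / first["mae"]
        if first["count"] and last["count"] and first["mae"] > 0
        else np.nan
    )
    ratio_rmse = (
        last["rmse"] / first["rmse"]
        if first["count"] and last["count"] and first["rmse"] > 0
        else np.nan
    )
    try:
        r = shift_correlation(pairs, residue_types)
    except ValueError:
        r = None
    return EvalReport(
        n=len(pairs), mae=mae, rmse=rmse, per_type=per_type,
        quantiles=quantiles, q_ratio_mae=ratio_mae, q_ratio_rmse=ratio_rmse,
        shift_r=r,
    )


# ---------------------------------------------------------------------------
# Batching (graphs of equal node count stack into one tensor)
# ---------------------------------------------------------------------------

def _stack(graphs: Sequence[ResidueGraph]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.stack([g.node_features for g in graphs])
    A = np.stack([g.adjacency for g in graphs])
    y = np.array([g.label for g in graphs], dtype=float)
    return X, A, y


def _size_buckets(indices: Iterable[int], graphs: Sequence[ResidueGraph]):
    buckets: dict[int, list[int]] = {}
    for i in indices:
        buckets.setdefault(graphs[i].n_nodes, []).append(i)
    return buckets


def _minibatches(
    graphs: Sequence[ResidueGraph],
    batch_size: int,
    rng: np.random.Generator | None,
):
    """Yield index lists; graphs within a batch share a node count."""
    order = np.arange(len(graphs))
    if rng is not None:
        rng.shuffle(order)
    buckets = _size_buckets(order.tolist(), graphs)
    starts = []
    for size in sorted(buckets):
        idx = buckets[size]
        for s in range(0, len(idx), batch_size):
            starts.append(idx[s:s + batch_size])
    if rng is not None:
        perm = rng.permutation(len(starts))
        starts = [starts[k] for k in perm]
    return starts


class _Adam:
    """Adaptive-moment gradient updates over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class PkaGNN:
    """A graph-network pKa regressor bound to its training data.

    Parameters
    ----------
    graphs : training residue graphs (labels set).
    config : architecture + hyperparameters.
    val_graphs : held-out graphs monitored for early stopping; when
        omitted, a seeded 10% split of ``graphs`` is carved out.
    """

    def __init__(
        self,
        graphs: Sequence[ResidueGraph],
        config: ModelConfig,
        val_graphs: Sequence[ResidueGraph] | None = None,
    ):
        if not graphs:
            raise ValueError("no training graphs")
        self.config = config
        if val_graphs is None:
            rng = np.random.default_rng(config.seed)
            order = rng.permutation(len(graphs))
            n_val = max(1, len(graphs) // 10)
            val_idx = set(order[:n_val].tolist())
            val_graphs = [graphs[i] for i in sorted(val_idx)]
            graphs = [g for i, g in enumerate(graphs) if i not in val_idx]
            if not graphs:
                raise ValueError("validation split consumed all graphs")
        self.train_graphs = list(graphs)
        self.val_graphs = list(val_graphs)

    def fit(
        self,
        max_epochs: int = DEFAULT_MAX_EPOCHS,
        patience: int = DEFAULT_PATIENCE,
    ) -> "PkaGNNResults":
        """Seeded mini-batch Adam with early stopping on validation loss.

        Stops after ``patience`` epochs without improvement (or at
        ``max_epochs``); the returned results carry the best-epoch
        parameters.  Fully reproducible for a given config seed.
        """
        cfg = self.config
        params = init_parameters(cfg)
        opt = _Adam(params, lr=cfg.learning_rate)
        rng = np.random.default_rng([cfg.seed, 7])

        best_val = np.inf
        best_params = {k: v.copy() for k, v in params.items()}
        best_epoch = 0
        history: list[dict] = []
        since_best = 0

        for epoch in range(1, max_epochs + 1):
            train_losses = []
            for batch_idx in _minibatches(self.train_graphs, cfg.batch_size, rng):
                batch = [self.train_graphs[i] for i in batch_idx]
                X, A, y = _stack(batch)
                pvars = {k: as_var(v) for k, v in params.items()}
                pred = forward_var(
                    as_var(X), as_var(A), cfg, pvars, training=True, rng=rng
                )
                loss = _loss_var(pred, y, cfg.loss)
                if not np.isfinite(loss.value):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch} "
                        f"(config: {cfg})"
                    )
                loss.backward()
                grads = {k: pvars[k].grad for k in params}
                opt.step(params, grads)
                train_losses.append(float(loss.value))
            val_pred = _predict(self.val_graphs, cfg, params)
            val_y = np.array([g.label for g in self.val_graphs])
            val_loss = loss_value(val_pred, val_y, cfg.loss)
            history.append(
                {"epoch": epoch,
                 "train_loss": float(np.mean(train_losses)),
                 "val_loss": val_loss}
            )
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in params.items()}
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= patience:
                    break
        return PkaGNNResults(
            config=cfg,
            params=best_params,
            history=history,
            best_epoch=best_epoch,
            best_val_loss=float(best_val),
        )


def _predict(
    graphs: Sequence[ResidueGraph],
    config: ModelConfig,
    params: dict[str, np.ndarray],
) -> np.ndarray:
    """Deterministic (dropout-off) predictions, bucketed by graph size."""
    out = np.empty(len(graphs))
    buckets = _size_buckets(range(len(graphs)), graphs)
    pvars = {k: as_var(v) for k, v in params.items()}
    for size, idx in buckets.items():
        X, A, _ = _stack([graphs[i] for i in idx])
        pred = forward_var(as_var(X), as_var(A), config, pvars, training=False)
        out[np.array(idx)] = np.atleast_1d(pred.value)
    return out


@dataclass
class PkaGNNResults:
    """Fitted parameters plus training history and prediction interface."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    history: list[dict]
    best_epoch: int
    best_val_loss: float
    normalization: dict[str, np.ndarray] | None = None

    @property
    def epochs_run(self) -> int:
        return len(self.history)

    def predict(self, graphs: Sequence[ResidueGraph]) -> np.ndarray:
        return _predict(graphs, self.config, self.params)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "pKa graph-network regression results",
            "=" * 44,
            f"architecture      {cfg.architecture}",
            f"hidden channels   {cfg.hidden_channels}",
            f"dropout           {cfg.dropout_rate}",
            f"loss              {cfg.loss}",
            f"learning rate     {cfg.learning_rate}",
            f"batch size        {cfg.batch_size}",
            f"seed              {cfg.seed}",
        ]
        if cfg.architecture == "GAT":
            lines.append(f"attention heads   {cfg.n_heads}")
        if cfg.architecture == "GIN":
            lines.append(f"pooling           {cfg.pooling}")
        lines += [
            "-" * 44,
            f"epochs run        {self.epochs_run}",
            f"best epoch        {self.best_epoch}",
            f"best val loss     {self.best_val_loss:.4f}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Self-contained checkpoint: config + parameters (+ normalization)."""
        payload = {
            "config": self.config.__dict__,
            "params": {k: v.tolist() for k, v in self.params.items()},
            "best_epoch": self.best_epoch,
            "best_val_loss": self.best_val_loss,
            "history": self.history,
        }
        if self.normalization is not None:
            payload["normalization"] = {
                k: np.asarray(v).tolist() for k, v in self.normalization.items()
            }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "PkaGNNResults":
        with open(path) as fh:
            payload = json.load(fh)
        norm = payload.get("normalization")
        return cls(
            config=ModelConfig(**payload["config"]),
            params={k: np.array(v) for k, v in payload["params"].items()},
            history=payload.get("history", []),
            best_epoch=payload["best_epoch"],
            best_val_loss=payload["best_val_loss"],
            normalization=(
                {k: np.array(v) for k, v in norm.items()} if norm else None
            ),
        )


def train_model(
    train_graphs: Sequence[ResidueGraph],
    val_graphs: Sequence[ResidueGraph],
    config: ModelConfig,
    max_epochs: int = DEFAULT_MAX_EPOCHS,
    patience: int = DEFAULT_PATIENCE,
) -> PkaGNNResults:
    """Functional wrapper: fit on an explicit train/validation split."""
    if not train_graphs or not val_graphs:
        raise ValueError("train and validation sets must be non-empty")
    return PkaGNN(train_graphs, config, val_graphs=val_graphs).fit(
        max_epochs=max_epochs, patience=patience
    )


# ---------------------------------------------------------------------------
# Cross-validation and grid search
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    fold_index: int
    predictions: list[tuple[ResidueKey, float, float]]  # key, pred, exp
    epochs_run: int
    best_validation_loss: float


@dataclass
class CrossValidationResult:
    fold_results: list[FoldResult]
    report: EvalReport
    config: ModelConfig

    @property
    def pooled_pairs(self) -> list[tuple[float, float]]:
        return [
            (pred, exp)
            for fr in self.fold_results
            for _k, pred, exp in fr.predictions
        ]

    def summary(self) -> str:
        head = (
            f"{len(self.fold_results)}-fold cross-validation, "
            f"{self.config.architecture}"
        )
        return head + "\n" + self.report.summary()


def _partition(
    n: int, k: int, rng: np.random.Generator,
    strata: Sequence[str] | None = None,
) -> list[np.ndarray]:
    """Seeded random split into k near-equal folds (optionally stratified)."""
    if strata is None:
        order = rng.permutation(n)
        return [order[f::k] for f in range(k)]
    folds: list[list[int]] = [[] for _ in range(k)]
    by_stratum: dict[str, list[int]] = {}
    for i, s in enumerate(strata):
        by_stratum.setdefault(s, []).append(i)
    f = 0
    for s in sorted(by_stratum):
        idx = np.array(by_stratum[s])
        rng.shuffle(idx)
        for i in idx:
            folds[f % k].append(int(i))
            f += 1
    return [np.array(sorted(fold)) for fold in folds]


def cross_validate(
    graphs: Sequence[ResidueGraph],
    config: ModelConfig,
    k: int = 10,
    seed: int | None = None,
    max_epochs: int = DEFAULT_MAX_EPOCHS,
    patience: int = DEFAULT_PATIENCE,
    stratify_by_type: bool = False,
    boundaries: Sequence[float] = DEFAULT_QUANTILE_BOUNDARIES,
) -> CrossValidationResult:
    """k-fold CV: each graph is predicted exactly once while held out.

    Folds are a seeded random partition (optionally stratified by residue
    type).  Per-fold models train on the other k-1 folds with early
    stopping monitored on the held-out fold; metrics are computed on the
    pooled held-out predictions.
    """
    if k > len(graphs):
        raise ValueError(f"k={k} exceeds the number of graphs ({len(graphs)})")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([seed, 11])
    strata = [g.key.residue_name for g in graphs] if stratify_by_type else None
    folds = _partition(len(graphs), k, rng, strata)

    fold_results: list[FoldResult] = []
    for f, val_idx in enumerate(folds):
        val_set = set(val_idx.tolist())
        train = [g for i, g in enumerate(graphs) if i not in val_set]
        val = [graphs[i] for i in val_idx]
        fold_cfg = replace(config, seed=(seed * 31 + f) % (2**31))
        res = train_model(train, val, fold_cfg, max_epochs, patience)
        preds = res.predict(val)
        fold_results.append(
            FoldResult(
                fold_index=f,
                predictions=[
                    (g.key, float(p), g.label) for g, p in zip(val, preds)
                ],
                epochs_run=res.epochs_run,
                best_validation_loss=res.best_val_loss,
            )
        )
    pairs = [
        (pred, exp) for fr in fold_results for _k, pred, exp in fr.predictions
    ]
    types = [
        key.residue_name for fr in fold_results
        for key, _p, _e in fr.predictions
    ]
    report = evaluate_predictions(pairs, types, boundaries)
    return CrossValidationResult(fold_results, report, config)


def _config_hash(cfg: ModelConfig) -> str:
    blob = json.dumps(cfg.__dict__, sort_keys=True)
    return hashlib.md5(blob.encode()).hexdigest()[:10]


def grid_search(
    graphs: Sequence[ResidueGraph],
    grid: Mapping[str, Sequence],
    k: int = 10,
    seed: int = 0,
    max_epochs: int = DEFAULT_MAX_EPOCHS,
    patience: int = DEFAULT_PATIENCE,
) -> pd.DataFrame:
    """Cartesian sweep over ModelConfig fields; one CV row per combination.

    ``grid`` maps ModelConfig field names to value lists (e.g.
    ``{"architecture": ["GCN"], "hidden_channels": [16, 32], ...}``).
    Returns a table with pooled CV MAE/RMSE per configuration; the best
    row (minimum MAE, RMSE tie-break) is flagged in the ``best`` column.
    """
    keys = list(grid)
    if not keys or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty on every axis")
    rows = []
    for combo in itertools.product(*(grid[k_] for k_ in keys)):
        cfg = ModelConfig(**{**dict(zip(keys, combo)), "seed": seed})
        cv = cross_validate(
            graphs, cfg, k=k, seed=seed,
            max_epochs=max_epochs, patience=patience,
        )
        rows.append(
            {
                "config_hash": _config_hash(cfg),
                "architecture": cfg.architecture,
                "hidden": cfg.hidden_channels,
                "batch": cfg.batch_size,
                "lr": cfg.learning_rate,
                "dropout": cfg.dropout_rate,
                "loss": cfg.loss,
                "heads": cfg.n_heads,
                "pooling": cfg.pooling,
                "mae": cv.report.mae,
                "rmse": cv.report.rmse,
            }
        )
    table = pd.DataFrame(rows)
    best_idx = table.sort_values(["mae", "rmse"]).index[0]
    table["best"] = False
    table.loc[best_idx, "best"] = True
    return table
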