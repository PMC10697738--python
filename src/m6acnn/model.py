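"""Convolutional classifier for m6A site windows: model and results objects.

The estimator follows the model/results idiom of statistical modelling
packages: :class:`M6AConvNet` is constructed from encoded data (or built via
:meth:`M6AConvNet.from_samples`), and :meth:`M6AConvNet.fit` returns an
:class:`M6AConvNetResults` carrying the learned weights, the per-epoch
training history, and prediction/evaluation/summary methods.

The network is a stack of [conv -> ReLU -> max-pool -> dropout] blocks over
the ENAC-encoded sequence, a fully connected ReLU layer (or layers) with
dropout, and a single sigmoid output unit. Training minimizes binary
cross-entropy with Adam; everything is seeded end-to-end, so the same
configuration, data and seed reproduce identical weights and predictions.

Model capacity follows data volume: three presets (small/medium/large keyed
on training-set size) adjust the convolution blocks and fully connected
widths, all keeping 64 filters in the first convolutional layer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .datasets import SequenceSample
from .encoding import enac_encode_batch
from .nnet import Adam, ConvNet, bce_loss, sigmoid

__all__ = [
    "ModelConfig",
    "preset_config",
    "M6AConvNet",
    "M6AConvNetResults",
    "CrossValidationResult",
    "cross_validate",
]


@dataclass
class ModelConfig:
    """Architecture and optimization hyperparameters.

    conv_blocks entries: n_filters, kernel_rows, pool, dropout. The first
    convolutional layer defaults to 64 filters; its post-ReLU activations are
    the substrate of filter-level interpretation.
    """

    conv_blocks: list[dict] = field(
        default_factory=lambda: [
            {"n_filters": 64, "kernel_rows": 5, "pool": 2, "dropout": 0.25}
        ]
    )
    fc_units: list[int] = field(default_factory=lambda: [32])
    fc_dropout: float = 0.25
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 20
    early_stop_patience: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for b in self.conv_blocks:
            if not (0.0 <= b["dropout"] < 1.0):
                raise ValueError("conv dropout must be in [0, 1)")
            if min(b["n_filters"], b["kernel_rows"], b["pool"]) < 1:
                raise ValueError("conv block sizes must be positive")
        if not (0.0 <= self.fc_dropout < 1.0):
            raise ValueError("fc_dropout must be in [0, 1)")

    def replace(self, **kw) -> "ModelConfig":
        d = asdict(self)
        d.update(kw)
        return ModelConfig(**d)


def preset_config(n_train: int, seed: int = 0) -> ModelConfig:
    """Capacity preset keyed on training-set size.

    small (< 10k samples): one conv block with wide max-pooling (a first-layer
    motif detector reduced to a few coarse position bins, which suits signals
    that float within the flanks) and a narrow head; medium (< 50k): two conv
    blocks; large: two wider blocks and a deeper head.
    """
    if n_train < 10_000:
        return ModelConfig(
            conv_blocks=[{"n_filters": 64, "kernel_rows": 7, "pool": 31, "dropout": 0.25}],
            fc_units=[32],
            learning_rate=2e-3,
            seed=seed,
        )
    if n_train < 50_000:
        return ModelConfig(
            conv_blocks=[
                {"n_filters": 64, "kernel_rows": 7, "pool": 4, "dropout": 0.25},
                {"n_filters": 32, "kernel_rows": 5, "pool": 4, "dropout": 0.25},
            ],
            fc_units=[64],
            seed=seed,
        )
    return ModelConfig(
        conv_blocks=[
            {"n_filters": 64, "kernel_rows": 7, "pool": 2, "dropout": 0.3},
            {"n_filters": 64, "kernel_rows": 5, "pool": 2, "dropout": 0.3},
        ],
        fc_units=[128, 32],
        fc_dropout=0.3,
        seed=seed,
    )


class M6AConvNet:
    """Binary classifier over ENAC-encoded A-centered windows.

    Parameters
    ----------
    X : ndarray, shape (N, rows, 4)
        ENAC-encoded windows (rows = L - 1 for the default encoding).
    y : ndarray, shape (N,)
        0/1 labels (1 = modified site).
    config : ModelConfig, optional
        Defaults to the small preset adjusted for len(y).
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        config: ModelConfig | None = None,
    ) -> None:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 3 or X.shape[2] != 4:
            raise ValueError(f"X must have shape (N, rows, 4), got {X.shape}")
        if y.shape != (X.shape[0],):
            raise ValueError("y length must match X")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("labels must be 0/1")
        self.X, self.y = X, y
        self.config = config if config is not None else preset_config(len(y))

    @classmethod
    def from_samples(
        cls, samples: Sequence[SequenceSample], config: ModelConfig | None = None
    ) -> "M6AConvNet":
        X, y = enac_encode_batch(samples)
        return cls(X, y, config)

    @property
    def input_rows(self) -> int:
        return self.X.shape[1]

    def _build_net(self) -> ConvNet:
        cfg = self.config
        return ConvNet(
            self.input_rows, cfg.conv_blocks, cfg.fc_units, cfg.fc_dropout, cfg.seed
        )

    def fit(self, validation_fraction: float = 0.0, verbose: bool = False
            ) -> "M6AConvNetResults":
        """Train with Adam on binary cross-entropy.

        If ``validation_fraction`` > 0 (or early stopping is configured), a
        stratified tail fraction is held out for per-epoch validation loss;
        early stopping restores the best-validation-loss weights.
        """
        cfg = self.config
        classes = np.unique(self.y)
        if classes.size < 2:
            raise ValueError("training data must contain both classes")
        rng = np.random.default_rng(cfg.seed)

        X, y = self.X, self.y
        Xval = yval = None
        if cfg.early_stop_patience is not None and validation_fraction <= 0:
            validation_fraction = 0.1
        if validation_fraction > 0:
            idx = _stratified_holdout(y, validation_fraction, rng)
            val_mask = np.zeros(len(y), dtype=bool)
            val_mask[idx] = True
            Xval, yval = X[val_mask], y[val_mask]
            X, y = X[~val_mask], y[~val_mask]

        net = self._build_net()
        opt = Adam(lr=cfg.learning_rate)
        n = len(y)
        history: list[dict] = []
        best_val = np.inf
        best_weights = None
        patience_left = cfg.early_stop_patience

        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                Xb, yb = X[batch], y[batch]
                logits, cache = net.forward(Xb, training=True, rng=rng)
                p = sigmoid(logits)
                loss = bce_loss(p, yb)
                dlogits = (p - yb) / len(yb)
                grads, _ = net.backward(cache, dlogits)
                opt.step(net.params, grads)
                epoch_loss += loss * len(yb)
            rec = {"epoch": epoch, "train_loss": epoch_loss / n}
            if Xval is not None:
                val_loss = bce_loss(net.predict_proba(Xval), yval)
                rec["val_loss"] = val_loss
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_weights = net.get_weights()
                    patience_left = cfg.early_stop_patience
                elif cfg.early_stop_patience is not None:
                    patience_left -= 1
                    if patience_left < 0:
                        if verbose:
                            print(f"early stop at epoch {epoch}")
                        break
            history.append(rec)
            if verbose:
                print(", ".join(f"{k}={v:.4f}" if k != "epoch" else f"epoch {v}"
                                for k, v in rec.items()))
        if cfg.early_stop_patience is not None and best_weights is not None:
            net.set_weights(best_weights)
        return M6AConvNetResults(self, net, pd.DataFrame(history))


def _stratified_holdout(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a stratified holdout of about ``fraction`` of the data."""
    take: list[np.ndarray] = []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        k = max(1, int(round(fraction * idx.size)))
        take.append(rng.choice(idx, size=k, replace=False))
    return np.concatenate(take)


class M6AConvNetResults:
    """Fitted classifier: learned weights, history, prediction and reporting."""

    def __init__(self, model: M6AConvNet, net: ConvNet, history: pd.DataFrame) -> None:
        self.model = model
        self.net = net
        self.history = history
        self.config = model.config

    # -- prediction --------------------------------------------------------

    def _encode_if_needed(self, X) -> np.ndarray:
        if len(X) and isinstance(X[0], SequenceSample):
            X, _ = enac_encode_batch(X)
        return np.asarray(X, dtype=float)

    def predict_proba(self, X) -> np.ndarray:
        """Sigmoid probabilities in [0, 1]; dropout disabled, deterministic."""
        return self.net.predict_proba(self._encode_if_needed(X))

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        """Hard 0/1 calls at the given threshold (ties classified positive)."""
        return (self.predict_proba(X) >= threshold).astype(int)

    def score(self, X: np.ndarray, output: str = "prob") -> np.ndarray:
        """Scores for attribution: sigmoid probability or pre-sigmoid logit."""
        X = self._encode_if_needed(X)
        if output == "prob":
            return self.net.predict_proba(X)
        if output == "logit":
            return self.net.predict_logit(X)
        raise ValueError("output must be 'prob' or 'logit'")

    def input_gradient(self, X: np.ndarray, output: str = "prob") -> np.ndarray:
        return self.net.input_gradient(self._encode_if_needed(X), wrt=output)

    # -- reporting ---------------------------------------------------------

    def evaluate(self, X, y: np.ndarray, threshold: float = 0.5):
        from .evaluation import evaluate

        return evaluate(np.asarray(y), self.predict_proba(X), threshold)

    def summary(self) -> str:
        cfg = self.config
        lines = ["M6AConvNet results", "=" * 40]
        lines.append(f"input rows            {self.model.input_rows}")
        for i, b in enumerate(cfg.conv_blocks):
            lines.append(
                f"conv block {i}          {b['n_filters']} filters x {b['kernel_rows']} rows,"
                f" pool {b['pool']}, dropout {b['dropout']}"
            )
        lines.append(f"fc units              {cfg.fc_units} (dropout {cfg.fc_dropout})")
        n_params = sum(v.size for v in self.net.params.values())
        lines.append(f"parameters            {n_params}")
        lines.append(f"optimizer             Adam(lr={cfg.learning_rate})")
        lines.append(f"loss                  binary cross-entropy")
        lines.append(f"epochs run            {len(self.history)}")
        if len(self.history):
            lines.append(f"final train loss      {self.history['train_loss'].iloc[-1]:.4f}")
            if "val_loss" in self.history:
                lines.append(f"final val loss        {self.history['val_loss'].iloc[-1]:.4f}")
        lines.append(f"seed                  {cfg.seed}")
        return "\n".join(lines)

    # -- persistence (single JSON text file: config + weights) -------------

    def save(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "input_rows": self.model.input_rows,
            "weights": {k: v.tolist() for k, v in self.net.params.items()},
            "history": self.history.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "M6AConvNetResults":
        payload = json.loads(Path(path).read_text())
        cfg = ModelConfig(**payload["config"])
        rows = payload["input_rows"]
        model = M6AConvNet(np.zeros((2, rows, 4)), np.array([0.0, 1.0]), cfg)
        res_net = model._build_net()
        res_net.set_weights({k: np.asarray(v) for k, v in payload["weights"].items()})
        return cls(model, res_net, pd.DataFrame(payload["history"]))


@dataclass
class CrossValidationResult:
    best_config: ModelConfig
    fold_metrics: pd.DataFrame
    results: M6AConvNetResults


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    config_grid: Sequence[ModelConfig],
    k: int = 5,
    seed: int = 0,
) -> CrossValidationResult:
    """Stratified k-fold model selection, then a final fit on all data.

    Each candidate configuration is trained on k-1 folds and scored on the
    held-out fold; the configuration with the highest mean validation AUC is
    refit on the full training data. The fold table reports Sen/Spe/Acc/MCC/
    AUC/AP per (config, fold).
    """
    from .evaluation import evaluate

    if k < 2:
        raise ValueError("k must be >= 2")
    if not config_grid:
        raise ValueError("config grid must be non-empty")
    y = np.asarray(y, dtype=float)
    for c in np.unique(y):
        if (y == c).sum() < k:
            raise ValueError(f"class {c} has fewer samples than k={k}")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows: list[dict] = []
    mean_auc = np.full(len(config_grid), -np.inf)
    for ci, cfg in enumerate(config_grid):
        aucs = []
        for fold, (tr, va) in enumerate(skf.split(X, y)):
            res = M6AConvNet(X[tr], y[tr], cfg).fit()
            rep = evaluate(y[va], res.predict_proba(X[va]))
            rows.append(
                {
                    "config": ci,
                    "fold": fold,
                    "Sen": rep.sen,
                    "Spe": rep.spe,
                    "Acc": rep.acc,
                    "MCC": rep.mcc,
                    "AUC": rep.auc,
                    "AP": rep.ap,
                }
            )
            aucs.append(rep.auc)
        mean_auc[ci] = float(np.mean(aucs))
    best = int(np.argmax(mean_auc))
    final = M6AConvNet(X, y, config_grid[best]).fit()
    return CrossValidationResult(config_grid[best], pd.DataFrame(rows), final)
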