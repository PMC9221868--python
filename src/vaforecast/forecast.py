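"""Visual-acuity forecasting models and their metric suite.

Shallow regressors (linear, gradient boosting, random forest, extremely
randomised trees) are evaluated with patient-grouped 10-fold
cross-validation on flattened windows. The recurrent forecaster is a
bidirectional RNN/LSTM/GRU whose concatenated final states pass through
dropout and a single sigmoid unit, so predictions are bounded in (0, 1)
like decimal VA; it trains with MSE loss, early stopping on a
patient-grouped validation split, and best-weights restore. The LSTM
variant L1-penalises its input-feature weights (alpha = 0.01 by
default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import (
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import LinearRegression

from . import nn
from .prep import WindowedDataset, build_windowed_dataset, grouped_train_val_test, min_max_normalise
from .records import EyeSeries

__all__ = [
    "MetricsReport",
    "RecurrentNetConfig",
    "RecurrentNetRegressor",
    "compute_metrics",
    "grouped_folds",
    "fit_shallow",
    "fit_recurrent",
    "run_experiment",
    "SHALLOW_MODELS",
    "RECURRENT_MODELS",
]

log = logging.getLogger(__name__)

RMSPE_EPS = 1e-3  # actual VAs below this are excluded from the percentage error


@dataclass
class MetricsReport:
    """Regression metrics for one model/encoding/window-size cell."""

    mse: float
    mae: float
    rmse: float
    rmspe: float
    r2: float
    model: str = ""
    encoding: str = ""
    n_input_visits: int = 0
    fold_scores: list[dict] = field(default_factory=list)
    rmspe_defined: bool = True

    def as_row(self) -> dict:
        return {
            "model": self.model,
            "encoding": self.encoding,
            "n_input_visits": self.n_input_visits,
            "mse": self.mse,
            "mae": self.mae,
            "rmse": self.rmse,
            "rmspe": self.rmspe,
            "r2": self.r2,
        }


def compute_metrics(actual, predicted, eps: float = RMSPE_EPS) -> MetricsReport:
    """MSE, MAE, RMSE, RMSPE and R² of predictions against actual VA.

    RMSPE divides by the actual value, so entries with actual <= eps are
    excluded; if none remain RMSPE is NaN and flagged undefined.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.size == 0:
        raise ValueError("actual and predicted must be equal-length nonempty vectors")
    err = a - p
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(mse))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else np.nan
    mask = a > eps
    if mask.any():
        rmspe = float(np.sqrt(np.mean((err[mask] / a[mask]) ** 2)))
        defined = True
    else:
        rmspe, defined = np.nan, False
        log.warning("all actual values <= %g: RMSPE undefined", eps)
    return MetricsReport(mse, mae, rmse, rmspe, r2, rmspe_defined=defined)


@dataclass
class RecurrentNetConfig:
    """Hyper-parameters of the bidirectional recurrent forecaster."""

    nn_type: str = "lstm"  # simple | lstm | gru
    bidirectional: bool = True
    hidden_units: int = 64
    dropout_rate: float = 0.2
    l1_alpha: float = 0.01
    epochs_max: int = 300
    patience: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-2
    seed: int = 0

    def validate(self) -> "RecurrentNetConfig":
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l1_alpha < 0:
            raise ValueError("l1_alpha must be >= 0")
        if self.nn_type not in ("simple", "lstm", "gru"):
            raise ValueError("nn_type must be simple, lstm or gru")
        return self


class RecurrentNetRegressor(BaseEstimator, RegressorMixin):
    """Bidirectional recurrent VA forecaster with a sigmoid output unit.

    Input is a (n_series, timesteps, n_features) block; features are
    min-max scaled on the fitting data. Early stopping monitors the MSE
    on ``validation_data`` when given, otherwise on an internal
    patient-grouped 80/20 split.
    """

    def __init__(
        self,
        nn_type: str = "lstm",
        bidirectional: bool = True,
        hidden_units: int = 64,
        dropout_rate: float = 0.2,
        l1_alpha: float = 0.01,
        epochs_max: int = 300,
        patience: int = 20,
        batch_size: int = 32,
        learning_rate: float = 1e-2,
        seed: int = 0,
    ):
        self.nn_type = nn_type
        self.bidirectional = bidirectional
        self.hidden_units = hidden_units
        self.dropout_rate = dropout_rate
        self.l1_alpha = l1_alpha
        self.epochs_max = epochs_max
        self.patience = patience
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    def _config(self) -> RecurrentNetConfig:
        return RecurrentNetConfig(
            self.nn_type,
            self.bidirectional,
            self.hidden_units,
            self.dropout_rate,
            self.l1_alpha,
            self.epochs_max,
            self.patience,
            self.batch_size,
            self.learning_rate,
            self.seed,
        ).validate()

    def _forward(self, x: np.ndarray, rng=None, training: bool = False) -> nn.Tensor:
        steps = [nn.Tensor(x[:, t, :], requires_grad=False) for t in range(x.shape[1])]
        h = self._recurrent(steps)
        h = nn.dropout(h, self.dropout_rate, rng, training)
        return self._head(h).sigmoid()

    def fit(self, X, y, groups=None, validation_data=None):
        cfg = self._config()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        if X.ndim != 3 or X.shape[1] == 0:
            raise ValueError("X must be (n_series, timesteps>=1, n_features)")
        n, t, f = X.shape
        flat = X.reshape(n * t, f)
        if validation_data is None:
            split_groups = groups if groups is not None else np.arange(n)
            tr, va, _ = grouped_train_val_test(split_groups, (0.8, 0.15, 0.05), seed=cfg.seed)
            va = np.concatenate([va, _])
            X_tr, y_tr, X_va, y_va = X[tr], y[tr], X[va], y[va]
        else:
            X_tr, y_tr = X, y
            X_va = np.asarray(validation_data[0], dtype=float)
            y_va = np.asarray(validation_data[1], dtype=float).reshape(-1, 1)
        scaled, scaler = min_max_normalise(X_tr.reshape(-1, f), X_va.reshape(-1, f))
        self.scaler_ = scaler
        self._constant_mask = scaler.data_range_ == 0
        X_tr = scaled[0].reshape(X_tr.shape)
        X_va = scaled[1].reshape(X_va.shape)
        rng = np.random.default_rng(cfg.seed)
        self._recurrent = nn.BiRecurrent(rng, cfg.nn_type, f, cfg.hidden_units, cfg.bidirectional)
        self._head = nn.Dense(rng, self._recurrent.out_dim, 1)
        params = self._recurrent.params + self._head.params
        opt = nn.Adam(params, lr=cfg.learning_rate)
        best_val, best_weights, since_best = np.inf, None, 0
        self.train_curve_, self.val_curve_ = [], []
        for _epoch in range(cfg.epochs_max):
            order = rng.permutation(len(X_tr))
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                pred = self._forward(X_tr[idx], rng=rng, training=True)
                loss = ((pred - nn.Tensor(y_tr[idx], requires_grad=False)) ** 2).mean()
                penalty = self._recurrent.input_weight_l1()
                if penalty is not None and cfg.l1_alpha > 0:
                    loss = loss + penalty * cfg.l1_alpha
                loss.backward()
                opt.step()
                losses.append(loss.data.item())
            val_pred = self._forward(X_va).data
            val_mse = float(np.mean((val_pred - y_va) ** 2))
            if not np.isfinite(val_mse):
                raise RuntimeError("training failure: non-finite validation loss")
            self.train_curve_.append(float(np.mean(losses)))
            self.val_curve_.append(val_mse)
            if val_mse < best_val - 1e-9:
                best_val, since_best = val_mse, 0
                best_weights = [p.data.copy() for p in params]
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        if best_weights is not None:
            for p, w in zip(params, best_weights):
                p.data = w
        self.val_mse_ = best_val
        self.n_features_in_ = f
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n, t, f = X.shape
        scaled = self.scaler_.transform(X.reshape(n * t, f))
        scaled[:, self._constant_mask] = 0.0
        return self._forward(scaled.reshape(n, t, f)).data.ravel()


SHALLOW_MODELS = ("linear", "gbm", "random_forest", "extra_trees")
RECURRENT_MODELS = ("rnn", "lstm", "gru")


def _make_shallow(model: str, seed: int):
    if model == "linear":
        return LinearRegression()
    if model == "gbm":
        return GradientBoostingRegressor(random_state=seed)
    if model == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1)
    if model == "extra_trees":
        return ExtraTreesRegressor(random_state=seed, n_jobs=1)
    raise ValueError(f"unknown shallow model {model!r}")


def grouped_folds(groups: np.ndarray, n_folds: int, seed: int = 0) -> list[np.ndarray]:
    """Deterministic patient-grouped folds, invariant to sample order."""
    uniq = sorted(set(groups))
    rng = np.random.default_rng(seed)
    rng.shuffle(uniq)
    assignment = {g: i % n_folds for i, g in enumerate(uniq)}
    fold_of = np.array([assignment[g] for g in groups])
    return [np.flatnonzero(fold_of == i) for i in range(n_folds)]


def fit_shallow(
    dataset: WindowedDataset, model: str = "linear", n_folds: int = 10, seed: int = 0
) -> MetricsReport:
    """Patient-grouped k-fold cross-validation of a shallow regressor.

    Windows are flattened to one feature vector per sample; features are
    min-max scaled inside each training fold. Mean metrics over folds are
    reported, with per-fold scores retained.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    x, _ = dataset.flatten()
    y = dataset.targets
    n_groups = len(set(dataset.groups))
    if n_groups < n_folds:
        log.warning("only %d patient groups: reducing fold count from %d", n_groups, n_folds)
        n_folds = max(2, n_groups)
    folds = grouped_folds(dataset.groups, n_folds, seed=seed)
    fold_scores = []
    preds = np.full(len(y), np.nan)
    for i, test_idx in enumerate(folds):
        if len(test_idx) == 0:
            continue
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        (x_tr, x_te), _scaler = min_max_normalise(x[train_idx], x[test_idx])
        est = _make_shallow(model, seed)
        est.fit(x_tr, y[train_idx])
        p = est.predict(x_te)
        preds[test_idx] = p
        rep = compute_metrics(y[test_idx], p)
        fold_scores.append({"fold": i, **rep.as_row()})
    overall = compute_metrics(y[~np.isnan(preds)], preds[~np.isnan(preds)])
    overall.model = model
    overall.encoding = dataset.encoding
    overall.n_input_visits = dataset.k - 1
    overall.fold_scores = fold_scores
    return overall


def fit_recurrent(
    dataset: WindowedDataset, config: RecurrentNetConfig | None = None, seed: int | None = None
) -> tuple[MetricsReport, RecurrentNetRegressor]:
    """Train the recurrent forecaster under a grouped 60/30/10 protocol.

    The patient-grouped split gives 60% train, 30% validation (early
    stopping) and 10% held-out test; metrics are reported on the test
    split.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    config = config or RecurrentNetConfig()
    if seed is not None:
        config.seed = seed
    config.validate()
    tr, va, te = grouped_train_val_test(dataset.groups, (0.6, 0.3, 0.1), seed=config.seed)
    model = RecurrentNetRegressor(**vars(config))
    model.fit(
        dataset.inputs[tr],
        dataset.targets[tr],
        validation_data=(dataset.inputs[va], dataset.targets[va]),
    )
    pred = model.predict(dataset.inputs[te])
    report = compute_metrics(dataset.targets[te], pred)
    report.model = config.nn_type
    report.encoding = dataset.encoding
    report.n_input_visits = dataset.k - 1
    return report, model


def run_experiment(
    cohort: list[EyeSeries],
    experiments=("va_only",),
    encodings=("resampled", "timesteps"),
    visit_counts=(1, 2, 3),
    models=SHALLOW_MODELS + RECURRENT_MODELS,
    embeddings: dict[str, np.ndarray] | None = None,
    recurrent_config: RecurrentNetConfig | None = None,
    seed: int = 0,
    paper_mode: bool = False,
) -> pd.DataFrame:
    """Full result grid over experiments x models x encodings x window sizes.

    ``embeddings`` maps eye_id to a (n_visits, d) latent block and is
    required for the image experiments. Returns one row per cell with the
    full metric suite. ``paper_mode=True`` splits the augmented windows
    without patient grouping (the source protocol), which leaks
    overlapping windows across splits; the grouped default is stricter.
    """
    from .prep import series_to_frame

    if not cohort:
        raise ValueError("empty cohort")
    needs_emb = [e for e in experiments if e in ("oct_plus_images", "all_features")]
    if needs_emb:
        missing = [s.eye_id for s in cohort if embeddings is None or s.eye_id not in embeddings]
        if missing:
            raise ValueError(
                f"experiments {needs_emb} need embeddings; missing for eyes {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
    frames = []
    for series in cohort:
        frame = series_to_frame(series)
        if embeddings is not None and series.eye_id in embeddings:
            emb = np.asarray(embeddings[series.eye_id], dtype=float)
            for j in range(emb.shape[1]):
                frame[f"emb_{j + 1}"] = emb[:, j]
        frames.append(frame)
    rows = []
    for experiment in experiments:
        for encoding in encodings:
            for k_in in visit_counts:
                dataset = build_windowed_dataset(
                    frames, encoding=encoding, n_input_visits=k_in, experiment=experiment
                )
                if len(dataset) == 0:
                    continue
                if paper_mode:
                    dataset.groups = np.arange(len(dataset)).astype(object)
                for model in models:
                    if model in SHALLOW_MODELS:
                        rep = fit_shallow(dataset, model=model, seed=seed)
                    else:
                        nn_type = "simple" if model == "rnn" else model
                        cfg_src = recurrent_config or RecurrentNetConfig()
                        cfg = RecurrentNetConfig(**{**vars(cfg_src), "nn_type": nn_type, "seed": seed})
                        rep, _ = fit_recurrent(dataset, cfg)
                    row = rep.as_row()
                    row["model"] = model
                    row["experiment"] = experiment
                    rows.append(row)
    grid = pd.DataFrame(rows)
    cols = ["experiment", "model", "encoding", "n_input_visits", "mse", "mae", "rmse", "rmspe", "r2"]
    return grid[cols] if len(grid) else grid
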