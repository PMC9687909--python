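"""Multi-output regression models correcting optical-flow velocities.

Maps the four per-pixel features ``(u_ofm, v_ofm, Ix, Iy)`` to the two
ground-truth velocity components.  Four model families are provided:

* LASSO — L1-penalized linear regression (the interpretable baseline);
* MLP — one ReLU hidden layer (10 units by default, the grid-search
  optimum; 32 available via config), dropout 0.02, Adam;
* CNN — three 1D convolutions over the feature sequence with a max pool
  and a linear regression head;
* LSTM — gated recurrence over the features read as a length-4 sequence,
  ReLU dense layer, linear head.

Features and targets are standardized on training statistics; the
standardization is stored with the model and inverted at prediction, so
all reported errors are in m/s.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso
from sklearn.model_selection import RepeatedKFold

from . import _nn
from .dataset import FEATURE_COLUMNS, TARGET_COLUMNS

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "fit_lasso",
    "fit_mlp",
    "fit_cnn",
    "fit_lstm",
    "fit_model",
    "cross_validate",
    "predict",
    "lstm_cell_step",
    "DEFAULT_EPOCHS",
]

lstm_cell_step = _nn.lstm_cell_step

DEFAULT_EPOCHS = {"mlp": 100, "cnn": 500, "lstm": 500}


@dataclass
class ModelConfig:
    """Hyper-parameters of one regressor."""

    kind: str = "mlp"                 # lasso | mlp | cnn | lstm
    l1_penalty: float = 1e-3          # lasso, on standardized data
    hidden: tuple = (10,)             # mlp layer widths
    lstm_hidden: int = 10
    cnn_channels: tuple = (8, 16, 16)
    dropout: float = 0.02
    batch_size: int = 32
    epochs: int | None = None         # None -> per-kind default
    learning_rate: float = 1e-3
    loss: str = "mae"                 # training loss: mae | mse
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("lasso", "mlp", "cnn", "lstm"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.loss not in ("mae", "mse"):
            raise ValueError("loss must be 'mae' or 'mse'")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs is None:
            self.epochs = DEFAULT_EPOCHS.get(self.kind, 100)
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class _Scaler:
    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray, shared: bool = False) -> "_Scaler":
        """Column standardizer; ``shared=True`` pools one std across columns.

        The shared form is used for the velocity targets: u and v are the
        same physical quantity, and a per-column scale would blow a
        zero-variance component (u is identically zero on the centre
        plane of the substitute flow) up to unit scale in m/s.
        """
        mean = x.mean(axis=0)
        if shared:
            std = np.full(x.shape[1], (x - mean).std())
        else:
            std = x.std(axis=0)
        std = np.where(std < 1e-12, 1.0, std)    # zero-variance guard
        return cls(mean=mean, std=std)

    def transform(self, x):
        return (x - self.mean) / self.std

    def inverse(self, x):
        return x * self.std + self.mean


@dataclass
class TrainedModel:
    """A fitted regressor with its scalers, config and training history."""

    config: ModelConfig
    x_scaler: _Scaler
    y_scaler: _Scaler
    net: object = None                # _nn network (mlp/cnn/lstm)
    coef: np.ndarray | None = None    # lasso
    intercept: np.ndarray | None = None
    history: list = field(default_factory=list)
    cv_scores: pd.DataFrame | None = None

    @property
    def kind(self) -> str:
        return self.config.kind

    def predict(self, features) -> np.ndarray:
        """Predict (u, v) in m/s for rows of 4 features."""
        x = _as_features(features)
        xs = self.x_scaler.transform(x)
        if self.kind == "lasso":
            if self.coef is None:
                raise RuntimeError("model is not fitted")
            ys = xs @ self.coef.T + self.intercept
        else:
            if self.net is None:
                raise RuntimeError("model is not fitted")
            ys = self.net.predict(xs)
        return self.y_scaler.inverse(ys)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path):
        """Self-describing container: npz arrays + embedded JSON config."""
        path = Path(path)
        arrays = {
            "x_mean": self.x_scaler.mean, "x_std": self.x_scaler.std,
            "y_mean": self.y_scaler.mean, "y_std": self.y_scaler.std,
        }
        if self.kind == "lasso":
            arrays["coef"] = self.coef
            arrays["intercept"] = self.intercept
        else:
            for k, v in self.net.params.items():
                arrays[f"param_{k}"] = v
        cfg = asdict(self.config)
        cfg["hidden"] = list(cfg["hidden"])
        cfg["cnn_channels"] = list(cfg["cnn_channels"])
        arrays["config_json"] = np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(Path(path)) as data:
            cfg_dict = json.loads(bytes(data["config_json"].tobytes()).decode())
            cfg_dict["hidden"] = tuple(cfg_dict["hidden"])
            cfg_dict["cnn_channels"] = tuple(cfg_dict["cnn_channels"])
            config = ModelConfig(**cfg_dict)
            model = cls(
                config=config,
                x_scaler=_Scaler(data["x_mean"], data["x_std"]),
                y_scaler=_Scaler(data["y_mean"], data["y_std"]),
            )
            if config.kind == "lasso":
                model.coef = data["coef"]
                model.intercept = data["intercept"]
            else:
                net = _build_net(config)
                for k in net.params:
                    net.params[k] = data[f"param_{k}"]
                model.net = net
        return model


def _as_features(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        x = features[FEATURE_COLUMNS].to_numpy(float)
    else:
        x = np.asarray(features, float)
    if x.ndim != 2 or x.shape[1] != len(FEATURE_COLUMNS):
        raise ValueError(f"expected (n, {len(FEATURE_COLUMNS)}) features, got {x.shape}")
    return x


def _as_xy(table) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(table, pd.DataFrame):
        return (table[FEATURE_COLUMNS].to_numpy(float),
                table[TARGET_COLUMNS].to_numpy(float))
    x, y = table
    return np.asarray(x, float), np.asarray(y, float)


def _build_net(config: ModelConfig):
    if config.kind == "mlp":
        return _nn.MLPNet(hidden=config.hidden, dropout=config.dropout,
                          seed=config.seed)
    if config.kind == "cnn":
        return _nn.ConvNet1D(channels=config.cnn_channels, seed=config.seed)
    if config.kind == "lstm":
        return _nn.LSTMNet(hidden=config.lstm_hidden, seed=config.seed)
    raise ValueError(config.kind)


def fit_model(train, config: ModelConfig,
              subsample: int | None = None) -> TrainedModel:
    """Fit any model kind on a sample table (or an (X, Y) pair).

    ``subsample`` caps the number of training rows for the iterative
    network fits (rows chosen with the config seed); the statistics of
    the standardizers always use the full table.
    """
    x, y = _as_xy(train)
    if x.shape[0] == 0:
        raise ValueError("training table is empty")
    xsc = _Scaler.fit(x)
    ysc = _Scaler.fit(y, shared=True)
    xs, ys = xsc.transform(x), ysc.transform(y)

    model = TrainedModel(config=config, x_scaler=xsc, y_scaler=ysc)
    if config.kind == "lasso":
        las = Lasso(alpha=config.l1_penalty, max_iter=50_000, tol=1e-12)
        las.fit(xs, ys)
        model.coef = np.atleast_2d(las.coef_)
        model.intercept = np.atleast_1d(las.intercept_)
        return model

    if subsample is not None and x.shape[0] > subsample:
        rng = np.random.default_rng(config.seed)
        idx = rng.choice(x.shape[0], subsample, replace=False)
        xs, ys = xs[idx], ys[idx]
    net = _build_net(config)
    _nn.fit_network(net, xs, ys, loss=config.loss, epochs=config.epochs,
                    batch_size=config.batch_size, lr=config.learning_rate,
                    seed=config.seed, history=model.history)
    model.net = net
    return model


def fit_lasso(train, penalty: float = 1e-3, seed: int = 0) -> TrainedModel:
    return fit_model(train, ModelConfig(kind="lasso", l1_penalty=penalty, seed=seed))


def fit_mlp(train, config: ModelConfig | None = None, **kw) -> TrainedModel:
    return fit_model(train, config or ModelConfig(kind="mlp", **kw))


def fit_cnn(train, config: ModelConfig | None = None, **kw) -> TrainedModel:
    return fit_model(train, config or ModelConfig(kind="cnn", **kw))


def fit_lstm(train, config: ModelConfig | None = None, **kw) -> TrainedModel:
    return fit_model(train, config or ModelConfig(kind="lstm", **kw))


def predict(model: TrainedModel, features) -> np.ndarray:
    return model.predict(features)


def cross_validate(config: ModelConfig, table, k: int = 10, repeats: int = 3,
                   seed: int = 0, subsample: int | None = None) -> pd.DataFrame:
    """Repeated k-fold cross-validation (default 10 folds x 3 repeats).

    Each fold's model is fitted on the fold-training rows (optionally
    subsampled for the iterative fits) and scored on the *entire*
    validation fold; returns one row per fold with MAE and MSE in m/s
    over both velocity components.
    """
    x, y = _as_xy(table)
    n = x.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    rkf = RepeatedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    rows = []
    for fold_idx, (tr, va) in enumerate(rkf.split(x)):
        cfg = replace(config, seed=config.seed + fold_idx)
        model = fit_model((x[tr], y[tr]), cfg, subsample=subsample)
        pred = model.predict(x[va])
        err = pred - y[va]
        rows.append({
            "model": config.kind,
            "loss": config.loss,
            "repeat": fold_idx // k,
            "fold": fold_idx % k,
            "mae": float(np.mean(np.abs(err))),
            "mse": float(np.mean(err**2)),
        })
    return pd.DataFrame(rows)


def cv_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of the fold scores per model/loss."""
    return (scores.groupby(["model", "loss"])
            .agg(mae_mean=("mae", "mean"), mae_std=("mae", "std"),
                 mse_mean=("mse", "mean"), mse_std=("mse", "std"))
            .reset_index())
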