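"""RNN-G biomass predictor: stacked LSTM cells over the observation-date
axis, concatenation with a static genotype-cluster feature, and a single
fully connected output layer.

The network is implemented directly in NumPy (forward pass, full
backpropagation through time, Adam), which keeps training deterministic
under a seed and lets the gradients be verified against finite differences
in the test suite.  Training minimises mean squared error on z-scored
targets; features and target are standardised with statistics fitted on the
training split only, and the weight snapshot with the lowest validation
loss is retained.

Evaluation follows the reference-R² convention

    R2_ref = 1 - sum_i (y_i - yhat_i)^2 / sum_i (y_i - ybar)^2

which can be negative for biased predictors, plus RMSE (g/m^2) and a
ranking R2_ref computed on per-hybrid mean biomass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RNNGConfig",
    "LSTMNet",
    "TrainedModel",
    "EvalReport",
    "split_cv",
    "build_model",
    "encode_static",
    "train",
    "predict",
    "r2_ref",
    "rmse",
    "evaluate",
    "fit_cv",
    "save_model",
    "load_model",
]


@dataclass
class RNNGConfig:
    """Architecture and optimisation settings."""

    n_stacked_cells: int = 2
    hidden_size: int = 64
    learning_rate: float = 5e-4
    epochs: int = 1000
    batch_size: int = 64
    static_encoding: str = "one-hot"  # or "integer"
    # scale of the encoded static input; with Adam's per-step displacement
    # capped near the learning rate, an O(1) one-hot would need more
    # optimisation steps than short training budgets provide before the
    # output-layer cluster coefficients reach their targets
    static_gain: float = 8.0
    use_genotype: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_stacked_cells", "hidden_size", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"RNNGConfig.{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("RNNGConfig.learning_rate must be > 0")
        if self.static_encoding not in ("one-hot", "integer"):
            raise ValueError("static_encoding must be 'one-hot' or 'integer'")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTMNet:
    """Stacked-LSTM regression network with a static input branch.

    Parameters per LSTM layer l (input width F_l, hidden width H): input
    weights ``Wx`` (F_l, 4H), recurrent weights ``Wh`` (H, 4H) and bias
    ``b`` (4H,), gate order (input, forget, cell, output) with the forget
    bias initialised to 1.  The top layer's final hidden state is
    concatenated with the static vector and mapped to a scalar by ``Wo``,
    ``bo``.
    """

    def __init__(self, n_features: int, n_timesteps: int, static_dim: int,
                 config: RNNGConfig):
        if n_timesteps < 2:
            raise ValueError("the model needs at least 2 timesteps")
        self.n_features = n_features
        self.n_timesteps = n_timesteps
        self.static_dim = static_dim
        self.config = config
        H = config.hidden_size
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        f_in = n_features
        for l in range(config.n_stacked_cells):
            s = np.sqrt(6.0 / (f_in + 4 * H))
            self.params[f"Wx{l}"] = rng.uniform(-s, s, size=(f_in, 4 * H))
            # orthogonal recurrent init
            a = rng.normal(size=(H, 4 * H))
            q, _ = np.linalg.qr(a.T)
            self.params[f"Wh{l}"] = q.T[:H, :]
            b = np.zeros(4 * H)
            b[H:2 * H] = 1.0  # forget gate
            self.params[f"b{l}"] = b
            f_in = H
        # zero-initialised output layer: epoch-0 predictions equal the
        # (scaled) target mean, so neither branch starts with a spurious
        # offset the optimiser must first unlearn
        self.params["Wo"] = np.zeros(H + static_dim)
        self.params["bo"] = np.zeros(1)

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def forward(self, x: np.ndarray, static: np.ndarray,
                keep_cache: bool = False) -> np.ndarray:
        """x: (B, T, F); static: (B, C). Returns (B,) predictions."""
        B, T, F = x.shape
        H = self.config.hidden_size
        cache = {"x": x, "static": static, "layers": []}
        inp = x
        for l in range(self.config.n_stacked_cells):
            Wx, Wh, b = (self.params[f"Wx{l}"], self.params[f"Wh{l}"],
                         self.params[f"b{l}"])
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            hs = np.empty((B, T, H))
            steps = []
            for t in range(T):
                z = inp[:, t, :] @ Wx + h @ Wh + b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = _sigmoid(z[:, 3 * H:])
                c_new = f * c + i * g
                h_new = o * np.tanh(c_new)
                if keep_cache:
                    steps.append((inp[:, t, :], h, c, i, f, g, o, c_new))
                h, c = h_new, c_new
                hs[:, t, :] = h
            cache["layers"].append(steps)
            inp = hs
        u = np.concatenate([inp[:, -1, :], static], axis=1)
        yhat = u @ self.params["Wo"] + self.params["bo"][0]
        if keep_cache:
            cache["u"] = u
            self._cache = cache
        return yhat

    def backward(self, dy: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. all parameters, given dL/dyhat."""
        cache = self._cache
        H = self.config.hidden_size
        L = self.config.n_stacked_cells
        B, T, _ = cache["x"].shape
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        u = cache["u"]
        grads["Wo"] = u.T @ dy
        grads["bo"] = np.array([dy.sum()])
        du = np.outer(dy, self.params["Wo"])
        # gradient w.r.t. each layer's output sequence
        dH_seq = np.zeros((B, T, H))
        dH_seq[:, -1, :] = du[:, :H]
        for l in range(L - 1, -1, -1):
            Wx, Wh = self.params[f"Wx{l}"], self.params[f"Wh{l}"]
            steps = cache["layers"][l]
            f_in = Wx.shape[0]
            dX_seq = np.zeros((B, T, f_in))
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                x_t, h_prev, c_prev, i, f, g, o, c_t = steps[t]
                dh = dH_seq[:, t, :] + dh_next
                tc = np.tanh(c_t)
                do = dh * tc
                dc = dh * o * (1 - tc ** 2) + dc_next
                di = dc * g
                dg = dc * i
                df = dc * c_prev
                dc_next = dc * f
                dz = np.concatenate([
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g ** 2),
                    do * o * (1 - o),
                ], axis=1)
                grads[f"Wx{l}"] += x_t.T @ dz
                grads[f"Wh{l}"] += h_prev.T @ dz
                grads[f"b{l}"] += dz.sum(axis=0)
                dX_seq[:, t, :] = dz @ Wx.T
                dh_next = dz @ Wh.T
            dH_seq = dX_seq  # becomes the output-gradient of the layer below
        return grads

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}


def build_model(config: RNNGConfig, n_features: int, n_timesteps: int,
                n_clusters: int) -> LSTMNet:
    """Untrained RNN-G network.

    ``n_clusters == 0`` is only valid for the no-genotype model variant
    (``config.use_genotype = False``), the genotype-blind baseline.
    """
    if config.use_genotype and n_clusters < 1:
        raise ValueError("n_clusters < 1 requires use_genotype=False "
                         "(the no-genotype model variant)")
    static_dim = 0
    if config.use_genotype:
        static_dim = n_clusters if config.static_encoding == "one-hot" else 1
    return LSTMNet(n_features, n_timesteps, static_dim, config)


def encode_static(cluster_of_plot: pd.Series, n_clusters: int,
                  config: RNNGConfig) -> np.ndarray:
    """Static input matrix (plots x C) from per-plot cluster IDs (1..k)."""
    if not config.use_genotype:
        return np.zeros((len(cluster_of_plot), 0))
    ids = cluster_of_plot.to_numpy(dtype=int)
    if config.static_encoding == "integer":
        return ids[:, None].astype(float)
    out = np.zeros((len(ids), n_clusters))
    out[np.arange(len(ids)), ids - 1] = config.static_gain
    return out


# ---------------------------------------------------------------------------
# cross-validation protocol
# ---------------------------------------------------------------------------

def split_cv(records: pd.DataFrame, seed: int = 0,
             val_fraction: float = 0.1) -> list[dict[str, list[str]]]:
    """Three folds: disjoint test thirds covering all plots; the remainder
    of each fold split 90/10 into train/validation."""
    plots = records["plot_id"].tolist()
    if len(plots) < 10:
        raise ValueError("need at least 10 plots for the 3-fold protocol")
    rng = np.random.default_rng(seed)
    order = list(np.array(plots)[rng.permutation(len(plots))])
    bounds = [round(i * len(order) / 3) for i in range(4)]
    thirds = [order[bounds[i]:bounds[i + 1]] for i in range(3)]
    folds = []
    for i in range(3):
        test = thirds[i]
        rest = [p for j, t in enumerate(thirds) if j != i for p in t]
        rest = list(np.array(rest)[rng.permutation(len(rest))])
        n_val = max(1, round(val_fraction * len(rest)))
        if n_val >= len(rest):
            raise ValueError("too few plots to form a non-empty train split")
        folds.append({"train": rest[n_val:], "val": rest[:n_val],
                      "test": list(test)})
    return folds


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """Weights plus everything needed to reproduce and validate predictions."""

    params: dict[str, np.ndarray]
    config: RNNGConfig
    fingerprint: dict
    norm: dict                      # x_mean/x_std (F,), y_mean/y_std
    history: dict                   # per-epoch train/val loss
    best_epoch: int
    n_params: int


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _fingerprint(feature_names, n_timesteps, n_clusters, config) -> dict:
    return {"feature_names": list(feature_names),
            "n_timesteps": int(n_timesteps),
            "n_clusters": int(n_clusters),
            "static_encoding": config.static_encoding,
            "use_genotype": bool(config.use_genotype),
            "hidden_size": config.hidden_size,
            "n_stacked_cells": config.n_stacked_cells}


def _check_fingerprint(fp: dict, tensor, static: np.ndarray,
                       config: RNNGConfig) -> None:
    if fp["feature_names"] != list(tensor.feature_names):
        raise ValueError("fingerprint mismatch: feature_names")
    if fp["n_timesteps"] != tensor.values.shape[2]:
        raise ValueError("fingerprint mismatch: n_timesteps")
    exp_dim = 0
    if fp["use_genotype"]:
        exp_dim = fp["n_clusters"] if fp["static_encoding"] == "one-hot" else 1
    if static.shape[1] != exp_dim:
        raise ValueError("fingerprint mismatch: n_clusters/static encoding")


def train(model: LSTMNet, tensor, static: np.ndarray, biomass: pd.Series,
          split: dict[str, list[str]], config: RNNGConfig,
          n_clusters: int | None = None,
          initial_params: dict[str, np.ndarray] | None = None,
          freeze: tuple[str, ...] = ()) -> TrainedModel:
    """Fit the network by Adam on MSE; retain the best-validation weights.

    Features and the biomass target are z-scored with statistics computed
    on the training split only.  ``initial_params`` warm-starts the weights
    (used by fine-tuning); parameter names in ``freeze`` are not updated.
    """
    if set(split["train"]) & set(split["val"]) or \
       set(split["train"]) & set(split.get("test", [])) or \
       set(split["val"]) & set(split.get("test", [])):
        raise ValueError("train/val/test splits must be disjoint")
    pos = {p: i for i, p in enumerate(tensor.plot_ids)}
    tr = [pos[p] for p in split["train"]]
    va = [pos[p] for p in split["val"]]
    X = np.transpose(tensor.values, (0, 2, 1))  # (P, T, F)
    y = biomass.loc[tensor.plot_ids].to_numpy(dtype=float)

    x_mean = X[tr].reshape(-1, X.shape[2]).mean(axis=0)
    x_std = X[tr].reshape(-1, X.shape[2]).std(axis=0)
    x_std[x_std == 0] = 1.0
    y_mean = float(y[tr].mean())
    y_std = float(y[tr].std()) or 1.0
    Xn = (X - x_mean) / x_std
    yn = (y - y_mean) / y_std

    if initial_params is not None:
        model.set_params(initial_params)
    opt = _Adam(model.params, config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    hist_train, hist_val = [], []
    best_val, best_params, best_epoch = np.inf, model.copy_params(), 0

    Xtr, ytr = Xn[tr], yn[tr]
    Xva, yva = Xn[va], yn[va]
    st_tr, st_va = static[tr], static[va]
    n = len(tr)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        ep_loss = 0.0
        for s in range(0, n, config.batch_size):
            idx = perm[s:s + config.batch_size]
            xb, yb, sb = Xtr[idx], ytr[idx], st_tr[idx]
            pred = model.forward(xb, sb, keep_cache=True)
            err = pred - yb
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"lr={config.learning_rate}, "
                    f"|x| max={np.abs(xb).max():.3g}, |y| max={np.abs(yb).max():.3g}")
            ep_loss += loss * len(idx)
            grads = model.backward(2.0 * err / len(idx))
            for k in freeze:
                grads[k] = np.zeros_like(grads[k])
            opt.step(model.params, grads)
        hist_train.append(ep_loss / n)
        val_pred = model.forward(Xva, st_va)
        val_loss = float(np.mean((val_pred - yva) ** 2))
        hist_val.append(val_loss)
        if val_loss < best_val:
            best_val, best_params, best_epoch = val_loss, model.copy_params(), epoch
    model.set_params(best_params)

    n_clusters = n_clusters if n_clusters is not None else model.static_dim
    return TrainedModel(
        params=model.copy_params(),
        config=config,
        fingerprint=_fingerprint(tensor.feature_names, X.shape[1],
                                 n_clusters, config),
        norm={"x_mean": x_mean, "x_std": x_std,
              "y_mean": y_mean, "y_std": y_std},
        history={"train": hist_train, "val": hist_val},
        best_epoch=best_epoch,
        n_params=model.n_params,
    )


def _net_from(trained: TrainedModel) -> LSTMNet:
    fp = trained.fingerprint
    net = build_model(trained.config, len(fp["feature_names"]),
                      fp["n_timesteps"], fp["n_clusters"])
    net.set_params(trained.params)
    return net


def predict(trained: TrainedModel, tensor, static: np.ndarray) -> np.ndarray:
    """Per-plot biomass predictions (g/m^2) on the original scale."""
    _check_fingerprint(trained.fingerprint, tensor, static, trained.config)
    X = np.transpose(tensor.values, (0, 2, 1))
    Xn = (X - trained.norm["x_mean"]) / trained.norm["x_std"]
    net = _net_from(trained)
    yhat = net.forward(Xn, static)
    return yhat * trained.norm["y_std"] + trained.norm["y_mean"]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def r2_ref(y, yhat) -> float | None:
    """Reference R2 = 1 - SS_res / SS_tot; ``None`` when y is constant
    (zero denominator, the metric is undefined)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("y and yhat must be equal-length vectors (>= 2)")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return None
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def rmse(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass
class EvalReport:
    """Prediction and ranking metrics over a set of evaluation plots."""

    predictions: pd.DataFrame       # plot_id, hybrid_id, y, yhat
    r2_prediction: float | None
    rmse_prediction: float
    r2_ranking: float | None
    fold: str = ""
    excluded_hybrids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"r2_prediction": self.r2_prediction,
                "rmse_prediction": self.rmse_prediction,
                "r2_ranking": self.r2_ranking, "fold": self.fold,
                "n_plots": int(len(self.predictions))}


def evaluate(trained: TrainedModel, tensor, static: np.ndarray,
             biomass: pd.Series, hybrid_of: pd.Series,
             fold: str = "") -> EvalReport:
    """Evaluate on every plot of ``tensor``: plot-level R2_ref/RMSE and
    ranking R2_ref on per-hybrid mean biomass."""
    yhat = predict(trained, tensor, static)
    y = biomass.loc[tensor.plot_ids].to_numpy(dtype=float)
    hyb = hybrid_of.loc[tensor.plot_ids]
    df = pd.DataFrame({"plot_id": tensor.plot_ids, "hybrid_id": hyb.values,
                       "y": y, "yhat": yhat})
    means = df.groupby("hybrid_id")[["y", "yhat"]].mean()
    rank_r2 = r2_ref(means["y"], means["yhat"]) if len(means) >= 2 else None
    return EvalReport(df, r2_ref(y, yhat), rmse(y, yhat), rank_r2, fold)


def fit_cv(tensor, static: np.ndarray, biomass: pd.Series,
           records: pd.DataFrame, config: RNNGConfig, n_clusters: int,
           seed: int = 0) -> tuple[EvalReport, list[TrainedModel]]:
    """Run the 3-fold protocol; metrics are computed on the pooled test
    predictions of the three folds."""
    hybrid_of = records.set_index("plot_id")["hybrid_id"]
    folds = split_cv(records, seed)
    models, parts = [], []
    for i, split in enumerate(folds):
        net = build_model(config, tensor.n_features, tensor.values.shape[2],
                          n_clusters)
        trained = train(net, tensor, static, biomass, split, config,
                        n_clusters=n_clusters)
        models.append(trained)
        t_test = tensor.subset_plots(split["test"])
        pos = {p: j for j, p in enumerate(tensor.plot_ids)}
        st = static[[pos[p] for p in split["test"]]]
        rep = evaluate(trained, t_test, st, biomass, hybrid_of, fold=f"fold{i}")
        parts.append(rep.predictions)
    pooled = pd.concat(parts, ignore_index=True)
    means = pooled.groupby("hybrid_id")[["y", "yhat"]].mean()
    report = EvalReport(pooled, r2_ref(pooled["y"], pooled["yhat"]),
                        rmse(pooled["y"], pooled["yhat"]),
                        r2_ref(means["y"], means["yhat"]), fold="pooled")
    return report, models


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(trained: TrainedModel, path: str | Path) -> None:
    """Single-archive serialization: weight arrays + JSON metadata."""
    meta = {"config": asdict(trained.config),
            "fingerprint": trained.fingerprint,
            "norm": {"x_mean": trained.norm["x_mean"].tolist(),
                     "x_std": trained.norm["x_std"].tolist(),
                     "y_mean": trained.norm["y_mean"],
                     "y_std": trained.norm["y_std"]},
            "history": trained.history,
            "best_epoch": trained.best_epoch,
            "n_params": trained.n_params}
    np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **trained.params)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        params = {k: data[k].copy() for k in data.files if k != "_meta"}
    norm = {"x_mean": np.array(meta["norm"]["x_mean"]),
            "x_std": np.array(meta["norm"]["x_std"]),
            "y_mean": meta["norm"]["y_mean"], "y_std": meta["norm"]["y_std"]}
    return TrainedModel(params, RNNGConfig(**meta["config"]),
                        meta["fingerprint"], norm, meta["history"],
                        meta["best_epoch"], meta["n_params"])
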