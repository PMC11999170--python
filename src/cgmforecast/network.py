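"""Two-layer stacked LSTM forecaster, implemented directly in NumPy.

The network mirrors the standard small-footprint CGM forecasting
architecture: an LSTM layer of 32 units (ReLU activations), a dropout
layer (rate 0.2), a second LSTM layer of 16 units, and a dense head with
one output unit per future step (6 for a 30-minute horizon, 12 for 60).
Training minimizes the MSE over all output steps with Adam, warm-startable
from an existing parameter set (the basis of parameter transfer between
retraining stages), with early stopping on validation MSE.

Forward pass, backpropagation through time and the optimizer are written
here explicitly; gradients are validated against finite differences in the
test suite.  Parameters are float64 and serialize bit-exactly.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class ArchitectureSpec:
    history_steps: int = 24
    input_channels: int = 1
    layer1_units: int = 32
    layer2_units: int = 16
    output_units: int = 6  # 6 -> 30-min horizon, 12 -> 60-min
    dropout_rate: float = 0.2
    activation: str = "relu"

    def __post_init__(self):
        if min(self.history_steps, self.input_channels,
               self.layer1_units, self.layer2_units, self.output_units) < 1:
            raise ValueError("all architecture dimensions must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unsupported activation {self.activation!r}")


@dataclass
class TrainConfig:
    max_epochs: int = 50
    patience: int = 5
    batch_size: int = 64
    learning_rate: float = 1e-3
    clip_norm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class Normalization:
    """Per-channel min-max scaling to [0, 1], fit on training data only."""

    mins: np.ndarray
    maxs: np.ndarray

    @staticmethod
    def fit(X: np.ndarray, y: np.ndarray) -> "Normalization":
        mins = X.min(axis=(0, 1)).astype(float)
        maxs = X.max(axis=(0, 1)).astype(float)
        # targets are glucose: widen channel 0's range to cover them
        mins[0] = min(mins[0], float(y.min()))
        maxs[0] = max(maxs[0], float(y.max()))
        span = maxs - mins
        maxs[span <= 0] = mins[span <= 0] + 1.0  # guard flat channels
        return Normalization(mins, maxs)

    def transform_X(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mins) / (self.maxs - self.mins)

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (y - self.mins[0]) / (self.maxs[0] - self.mins[0])

    def inverse_y(self, y: np.ndarray) -> np.ndarray:
        return y * (self.maxs[0] - self.mins[0]) + self.mins[0]


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _act(z, kind):
    return np.maximum(z, 0.0) if kind == "relu" else np.tanh(z)


def _act_grad(z, kind):
    return (z > 0).astype(float) if kind == "relu" else 1.0 - np.tanh(z) ** 2


def _glorot(rng, fan_in, fan_out, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class ForecastModel:
    """Architecture + parameters + normalization statistics.

    Parameter layout per LSTM layer ``l``: ``W{l}`` (input, 4H), ``U{l}``
    (H, 4H), ``b{l}`` (4H,) with gate order (input, forget, candidate,
    output); dense head ``Wd`` (H2, h), ``bd`` (h,).
    """

    def __init__(self, spec: ArchitectureSpec, params: dict[str, np.ndarray],
                 norm: Normalization | None = None, training_meta: dict | None = None):
        self.spec = spec
        self.params = params
        self.norm = norm
        self.training_meta = training_meta or {}

    # -- construction ------------------------------------------------------
    @staticmethod
    def build(spec: ArchitectureSpec, seed: int = 0) -> "ForecastModel":
        """Fresh Glorot-initialized model; same (spec, seed) => same params."""
        rng = np.random.default_rng(seed)
        C, H1, H2, h = (spec.input_channels, spec.layer1_units,
                        spec.layer2_units, spec.output_units)
        params = {}
        for name, din, hid in (("1", C, H1), ("2", H1, H2)):
            params[f"W{name}"] = _glorot(rng, din, hid, (din, 4 * hid))
            params[f"U{name}"] = _glorot(rng, hid, hid, (hid, 4 * hid))
            b = np.zeros(4 * hid)
            b[hid:2 * hid] = 1.0  # forget-gate bias
            params[f"b{name}"] = b
        params["Wd"] = _glorot(rng, H2, h, (H2, h))
        params["bd"] = np.zeros(h)
        return ForecastModel(spec, params)

    def copy(self) -> "ForecastModel":
        return ForecastModel(
            self.spec,
            {k: v.copy() for k, v in self.params.items()},
            Normalization(self.norm.mins.copy(), self.norm.maxs.copy()) if self.norm else None,
            dict(self.training_meta),
        )

    def params_equal(self, other: "ForecastModel") -> bool:
        return all(np.array_equal(self.params[k], other.params[k]) for k in self.params)

    # -- forward / backward ------------------------------------------------
    def _lstm_forward(self, x, layer, cache=None):
        spec = self.spec
        W = self.params[f"W{layer}"]
        U = self.params[f"U{layer}"]
        b = self.params[f"b{layer}"]
        B, T, _ = x.shape
        H = U.shape[0]
        pre_x = x @ W  # (B, T, 4H)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.zeros((B, T, H))
        if cache is not None:
            cache.update(x=x, W=W, U=U, steps=[])
        for t in range(T):
            pre = pre_x[:, t] + h @ U + b
            i = _sigmoid(pre[:, :H])
            f = _sigmoid(pre[:, H:2 * H])
            g_pre = pre[:, 2 * H:3 * H]
            g = _act(g_pre, spec.activation)
            o = _sigmoid(pre[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            hc = _act(c, spec.activation)
            h_prev = h
            h = o * hc
            hs[:, t] = h
            if cache is not None:
                cache["steps"].append(
                    dict(i=i, f=f, g=g, g_pre=g_pre, o=o, c=c, c_prev=c_prev,
                         hc=hc, h_prev=h_prev)
                )
        return hs

    def _lstm_backward(self, cache, dH_seq):
        spec = self.spec
        x, W, U = cache["x"], cache["W"], cache["U"]
        steps = cache["steps"]
        B, T, _ = x.shape
        H = U.shape[0]
        dpre_all = np.zeros((B, T, 4 * H))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            st = steps[t]
            dh = dH_seq[:, t] + dh_next
            do = dh * st["hc"]
            dc = dc_next + dh * st["o"] * _act_grad(st["c"], spec.activation)
            di = dc * st["g"]
            df = dc * st["c_prev"]
            dg = dc * st["i"]
            dpre = np.concatenate(
                [
                    di * st["i"] * (1 - st["i"]),
                    df * st["f"] * (1 - st["f"]),
                    dg * _act_grad(st["g_pre"], spec.activation),
                    do * st["o"] * (1 - st["o"]),
                ],
                axis=1,
            )
            dpre_all[:, t] = dpre
            dh_next = dpre @ U.T
            dc_next = dc * st["f"]
        H_prev = np.stack([s["h_prev"] for s in steps], axis=1)  # (B,T,H)
        grads = {
            "W": np.einsum("btd,bth->dh", x, dpre_all),
            "U": np.einsum("bth,btk->hk", H_prev, dpre_all),
            "b": dpre_all.sum(axis=(0, 1)),
        }
        dx = dpre_all @ W.T
        return grads, dx

    def _forward(self, Xn, training=False, rng=None, caches=None):
        """Normalized input (B,T,C) -> normalized prediction (B,h)."""
        h1 = self._lstm_forward(Xn, "1", None if caches is None else caches.setdefault("l1", {}))
        p = self.spec.dropout_rate
        if training and p > 0:
            mask = (rng.random(h1.shape) >= p) / (1.0 - p)
            h1 = h1 * mask
            if caches is not None:
                caches["dropout_mask"] = mask
        elif caches is not None:
            caches["dropout_mask"] = None
        h2 = self._lstm_forward(h1, "2", None if caches is None else caches.setdefault("l2", {}))
        last = h2[:, -1]
        if caches is not None:
            caches["last_h2"] = last
        return last @ self.params["Wd"] + self.params["bd"]

    def _gradients(self, Xn, yn, rng):
        """MSE loss and parameter gradients for one (normalized) batch."""
        caches = {}
        pred = self._forward(Xn, training=True, rng=rng, caches=caches)
        B, h = pred.shape
        err = pred - yn
        loss = float(np.mean(err ** 2))
        dpred = 2.0 * err / (B * h)

        grads = {
            "Wd": caches["last_h2"].T @ dpred,
            "bd": dpred.sum(axis=0),
        }
        dh2_last = dpred @ self.params["Wd"].T
        T = Xn.shape[1]
        dH2 = np.zeros((B, T, self.spec.layer2_units))
        dH2[:, -1] = dh2_last
        g2, dH1 = self._lstm_backward(caches["l2"], dH2)
        if caches["dropout_mask"] is not None:
            dH1 = dH1 * caches["dropout_mask"]
        g1, _ = self._lstm_backward(caches["l1"], dH1)
        grads.update({"W2": g2["W"], "U2": g2["U"], "b2": g2["b"],
                      "W1": g1["W"], "U1": g1["U"], "b1": g1["b"]})
        return loss, grads

    # -- public API ---------------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        """Forecast in mg/dL from raw histories (n, 24, C) or (24, C)."""
        single = X.ndim == 2
        X = X[None] if single else X
        if X.shape[1] != self.spec.history_steps or X.shape[2] != self.spec.input_channels:
            raise ValueError(
                f"history shape {X.shape[1:]} does not match spec "
                f"({self.spec.history_steps}, {self.spec.input_channels})"
            )
        Xn = self.norm.transform_X(X) if self.norm is not None else X
        out = self._forward(Xn, training=False)
        if self.norm is not None:
            out = self.norm.inverse_y(out)
        return out[0] if single else out

    def mse(self, X: np.ndarray, y: np.ndarray) -> float:
        """Validation criterion: MSE over all output steps, mg^2/dL^2."""
        pred = self.predict(X)
        return float(np.mean((pred - y) ** 2))

    # -- serialization -------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "format_version": 1,
            "spec": asdict(self.spec),
            "training_meta": self.training_meta,
            "has_norm": self.norm is not None,
        }
        arrays = dict(self.params)
        if self.norm is not None:
            arrays["_norm_mins"] = self.norm.mins
            arrays["_norm_maxs"] = self.norm.maxs
        arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @staticmethod
    def load(path) -> "ForecastModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            spec = ArchitectureSpec(**meta["spec"])
            params = {k: data[k].copy() for k in data.files
                      if not k.startswith("_")}
            norm = None
            if meta["has_norm"]:
                norm = Normalization(data["_norm_mins"].copy(), data["_norm_maxs"].copy())
        return ForecastModel(spec, params, norm, meta["training_meta"])


class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without val-MSE improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.bad = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record an epoch's validation loss; return True to stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.bad = 0
            return False
        self.bad += 1
        return self.bad >= self.patience


def train_on_subset(
    model: ForecastModel,
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    config: TrainConfig | None = None,
    refit_norm: bool = True,
) -> tuple[ForecastModel, int, list[float]]:
    """Train (warm-start) on one subset with Adam and early stopping.

    Continues from ``model``'s current parameters; normalization statistics
    are refit on this subset's training windows (so each retraining stage
    scales by its own data).  Validation MSE is computed in mg/dL units on
    raw validation windows each epoch; the parameters from the best
    validation epoch are returned.  Returns (model, epochs_run, val_history).
    """
    config = config or TrainConfig()
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    if val_X.shape[0] == 0:
        raise ValueError("empty validation set: early stopping undefined")

    model = model.copy()
    if refit_norm or model.norm is None:
        model.norm = Normalization.fit(train_X, train_y)
    Xn = model.norm.transform_X(train_X)
    yn = model.norm.transform_y(train_y)

    rng = np.random.default_rng(config.seed)
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    stopper = EarlyStopper(config.patience)
    best_params = {k: p.copy() for k, p in model.params.items()}
    val_history: list[float] = []
    n = Xn.shape[0]
    epochs_run = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            _, grads = model._gradients(Xn[idx], yn[idx], rng)
            gnorm = np.sqrt(sum(float(np.sum(g ** 2)) for g in grads.values()))
            if config.clip_norm and gnorm > config.clip_norm:
                scale = config.clip_norm / gnorm
                grads = {k: g * scale for k, g in grads.items()}
            step += 1
            for k, g in grads.items():
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g ** 2
                mhat = m[k] / (1 - beta1 ** step)
                vhat = v[k] / (1 - beta2 ** step)
                model.params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        epochs_run = epoch + 1
        val_loss = model.mse(val_X, val_y)
        val_history.append(val_loss)
        if val_loss < stopper.best:
            best_params = {k: p.copy() for k, p in model.params.items()}
        if stopper.update(epoch, val_loss):
            break

    model.params = best_params
    model.training_meta = {
        "epochs_run": epochs_run,
        "best_epoch": stopper.best_epoch,
        "final_val_mse": stopper.best if np.isfinite(stopper.best) else None,
    }
    return model, epochs_run, val_history


def build_model(spec: ArchitectureSpec, seed: int = 0) -> ForecastModel:
    """Functional alias for :meth:`ForecastModel.build`."""
    return ForecastModel.build(spec, seed)


def last_value_baseline(X: np.ndarray, h: int) -> np.ndarray:
    """Naive last-value-carried-forward forecast, the floor any model must beat."""
    return np.repeat(X[:, -1, 0][:, None], h, axis=1)
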