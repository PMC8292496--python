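"""The day-5 PT INR predictor: dense static branch + stacked-LSTM series branch.

Architecture: the five static covariates (sex, age, weight, height, BSA)
pass through a small stack of ReLU dense layers; the 4-day (INR, dose)
series passes through a stack of LSTM layers (all but the last return full
sequences, the last returns its final hidden state); the branch outputs
are concatenated and fed to a ReLU dense head ending in one linear unit,
the predicted standardized 5th-day INR. Training minimizes mean absolute
error with Adam, holds out a seeded random 20% of samples for validation,
and stops when validation loss has not improved for a patience window,
restoring the best-validation weights.

The forward and backward passes are implemented directly in numpy in
float64: the model is small (tens of thousands of parameters, sequence
length four) and an explicit implementation keeps training bit-reproducible
for a given seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from inrcast.preprocess import Standardizer, fit_standardizer

N_STATIC = 5
SERIES_STEPS = 4
SERIES_CHANNELS = 2


@dataclass
class NetworkConfig:
    """Architecture and training hyperparameters.

    Defaults follow the published architecture search: 5 stacked LSTM
    layers of 32 units (more layers/units overfit), static branch capped
    at 16 nodes, a 4-layer 32-node dense head, ReLU activations, MAE loss,
    Adam, and a 20% validation split for early stopping.
    """

    static_branch: list = field(default_factory=lambda: [16, 16])
    recurrent_layers: int = 5
    recurrent_units: int = 32
    head_layers: int = 4
    head_units: int = 32
    activation: str = "relu"
    loss: str = "mae"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    validation_fraction: float = 0.20
    batch_size: int = 64
    max_epochs: int = 200
    early_stop_patience: int = 10
    output_units: int = 1
    seed: int = 0

    def validate(self):
        if self.recurrent_layers < 1:
            raise ValueError("recurrent_layers must be >= 1")
        if self.recurrent_units < 1 or self.head_units < 1:
            raise ValueError("layer widths must be positive")
        if self.head_layers < 0:
            raise ValueError("head_layers must be >= 0")
        if not self.static_branch or any(w < 1 for w in self.static_branch):
            raise ValueError("static_branch widths must be positive")
        if self.output_units != 1:
            raise ValueError("the head must emit exactly 1 value")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.activation != "relu":
            raise ValueError("only ReLU activations are supported")
        if self.loss != "mae":
            raise ValueError("only MAE loss is supported")
        if self.optimizer != "adam":
            raise ValueError("only Adam is supported")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d).validate()


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng, n_in, n_out):
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class _Dense:
    """Fully connected layer, ReLU or linear."""

    def __init__(self, rng, n_in, n_out, activation="relu"):
        self.W = _glorot(rng, n_in, n_out)
        self.b = np.zeros(n_out)
        self.activation = activation
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        return z

    def backward(self, dh):
        if self.activation == "relu":
            dh = np.where(self._mask, dh, 0.0)
        self.dW += self._x.T @ dh
        self.db += dh.sum(axis=0)
        return dh @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class _LSTM:
    """Single LSTM layer over a (batch, steps, features) input.

    Gate order in the fused weight matrices is input, forget, cell, output;
    the forget-gate bias is initialized to 1 (standard practice, keeps
    early gradients flowing). ``return_sequences`` controls whether the
    full hidden sequence or only the final state is emitted.
    """

    def __init__(self, rng, n_in, units, return_sequences=True):
        self.units = units
        self.W = _glorot(rng, n_in, 4 * units)
        self.U = _glorot(rng, units, 4 * units)
        self.b = np.zeros(4 * units)
        self.b[units:2 * units] = 1.0
        self.return_sequences = return_sequences
        self.dW = np.zeros_like(self.W)
        self.dU = np.zeros_like(self.U)
        self.db = np.zeros_like(self.b)

    def forward(self, X):
        B, T, _ = X.shape
        H = self.units
        xW = X.reshape(B * T, -1) @ self.W
        xW = xW.reshape(B, T, 4 * H)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        self._X = X
        hs = np.empty((B, T, H))
        for t in range(T):
            z = xW[:, t] + h @ self.U + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            self._cache.append((h_prev, c_prev, i, f, g, o, tc))
        return hs if self.return_sequences else h

    def backward(self, dout):
        X = self._X
        B, T, _ = X.shape
        H = self.units
        dX = np.zeros_like(X)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            if self.return_sequences:
                dh = dout[:, t] + dh_next
            else:
                dh = (dout if t == T - 1 else 0.0) + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.dW += X[:, t].T @ dz
            self.dU += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dX[:, t] = dz @ self.W.T
            dh_next = dz @ self.U.T
        return dX

    def params(self):
        return [self.W, self.U, self.b]

    def grads(self):
        return [self.dW, self.dU, self.db]


class InrNet:
    """The two-branch network; see the module docstring for the layout."""

    def __init__(self, config: NetworkConfig, seed: int | None = None):
        config.validate()
        self.config = config
        self.seed = config.seed if seed is None else seed
        rng = np.random.default_rng(self.seed)
        self.static_layers = []
        n_in = N_STATIC
        for w in config.static_branch:
            self.static_layers.append(_Dense(rng, n_in, w, "relu"))
            n_in = w
        static_out = n_in
        self.lstm_layers = []
        n_in = SERIES_CHANNELS
        for li in range(config.recurrent_layers):
            last = li == config.recurrent_layers - 1
            self.lstm_layers.append(
                _LSTM(rng, n_in, config.recurrent_units, return_sequences=not last))
            n_in = config.recurrent_units
        self.head_layers = []
        n_in = static_out + config.recurrent_units
        for _ in range(config.head_layers):
            self.head_layers.append(_Dense(rng, n_in, config.head_units, "relu"))
            n_in = config.head_units
        self.out_layer = _Dense(rng, n_in, 1, "linear")
        self._static_out = static_out

    # -- forward / backward ------------------------------------------------
    def forward(self, xs, xq):
        """xs: (B, 5) standardized statics; xq: (B, 4, 2) standardized series."""
        s = xs
        for layer in self.static_layers:
            s = layer.forward(s)
        h = xq
        for layer in self.lstm_layers:
            h = layer.forward(h)
        z = np.concatenate([s, h], axis=1)
        for layer in self.head_layers:
            z = layer.forward(z)
        return self.out_layer.forward(z)[:, 0]

    def backward(self, dy):
        dz = self.out_layer.backward(dy[:, None])
        for layer in reversed(self.head_layers):
            dz = layer.backward(dz)
        ds = dz[:, : self._static_out]
        dh = dz[:, self._static_out:]
        for layer in reversed(self.lstm_layers):
            dh = layer.backward(dh)
        for layer in reversed(self.static_layers):
            ds = layer.backward(ds)
        return ds, dh

    # -- parameter plumbing ------------------------------------------------
    def _layers(self):
        return (
            self.static_layers + self.lstm_layers + self.head_layers
            + [self.out_layer]
        )

    def params(self):
        return [p for layer in self._layers() for p in layer.params()]

    def grads(self):
        return [g for layer in self._layers() for g in layer.grads()]

    def zero_grads(self):
        for g in self.grads():
            g[...] = 0.0

    def get_weights(self):
        return [p.copy() for p in self.params()]

    def set_weights(self, weights):
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError("weight shapes do not match architecture")
            p[...] = w

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))


def build_network(config: NetworkConfig, seed: int | None = None) -> InrNet:
    """Construct an untrained network; identical seeds give identical weights."""
    return InrNet(config, seed=seed)


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1.0 - self.b1) * g
            v[...] = self.b2 * v + (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _config_hash(config: NetworkConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class TrainedPredictor:
    """A fitted network bundled with the standardizer it was fitted with.

    This is the only object that crosses from training to inference: all
    predictions go through :meth:`predict_day5`, which standardizes inputs
    with the stored training statistics and returns values on the INR
    scale.
    """

    model: InrNet
    standardizer: Standardizer
    config: NetworkConfig
    history: pd.DataFrame
    seed: int

    def predict_day5(self, static, series):
        """Predict the 5th-day PT INR.

        ``static``: (5,) or (n, 5) raw values ordered sex, age, weight,
        height, BSA; ``series``: (4, 2) or (n, 4, 2) day-ordered
        (INR, dose) pairs with all doses positive. Returns a float for a
        single sample or an (n,) array.
        """
        static = np.asarray(static, dtype=float)
        series = np.asarray(series, dtype=float)
        single = static.ndim == 1
        if single:
            static = static[None]
            series = series[None]
        if static.shape[1:] != (N_STATIC,):
            raise ValueError(f"static must have {N_STATIC} features")
        if series.shape[1:] != (SERIES_STEPS, SERIES_CHANNELS):
            raise ValueError(
                f"series must be ({SERIES_STEPS}, {SERIES_CHANNELS}) per sample")
        if static.shape[0] != series.shape[0]:
            raise ValueError("static and series batch sizes differ")
        if np.any(series[..., 1] <= 0):
            raise ValueError("all series doses must be positive")
        xs = self.standardizer.transform_static(static)
        xq = self.standardizer.transform_series(series)
        z = self.model.forward(xs, xq)
        out = self.standardizer.inverse_target(z)
        return float(out[0]) if single else out

    def predict_windows(self, windows: pd.DataFrame):
        """Vectorized prediction over a window table (target column ignored)."""
        xs, xq, _ = self.standardizer.transform_windows(windows)
        return self.standardizer.inverse_target(self.model.forward(xs, xq))

    # -- serialization -----------------------------------------------------
    def save(self, directory):
        """Write the model bundle: weights, standardizer, config, history."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz",
                 **{f"p{i}": p for i, p in enumerate(self.model.params())})
        std_json = self.standardizer.to_json()
        (d / "standardizer.json").write_text(std_json)
        (d / "config.yaml").write_text(yaml.safe_dump(self.config.to_dict()))
        self.history.to_csv(d / "history.csv", index=False)
        manifest = {
            "seed": self.seed,
            "config_hash": _config_hash(self.config),
            "standardizer_hash": hashlib.sha256(std_json.encode()).hexdigest()[:16],
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "TrainedPredictor":
        d = Path(directory)
        config = NetworkConfig.from_dict(
            yaml.safe_load((d / "config.yaml").read_text()))
        std_json = (d / "standardizer.json").read_text()
        standardizer = Standardizer.from_json(std_json)
        manifest = json.loads((d / "manifest.json").read_text())
        if manifest["config_hash"] != _config_hash(config):
            raise ValueError("model bundle is inconsistent: config hash mismatch")
        if manifest["standardizer_hash"] != hashlib.sha256(
                std_json.encode()).hexdigest()[:16]:
            raise ValueError(
                "model bundle is inconsistent: standardizer hash mismatch")
        model = InrNet(config, seed=manifest["seed"])
        with np.load(d / "weights.npz") as z:
            weights = [z[f"p{i}"] for i in range(len(z.files))]
        model.set_weights(weights)
        history = pd.read_csv(d / "history.csv")
        return cls(model=model, standardizer=standardizer, config=config,
                   history=history, seed=manifest["seed"])


def train(model: InrNet, windows: pd.DataFrame, config: NetworkConfig,
          standardizer: Standardizer) -> TrainedPredictor:
    """Fit the network on a window table by minibatch Adam on MAE loss.

    A seeded random ``validation_fraction`` of the samples is held out;
    training stops once validation loss has not improved for
    ``early_stop_patience`` epochs (or at ``max_epochs``) and the
    best-validation weights are restored. The standardizer must have been
    fitted on training data only.
    """
    config.validate()
    if len(windows) < 10:
        raise ValueError("need at least 10 training samples")
    xs, xq, y = standardizer.transform_windows(windows)
    if y is None:
        raise ValueError("training windows must carry target_inr")

    rng = np.random.default_rng(config.seed)
    n = len(y)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.validation_fraction * n)))
    val_idx = perm[n - n_val:]
    train_idx = perm[: n - n_val]
    if len(train_idx) == 0:
        raise ValueError("validation split leaves no training samples")

    opt = _Adam(model.params(), lr=config.learning_rate)
    best_val = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    history = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_idx))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = train_idx[order[start:start + config.batch_size]]
            pred = model.forward(xs[idx], xq[idx])
            resid = pred - y[idx]
            loss = np.abs(resid).mean()
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}")
            model.zero_grads()
            model.backward(np.sign(resid) / len(idx))
            opt.step(model.params(), model.grads())
            epoch_loss += loss * len(idx)
        train_loss = epoch_loss / len(train_idx)
        val_pred = model.forward(xs[val_idx], xq[val_idx])
        val_loss = float(np.abs(val_pred - y[val_idx]).mean())
        history.append(
            {"epoch": epoch, "train_loss": float(train_loss),
             "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch
        elif epoch - best_epoch >= config.early_stop_patience:
            break
    model.set_weights(best_weights)
    return TrainedPredictor(
        model=model,
        standardizer=standardizer,
        config=config,
        history=pd.DataFrame(history, columns=["epoch", "train_loss", "val_loss"]),
        seed=config.seed,
    )


def fit_predictor(windows: pd.DataFrame, config: NetworkConfig | None = None
                  ) -> TrainedPredictor:
    """Convenience: fit the standardizer on ``windows``, build and train."""
    config = (config or NetworkConfig()).validate()
    standardizer = fit_standardizer(windows)
    model = build_network(config)
    return train(model, windows, config, standardizer)
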