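"""1-D convolutional regressor on stacked feature channels, in NumPy.

Feature blocks are zero-padded to a common length and stacked as
channels of a (samples × channels × length) tensor. The network is
three (conv1d → ReLU → max-pool) stages followed by one fully connected
ReLU layer with dropout and a linear scalar output, trained with MSE
loss, a 10% validation slice, early stopping, and learning-rate
reduction on plateau. Forward and backward passes are vectorised im2col
einsums; with a fixed seed training is exactly reproducible because all
randomness (init, shuffling, dropout) flows from one generator.

The randomized hyperparameter search draws from the study's stated
space: filters 2–15 / 4–25 / 8–35 in steps of 2 per layer, odd kernels
3–19 / 5–17 / 7–15, fully connected width in {16, 32, 64, 128, 256},
optimizer in {Nadam, Adam, RMSprop}, batch size 8–128 and dropout
0–0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .data import FeatureStore
from .errors import (
    ArchitectureError,
    DataError,
    ParameterError,
    SelectionError,
    ShapeError,
)
from .gbt import TrainedRegressor, TrialLog

FC_NEURON_CHOICES = (16, 32, 64, 128, 256)
OPTIMIZER_CHOICES = ("nadam", "adam", "rmsprop")


@dataclass(frozen=True)
class CNNSearchSpace:
    """Per-layer filter/kernel ranges and training hyperparameters."""

    filters: tuple[tuple[int, int], ...] = ((2, 15), (4, 25), (8, 35))
    kernels: tuple[tuple[int, int], ...] = ((3, 19), (5, 17), (7, 15))
    fc_neurons: tuple[int, ...] = FC_NEURON_CHOICES
    optimizers: tuple[str, ...] = OPTIMIZER_CHOICES
    batch_size: tuple[int, int] = (8, 128)
    dropout_rate: tuple[float, float] = (0.0, 0.5)

    def __post_init__(self) -> None:
        if len(self.filters) != 3 or len(self.kernels) != 3:
            raise ParameterError("search space defines exactly 3 conv layers")
        for lo, hi in (*self.filters, *self.kernels, self.batch_size):
            if lo > hi or lo < 1:
                raise ParameterError(f"bad range ({lo}, {hi})")
        if not all(lo % 2 == 1 for lo, _ in self.kernels):
            raise ParameterError("kernel range minima must be odd")


def sample_cnn_config(space: CNNSearchSpace, seed: int) -> dict:
    """One uniform draw; filters step by 2, kernels stay odd."""
    rng = np.random.default_rng(seed)

    def step2(lo, hi):
        return int(rng.choice(np.arange(lo, hi + 1, 2)))

    return {
        "filters": tuple(step2(lo, hi) for lo, hi in space.filters),
        "kernels": tuple(step2(lo, hi) for lo, hi in space.kernels),
        "fc_neurons": int(rng.choice(space.fc_neurons)),
        "optimizer": str(rng.choice(space.optimizers)),
        "batch_size": int(rng.integers(space.batch_size[0], space.batch_size[1] + 1)),
        "dropout_rate": float(rng.uniform(*space.dropout_rate)),
        "learning_rate": 1e-3,
    }


def stack_feature_blocks(store: FeatureStore, selection: list[str]) -> np.ndarray:
    """Stack named blocks as channels, right-padding with zeros to max dim."""
    missing = [name for name in selection if name not in store.blocks]
    if missing:
        raise SelectionError(f"unknown feature blocks: {missing}")
    if not selection:
        raise SelectionError("selection must name at least one block")
    for name in selection:
        if store[name].sample_ids != store.sample_ids:
            raise SelectionError(f"block {name!r} is misaligned with the store")
    n = store.n_samples
    length = max(store[name].dim for name in selection)
    tensor = np.zeros((n, len(selection), length), dtype=np.float64)
    for c, name in enumerate(selection):
        block = store[name].matrix
        tensor[:, c, : block.shape[1]] = block
    return tensor


# ---------------------------------------------------------------------------
# layers


class _Conv1D:
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.W = rng.standard_normal((out_ch, in_ch, kernel)) * scale
        self.b = np.zeros(out_ch)
        self.kernel = kernel

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # x: (n, C, L) → (n, F, L-k+1)
        self._windows = sliding_window_view(x, self.kernel, axis=2)
        return np.einsum("nclk,fck->nfl", self._windows, self.W, optimize=True) + self.b[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = np.einsum("nfl,nclk->fck", dout, self._windows, optimize=True)
        self.db = dout.sum(axis=(0, 2))
        k = self.kernel
        pad = np.pad(dout, ((0, 0), (0, 0), (k - 1, k - 1)))
        win = sliding_window_view(pad, k, axis=2)
        return np.einsum("nftk,fck->nct", win, self.W[:, :, ::-1], optimize=True)

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params_grads(self):
        return []


class _MaxPool2:
    """Non-overlapping max pooling of width 2; a trailing odd column is dropped."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, length = x.shape
        self._in_length = length
        l2 = length // 2
        xr = x[:, :, : l2 * 2].reshape(n, c, l2, 2)
        self._argmax = xr.argmax(axis=3)
        return np.take_along_axis(xr, self._argmax[..., None], axis=3)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, l2 = dout.shape
        dxr = np.zeros((n, c, l2, 2))
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=3)
        dx = np.zeros((n, c, self._in_length))
        dx[:, :, : l2 * 2] = dxr.reshape(n, c, l2 * 2)
        return dx

    def params_grads(self):
        return []


class _Flatten:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def params_grads(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _Dropout:
    """Inverted dropout; identity at prediction time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self._rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask

    def params_grads(self):
        return []


class _Optimizer:
    """Adam / Nadam / RMSprop over a flat parameter list, in place."""

    def __init__(self, kind: str, lr: float):
        if kind not in OPTIMIZER_CHOICES:
            raise ParameterError(f"unknown optimizer {kind!r}")
        self.kind = kind
        self.lr = lr
        self.t = 0
        self._m: list[np.ndarray] = []
        self._v: list[np.ndarray] = []

    def step(self, params_grads) -> None:
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        if not self._m:
            self._m = [np.zeros_like(p) for p, _ in params_grads]
            self._v = [np.zeros_like(p) for p, _ in params_grads]
        self.t += 1
        for i, (p, g) in enumerate(params_grads):
            if self.kind == "rmsprop":
                self._v[i] = 0.9 * self._v[i] + 0.1 * g * g
                p -= self.lr * g / (np.sqrt(self._v[i]) + eps)
                continue
            self._m[i] = beta1 * self._m[i] + (1 - beta1) * g
            self._v[i] = beta2 * self._v[i] + (1 - beta2) * g * g
            m_hat = self._m[i] / (1 - beta1**self.t)
            v_hat = self._v[i] / (1 - beta2**self.t)
            if self.kind == "nadam":
                m_hat = beta1 * m_hat + (1 - beta1) * g / (1 - beta1**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + eps)


# ---------------------------------------------------------------------------
# network


class CNN1DRegressor:
    """The fixed 3-conv architecture built from one sampled configuration."""

    def __init__(self, in_shape: tuple[int, int], config: dict, rng: np.random.Generator):
        channels, length = in_shape
        filters, kernels = config["filters"], config["kernels"]
        self.layers: list = []
        cur_ch, cur_len = channels, length
        for f, k in zip(filters, kernels):
            if k > cur_len:
                raise ArchitectureError(
                    f"kernel {k} exceeds feature length {cur_len} at build time"
                )
            self.layers += [_Conv1D(cur_ch, f, k, rng), _ReLU(), _MaxPool2()]
            cur_ch, cur_len = f, (cur_len - k + 1) // 2
            if cur_len < 1:
                raise ArchitectureError("feature length collapsed below 1 after pooling")
        self.layers.append(_Flatten())
        flat = cur_ch * cur_len
        self.layers += [
            _Dense(flat, config["fc_neurons"], rng),
            _ReLU(),
            _Dropout(config["dropout_rate"], rng),
            _Dense(config["fc_neurons"], 1, rng),
        ]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x[:, 0]

    def backward(self, dloss: np.ndarray) -> None:
        grad = dloss[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def params_grads(self):
        out = []
        for layer in self.layers:
            out += layer.params_grads()
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in _params(layer)]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for p in _params(layer):
                p[...] = weights[i]
                i += 1


def _params(layer) -> list[np.ndarray]:
    if isinstance(layer, _Conv1D):
        return [layer.W, layer.b]
    if isinstance(layer, _Dense):
        return [layer.W, layer.b]
    return []


@dataclass
class _FitResult:
    val_losses: list[float] = field(default_factory=list)
    best_val: float = np.inf
    epochs_run: int = 0


def train_cnn(
    tensor: np.ndarray,
    y: np.ndarray,
    config: dict,
    seed: int = 0,
    max_epochs: int = 100,
    patience: int = 10,
    lr_patience: int = 5,
    lr_factor: float = 0.5,
) -> TrainedRegressor:
    """Train the 3-conv network with early stopping and LR-on-plateau.

    A seeded 10% slice of the rows is held out as the validation set;
    training halts once validation MSE has not improved for ``patience``
    epochs (best weights are restored), and the learning rate is halved
    after ``lr_patience`` stale epochs.
    """
    tensor = np.asarray(tensor, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if tensor.ndim != 3 or tensor.shape[0] != len(y):
        raise ShapeError(f"tensor {tensor.shape} does not align with y of length {len(y)}")
    if not np.isfinite(tensor).all() or not np.isfinite(y).all():
        raise DataError("non-finite values in tensor or y")
    n = tensor.shape[0]
    batch_size = int(config["batch_size"])
    if n < batch_size:
        raise ParameterError(f"{n} samples < batch size {batch_size}")

    rng = np.random.default_rng(seed)
    net = CNN1DRegressor(tensor.shape[1:], config, rng)
    opt = _Optimizer(config["optimizer"], config.get("learning_rate", 1e-3))

    n_val = max(1, int(round(0.1 * n)))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = tensor[tr_idx], y[tr_idx]
    Xval, yval = tensor[val_idx], y[val_idx]
    # start from the mean predictor: zero output weights, bias = mean target
    net.layers[-1].W[:] = 0.0
    net.layers[-1].b[:] = ytr.mean()

    result = _FitResult()
    best_weights = net.get_weights()
    stale = stale_lr = 0
    for epoch in range(max_epochs):
        order = rng.permutation(len(tr_idx))
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            pred = net.forward(Xtr[idx], train=True)
            dloss = 2.0 * (pred - ytr[idx]) / len(idx)
            net.backward(dloss)
            opt.step(net.params_grads())
        val_pred = net.forward(Xval, train=False)
        val_mse = float(np.mean((val_pred - yval) ** 2))
        result.val_losses.append(val_mse)
        result.epochs_run = epoch + 1
        if val_mse < result.best_val - 1e-9:
            result.best_val = val_mse
            best_weights = net.get_weights()
            stale = stale_lr = 0
        else:
            stale += 1
            stale_lr += 1
            if stale_lr >= lr_patience:
                opt.lr *= lr_factor
                stale_lr = 0
            if stale >= patience:
                break
    net.set_weights(best_weights)

    n_features = tensor.shape[1:]

    def _predict(Xnew):
        Xnew = np.asarray(Xnew, dtype=np.float64)
        if Xnew.ndim != 3 or Xnew.shape[1:] != n_features:
            raise ShapeError(
                f"prediction tensor has shape {Xnew.shape}, trained on {n_features}"
            )
        if Xnew.shape[0] == 0:
            return np.empty(0)
        return net.forward(Xnew, train=False)

    return TrainedRegressor(
        kind="cnn",
        config=dict(config),
        seed=seed,
        training_log=result.val_losses,
        _predict_fn=_predict,
    )


def random_search_cnn(
    tensor: np.ndarray,
    y: np.ndarray,
    space: CNNSearchSpace | None = None,
    n_trials: int = 10,
    seed: int = 0,
    max_epochs: int = 30,
) -> tuple[TrialLog, list[dict]]:
    """Randomized search ranked by best validation MSE, ascending.

    Per-trial training failures are recorded as infinite loss rather
    than aborting the search. Returns the full log (ranked accessor
    included) plus configs ordered best-first.
    """
    space = space or CNNSearchSpace()
    if n_trials < 1:
        raise ParameterError("n_trials must be ≥ 1")
    log = TrialLog()
    for t in range(n_trials):
        trial_seed = seed + 1000 * t + 7
        config = sample_cnn_config(space, trial_seed)
        try:
            model = train_cnn(tensor, y, config, seed=trial_seed, max_epochs=max_epochs)
            loss = min(model.training_log)
        except (ArchitectureError, ParameterError) as exc:
            config = {**config, "error": str(exc)}
            loss = float("inf")
        log.record(config, loss, trial_seed)
    ranked_configs = [
        log.trials[i][0] for i in log.ranked() if np.isfinite(log.trials[i][1])
    ]
    return log, ranked_configs
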