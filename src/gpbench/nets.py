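"""Fully connected and convolutional neural networks for genomic prediction.

Implemented directly on numpy so that first-hidden-layer weights are fully
under our control — the seeded-initialization procedure (starting a fraction
of hidden nodes from another genomic-prediction model's marker effects)
requires writing those weights explicitly.

The multilayer perceptron takes the marker vector as input, has one to
three fully connected hidden layers (ReLU or sigmoid), a linear output
node, inverted dropout and an L2 weight penalty, and is trained with Adam
on mean squared error.  Starting weights are Xavier-initialized (variance
``2 / (fan_in + fan_out)``, biases zero).  Training stops early once the
relative change in validation MSE has stayed below 0.1% for 10 consecutive
epochs after a 10-epoch burn-in; if the stopped network predicts
(near-)constant values on the validation set it is reinitialized and
retrained, up to a bounded number of restarts.

The convolutional network consumes one-hot-encoded markers (three channels:
aa / Aa / AA present or absent) through a fixed layer order — convolution,
max-pooling, dropout, dense, batch normalization, linear output — trained
with Adam in mini-batches of 100 for up to 1,000 epochs with
keras-style early stopping (min_delta = 0, patience = 10) and the same
degenerate-restart rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .datatypes import AlignmentError, GenotypeMatrix

__all__ = [
    "AnnArchitecture",
    "WeightInit",
    "TrainingTrace",
    "TrainingFailedError",
    "CnnSettings",
    "xavier_init",
    "seed_hidden_weights",
    "early_stopping_epoch",
    "keras_early_stopping_epoch",
    "train_ann",
    "one_hot_encode",
    "build_train_cnn",
    "MlpPredictor",
    "CnnPredictor",
]

DEGENERACY_VAR_RATIO = 1e-8
MAX_RESTARTS = 3


class TrainingFailedError(RuntimeError):
    """All restarts produced a degenerate (constant-output) network."""


@dataclass
class AnnArchitecture:
    """Hyperparameters of the multilayer perceptron."""

    hidden_layer_sizes: tuple[int, ...] = (50,)
    activation: str = "relu"
    dropout_rate: float = 0.10
    l2_penalty: float = 0.0
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        self.hidden_layer_sizes = tuple(int(h) for h in self.hidden_layer_sizes)
        if not (1 <= len(self.hidden_layer_sizes) <= 3):
            raise ValueError("between one and three hidden layers")
        if any(not (5 <= h <= 100) for h in self.hidden_layer_sizes):
            raise ValueError("hidden layer sizes must be in [5, 100]")
        if self.activation not in ("relu", "sigmoid"):
            raise ValueError("activation must be 'relu' or 'sigmoid'")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2_penalty < 0 or self.learning_rate <= 0:
            raise ValueError("invalid penalty or learning rate")


@dataclass
class WeightInit:
    """Per-layer starting weights and biases, with seeding provenance."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    seeded_node_indices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int)
    )
    provenance: str = "random_xavier"

    def copy(self) -> "WeightInit":
        return WeightInit(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            seeded_node_indices=self.seeded_node_indices.copy(),
            provenance=self.provenance,
        )


@dataclass
class TrainingTrace:
    """Per-epoch losses and stopping bookkeeping for one training run."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    restarts_used: int = 0


def xavier_init(
    layer_shapes: Sequence[tuple[int, int]], seed: int | None = None
) -> WeightInit:
    """Xavier (Glorot) starting weights: N(0, 2/(fan_in+fan_out)), zero biases."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in layer_shapes:
        if fan_in < 1 or fan_out < 1:
            raise ValueError("layer shapes must be positive")
        sd = np.sqrt(2.0 / (fan_in + fan_out))
        weights.append(rng.normal(0.0, sd, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return WeightInit(weights=weights, biases=biases)


def seed_hidden_weights(
    base: WeightInit,
    donor_scores: np.ndarray,
    fraction: float = 0.25,
    noise_seed: int | None = None,
    center_scores: bool = False,
    noise_mode: str = "multiplicative",
    donor_name: str = "donor",
) -> WeightInit:
    """Seed a fraction of first-hidden-layer nodes from another model.

    The first ``round(fraction * H)`` nodes of the first hidden layer receive
    the donor's per-marker score vector as incoming weights, linearly
    rescaled so its standard deviation matches that of the Xavier-initialized
    remainder of the layer, then perturbed with noise drawn per entry from
    ``N(0, sd_xavier)`` — multiplied in by default (``noise_mode=
    "multiplicative"``), or added (``"additive"``, which preserves the seed
    signs) behind the flag.  ``center_scores`` subtracts the mean first,
    which matters for non-negative importance scores (Random Forest) so
    seeds carry sign variation.  ``fraction=0`` returns the base unchanged.
    """
    if noise_mode not in ("multiplicative", "additive"):
        raise ValueError("noise_mode must be 'multiplicative' or 'additive'")
    scores = np.asarray(donor_scores, dtype=float)
    p, H = base.weights[0].shape
    if scores.shape != (p,):
        raise AlignmentError(
            f"donor provides {scores.shape} scores; first layer expects ({p},)"
        )
    n_seeded = int(round(fraction * H))
    if n_seeded == 0:
        return base
    if n_seeded >= H:
        raise ValueError("seeding fraction must leave some nodes random")

    out = base.copy()
    if center_scores:
        scores = scores - scores.mean()
    sd_scores = scores.std()
    if sd_scores == 0:
        raise ValueError("donor scores are constant; cannot rescale")
    sd_rest = out.weights[0][:, n_seeded:].std()
    seed_vec = scores * (sd_rest / sd_scores)

    rng = np.random.default_rng(noise_seed)
    for node in range(n_seeded):
        noise = rng.normal(0.0, sd_rest, size=p)
        if noise_mode == "multiplicative":
            out.weights[0][:, node] = seed_vec * noise
        else:
            out.weights[0][:, node] = seed_vec + noise
    out.seeded_node_indices = np.arange(n_seeded)
    out.provenance = f"seeded:{donor_name}"
    return out


def early_stopping_epoch(
    val_mse: Sequence[float],
    burn_in: int = 10,
    patience: int = 10,
    rel_tol: float = 1e-3,
) -> int | None:
    """First epoch at which the stop rule fires, or None.

    Epochs are 1-indexed.  An epoch t (> burn_in, t >= 2) counts as "flat"
    when ``|MSE_t - MSE_{t-1}| / MSE_{t-1} < rel_tol``; training stops at the
    first epoch ending a run of ``patience`` consecutive flat epochs, all
    after the burn-in.  A pure function of the validation-loss sequence.
    """
    run = 0
    for t in range(2, len(val_mse) + 1):
        if t <= burn_in:
            continue
        prev, cur = val_mse[t - 2], val_mse[t - 1]
        denom = abs(prev) if prev != 0 else 1e-300
        flat = abs(cur - prev) / denom < rel_tol
        run = run + 1 if flat else 0
        if run >= patience:
            return t
    return None


def keras_early_stopping_epoch(
    val_mse: Sequence[float], min_delta: float = 0.0, patience: int = 10
) -> int | None:
    """Stop when validation loss has not improved by > min_delta for
    ``patience`` epochs (the convention of common deep-learning toolkits)."""
    best = np.inf
    wait = 0
    for t, v in enumerate(val_mse, start=1):
        if v < best - min_delta:
            best = v
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                return t
    return None


# ---------------------------------------------------------------------------
# multilayer perceptron


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def _act_grad(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (a > 0).astype(float)
    return a * (1.0 - a)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class MlpPredictor:
    """A trained multilayer perceptron honoring the common predict contract."""

    def __init__(self, arch: AnnArchitecture, init: WeightInit):
        self.arch = arch
        self.weights = [w.copy() for w in init.weights]
        self.biases = [b.copy() for b in init.biases]
        self.init_provenance = init.provenance

    @property
    def n_markers(self) -> int:
        return self.weights[0].shape[0]

    def _forward(
        self, X: np.ndarray, dropout_rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
        """Returns (output, layer inputs, pre-dropout activations, masks)."""
        inputs = [X]  # input fed to each weight layer
        pre_drop: list[np.ndarray] = []  # hidden activations before dropout
        masks: list[np.ndarray] = []
        a = X
        n_hidden = len(self.weights) - 1
        for l in range(n_hidden):
            z = a @ self.weights[l] + self.biases[l]
            h = _act(z, self.arch.activation)
            pre_drop.append(h)
            if dropout_rng is not None and self.arch.dropout_rate > 0:
                keep = 1.0 - self.arch.dropout_rate
                mask = (dropout_rng.random(h.shape) < keep) / keep
            else:
                mask = np.ones_like(h)
            masks.append(mask)
            a = h * mask
            inputs.append(a)
        out = (a @ self.weights[-1] + self.biases[-1]).ravel()
        return out, inputs, pre_drop, masks

    def predict(self, G_new) -> np.ndarray:
        X = np.asarray(
            G_new.X() if isinstance(G_new, GenotypeMatrix) else G_new, dtype=float
        )
        if X.shape[1] != self.n_markers:
            raise AlignmentError(
                f"marker mismatch: fit expects {self.n_markers}, got {X.shape[1]}"
            )
        out, _, _, _ = self._forward(X)
        return out

    def loss_and_grads(
        self,
        X: np.ndarray,
        y: np.ndarray,
        dropout_rng: np.random.Generator | None = None,
    ) -> tuple[float, list[np.ndarray]]:
        """MSE + L2 loss and gradients w.r.t. [W..., b...]."""
        n = X.shape[0]
        out, inputs, pre_drop, masks = self._forward(X, dropout_rng)
        resid = out - y
        l2 = self.arch.l2_penalty
        loss = float(np.mean(resid**2)) + l2 * sum(
            float(np.sum(w * w)) for w in self.weights
        )
        gW = [np.zeros_like(w) for w in self.weights]
        gb = [np.zeros_like(b) for b in self.biases]
        delta = (2.0 / n) * resid[:, None]  # (n,1)
        gW[-1] = inputs[-1].T @ delta + 2 * l2 * self.weights[-1]
        gb[-1] = delta.sum(axis=0)
        back = delta @ self.weights[-1].T
        for l in range(len(self.weights) - 2, -1, -1):
            back = back * masks[l] * _act_grad(pre_drop[l], self.arch.activation)
            gW[l] = inputs[l].T @ back + 2 * l2 * self.weights[l]
            gb[l] = back.sum(axis=0)
            if l > 0:
                back = back @ self.weights[l].T
        return loss, gW + gb

    @property
    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases


def mlp_layer_shapes(n_markers: int, arch: AnnArchitecture) -> list[tuple[int, int]]:
    sizes = [n_markers, *arch.hidden_layer_sizes, 1]
    return list(zip(sizes[:-1], sizes[1:]))


def train_ann(
    G_train,
    y_train,
    G_val,
    y_val,
    arch: AnnArchitecture,
    init: WeightInit | None = None,
    max_epochs: int = 500,
    seed: int | None = None,
    reinit: Callable[[int], WeightInit] | None = None,
    max_restarts: int = MAX_RESTARTS,
) -> tuple[MlpPredictor, TrainingTrace]:
    """Train the multilayer perceptron with Adam, early stopping and restarts.

    The validation set (disjoint from training, by contract) drives the stop
    rule.  If the stopped network's validation predictions are near-constant
    (variance below ``1e-8 *`` the validation-phenotype variance) the run is
    considered degenerate and restarted from fresh starting weights —
    ``reinit(restart_index)`` when given (so seeded runs can re-seed with new
    noise), otherwise a fresh Xavier draw.  After ``max_restarts`` failed
    restarts a :class:`TrainingFailedError` is raised.
    """
    X = np.asarray(
        G_train.X() if isinstance(G_train, GenotypeMatrix) else G_train, dtype=float
    )
    y = np.asarray(y_train, dtype=float)
    Xv = np.asarray(
        G_val.X() if isinstance(G_val, GenotypeMatrix) else G_val, dtype=float
    )
    yv = np.asarray(y_val, dtype=float)
    shapes = mlp_layer_shapes(X.shape[1], arch)
    ss = np.random.SeedSequence(seed)
    init_seed_seq, drop_seed_seq = ss.spawn(2)
    base_init = init if init is not None else xavier_init(shapes, init_seed_seq)

    var_yv = float(np.var(yv)) if np.var(yv) > 0 else 1.0
    trace = TrainingTrace()
    cur_init = base_init
    for attempt in range(max_restarts + 1):
        model = MlpPredictor(arch, cur_init)
        opt = _Adam(model.params, arch.learning_rate)
        drop_rng = np.random.default_rng(drop_seed_seq)
        trace = TrainingTrace(restarts_used=attempt)
        for epoch in range(1, max_epochs + 1):
            loss, grads = model.loss_and_grads(X, y, dropout_rng=drop_rng)
            opt.step(model.params, grads)
            trace.train_mse.append(loss)
            val_pred, _, _, _ = model._forward(Xv)
            trace.val_mse.append(float(np.mean((val_pred - yv) ** 2)))
            stop = early_stopping_epoch(trace.val_mse)
            if stop is not None:
                trace.stop_epoch = stop
                break
        else:
            trace.stop_epoch = max_epochs
        val_pred, _, _, _ = model._forward(Xv)
        if float(np.var(val_pred)) >= DEGENERACY_VAR_RATIO * var_yv:
            return model, trace
        # degenerate: reinitialize and retrain
        if attempt < max_restarts:
            if reinit is not None:
                cur_init = reinit(attempt)
            else:
                cur_init = xavier_init(shapes, init_seed_seq.spawn(1)[0])
    raise TrainingFailedError(
        f"validation predictions stayed degenerate after {max_restarts} restarts"
    )


# ---------------------------------------------------------------------------
# convolutional network on one-hot markers


def one_hot_encode(G) -> np.ndarray:
    """Markers to (n, p, 3) one-hot channels for calls -1 / 0 / 1."""
    calls = np.asarray(G.calls if isinstance(G, GenotypeMatrix) else G)
    out = np.zeros((*calls.shape, 3), dtype=float)
    for c, val in enumerate((-1, 0, 1)):
        out[..., c] = calls == val
    return out


@dataclass
class CnnSettings:
    """Architecture and optimization settings for the convolutional network."""

    n_filters: int = 16
    kernel_width: int = 5
    pool_width: int = 2
    dropout_rate: float = 0.25
    dense_width: int = 32
    learning_rate: float = 1e-3
    batch_size: int = 100
    max_epochs: int = 1000
    patience: int = 10
    min_delta: float = 0.0
    bn_momentum: float = 0.9


class CnnPredictor:
    """Conv -> max-pool -> dropout -> dense -> batch-norm -> linear output."""

    def __init__(self, n_markers: int, settings: CnnSettings, seed=None):
        s = settings
        rng = np.random.default_rng(seed)
        self.settings = s
        self.n_markers = n_markers
        self.conv_len = n_markers - s.kernel_width + 1
        if self.conv_len < s.pool_width:
            raise ValueError("too few markers for this kernel/pool size")
        self.pool_len = self.conv_len // s.pool_width
        flat = self.pool_len * s.n_filters

        def xav(fi, fo, shape):
            return rng.normal(0.0, np.sqrt(2.0 / (fi + fo)), size=shape)

        k3 = s.kernel_width * 3
        self.Wc = xav(k3, s.n_filters, (k3, s.n_filters))
        self.bc = np.zeros(s.n_filters)
        self.Wd = xav(flat, s.dense_width, (flat, s.dense_width))
        self.bd = np.zeros(s.dense_width)
        self.gamma = np.ones(s.dense_width)
        self.beta = np.zeros(s.dense_width)
        self.Wo = xav(s.dense_width, 1, (s.dense_width, 1))
        self.bo = np.zeros(1)
        self.run_mean = np.zeros(s.dense_width)
        self.run_var = np.ones(s.dense_width)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.Wc, self.bc, self.Wd, self.bd, self.gamma, self.beta,
                self.Wo, self.bo]

    def _patches(self, Xoh: np.ndarray) -> np.ndarray:
        """(n, p, 3) -> (n, conv_len, kernel_width*3) sliding windows."""
        n = Xoh.shape[0]
        k = self.settings.kernel_width
        windows = np.lib.stride_tricks.sliding_window_view(Xoh, k, axis=1)
        # windows: (n, conv_len, 3, k) -> (n, conv_len, k*3)
        return windows.transpose(0, 1, 3, 2).reshape(n, self.conv_len, k * 3)

    def forward(
        self,
        Xoh: np.ndarray,
        train: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        s = self.settings
        n = Xoh.shape[0]
        P = self._patches(Xoh)
        zc = P @ self.Wc + self.bc  # (n, L, F)
        ac = np.maximum(zc, 0.0)
        L2 = self.pool_len * s.pool_width
        pooled_in = ac[:, :L2].reshape(n, self.pool_len, s.pool_width, s.n_filters)
        argmax = pooled_in.argmax(axis=2)
        pooled = pooled_in.max(axis=2)  # (n, pool_len, F)
        flat = pooled.reshape(n, -1)
        if train and s.dropout_rate > 0 and dropout_rng is not None:
            keep = 1.0 - s.dropout_rate
            mask = (dropout_rng.random(flat.shape) < keep) / keep
        else:
            mask = np.ones_like(flat)
        dropped = flat * mask
        zd = dropped @ self.Wd + self.bd
        ad = np.maximum(zd, 0.0)
        if train:
            mean = ad.mean(axis=0)
            var = ad.var(axis=0)
            m = s.bn_momentum
            self.run_mean = m * self.run_mean + (1 - m) * mean
            self.run_var = m * self.run_var + (1 - m) * var
        else:
            mean, var = self.run_mean, self.run_var
        xhat = (ad - mean) / np.sqrt(var + 1e-5)
        bn = self.gamma * xhat + self.beta
        out = (bn @ self.Wo + self.bo).ravel()
        cache = dict(
            P=P, zc=zc, ac=ac, argmax=argmax, pooled=pooled, mask=mask,
            dropped=dropped, zd=zd, ad=ad, xhat=xhat, bn=bn, mean=mean, var=var,
        )
        return out, cache

    def loss_and_grads(
        self,
        Xoh: np.ndarray,
        y: np.ndarray,
        dropout_rng: np.random.Generator | None = None,
        train: bool = True,
    ) -> tuple[float, list[np.ndarray]]:
        s = self.settings
        n = Xoh.shape[0]
        out, c = self.forward(Xoh, train=train, dropout_rng=dropout_rng)
        resid = out - y
        loss = float(np.mean(resid**2))
        dout = (2.0 / n) * resid[:, None]  # (n,1)
        gWo = c["bn"].T @ dout
        gbo = dout.sum(axis=0)
        dbn = dout @ self.Wo.T  # (n, d)
        ggamma = (dbn * c["xhat"]).sum(axis=0)
        gbeta = dbn.sum(axis=0)
        # batch-norm backward (through batch statistics)
        inv_sd = 1.0 / np.sqrt(c["var"] + 1e-5)
        dxhat = dbn * self.gamma
        dad = inv_sd / n * (
            n * dxhat
            - dxhat.sum(axis=0)
            - c["xhat"] * (dxhat * c["xhat"]).sum(axis=0)
        )
        dzd = dad * (c["zd"] > 0)
        gWd = c["dropped"].T @ dzd
        gbd = dzd.sum(axis=0)
        dflat = (dzd @ self.Wd.T) * c["mask"]
        dpooled = dflat.reshape(n, self.pool_len, s.n_filters)
        # route gradient through the max locations
        dac = np.zeros_like(c["ac"])
        L2 = self.pool_len * s.pool_width
        dpool_in = np.zeros((n, self.pool_len, s.pool_width, s.n_filters))
        idx_n, idx_l, idx_f = np.ogrid[: n, : self.pool_len, : s.n_filters]
        dpool_in[idx_n, idx_l, c["argmax"], idx_f] = dpooled
        dac[:, :L2] = dpool_in.reshape(n, L2, s.n_filters)
        dzc = dac * (c["zc"] > 0)
        gWc = np.einsum("nlk,nlf->kf", c["P"], dzc)
        gbc = dzc.sum(axis=(0, 1))
        return loss, [gWc, gbc, gWd, gbd, ggamma, gbeta, gWo, gbo]

    def predict(self, G_new) -> np.ndarray:
        Xoh = G_new if isinstance(G_new, np.ndarray) else one_hot_encode(G_new)
        if Xoh.shape[1] != self.n_markers:
            raise AlignmentError(
                f"marker mismatch: fit expects {self.n_markers}, got {Xoh.shape[1]}"
            )
        out, _ = self.forward(Xoh, train=False)
        return out


def build_train_cnn(
    G_train,
    y_train,
    G_val,
    y_val,
    settings: CnnSettings | None = None,
    seed: int | None = None,
    max_restarts: int = MAX_RESTARTS,
) -> tuple[CnnPredictor, TrainingTrace]:
    """Train the one-hot CNN with mini-batch Adam and patience-based stopping."""
    s = settings or CnnSettings()
    Xoh = G_train if isinstance(G_train, np.ndarray) else one_hot_encode(G_train)
    Xv = G_val if isinstance(G_val, np.ndarray) else one_hot_encode(G_val)
    y = np.asarray(y_train, dtype=float)
    yv = np.asarray(y_val, dtype=float)
    n, p = Xoh.shape[0], Xoh.shape[1]
    ss = np.random.SeedSequence(seed)
    var_yv = float(np.var(yv)) if np.var(yv) > 0 else 1.0

    for attempt in range(max_restarts + 1):
        init_seq, shuf_seq, drop_seq = ss.spawn(3)
        model = CnnPredictor(p, s, seed=init_seq)
        opt = _Adam(model.params, s.learning_rate)
        shuffle_rng = np.random.default_rng(shuf_seq)
        drop_rng = np.random.default_rng(drop_seq)
        trace = TrainingTrace(restarts_used=attempt)
        for epoch in range(1, s.max_epochs + 1):
            order = shuffle_rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, s.batch_size):
                idx = order[start : start + s.batch_size]
                loss, grads = model.loss_and_grads(
                    Xoh[idx], y[idx], dropout_rng=drop_rng
                )
                opt.step(model.params, grads)
                ep_loss += loss * len(idx)
            trace.train_mse.append(ep_loss / n)
            val_pred, _ = model.forward(Xv, train=False)
            trace.val_mse.append(float(np.mean((val_pred - yv) ** 2)))
            stop = keras_early_stopping_epoch(
                trace.val_mse, min_delta=s.min_delta, patience=s.patience
            )
            if stop is not None:
                trace.stop_epoch = stop
                break
        else:
            trace.stop_epoch = s.max_epochs
        val_pred, _ = model.forward(Xv, train=False)
        if float(np.var(val_pred)) >= DEGENERACY_VAR_RATIO * var_yv:
            return model, trace
        ss = np.random.SeedSequence((0 if seed is None else seed) + 7919 * (attempt + 1))
    raise TrainingFailedError(
        f"validation predictions stayed degenerate after {max_restarts} restarts"
    )
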