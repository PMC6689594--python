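"""Stacked recurrent neural network for frame-rate trajectory regression.

The model maps a per-frame feature sequence x(t) (10-dim) to the 2-D hyoid
trajectory in scaled target space.  Hidden layers are plain recurrent units
with rectified-linear activation,

    h_1(t) = relu(W_1 h_1(t-1) + R x(t) + b_0)
    h_k(t) = relu(W_k h_k(t-1) + V_{k-1} h_{k-1}(t) + b_{k-1}),  k = 2..m
    yhat(t) = U h_m(t) + b_m,

with h_k(-1) = 0.  Each recurrent matrix W_k is initialised to a symmetric
positive-definite matrix normalised so its largest eigenvalue is exactly 1
(the rest strictly below 1), which keeps early recurrent dynamics neither
exploding nor vanishing; R, V_k and U start uniform in [-0.01, 0.01] and all
biases at zero.

Training is full-sequence backpropagation through time with a mean-squared
error over all frames and output axes, one swallow per gradient step, Adam
as the adaptive-learning-rate scheme, and early stopping on validation loss.
Everything is plain numpy: sequences are ~30 frames and layers 64 units, so
autodiff machinery buys nothing here.
"""

from __future__ import annotations

import copy
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .preprocess import FrameFeatureSequence
from .targets import (HyoidAnnotation, TargetScaler, BoundingBox,
                      DEFAULT_BOX_SIDE, standardize_by_vertebra,
                      pixels_from_standardized, trajectory_to_boxes)

__all__ = ["SRNNConfig", "SRNNParams", "TrainingHistory",
           "init_params", "forward", "mse_loss", "backward",
           "train", "predict", "predict_pixels",
           "save_params", "load_params"]


@dataclass
class SRNNConfig:
    n_layers: int = 4
    units: int = 64
    input_dim: int = 10
    output_dim: int = 2
    seed: int = 0
    learning_rate: float = 2e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    patience: int = 20
    max_epochs: int = 500
    init_scale: float = 0.01     # half-width of the uniform R/V/U init

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.units < 1:
            raise ValueError("need at least one layer and one unit")
        if self.input_dim < 1 or self.output_dim < 1:
            raise ValueError("dims must be >= 1")


@dataclass
class SRNNParams:
    """All trainable arrays.

    ``W`` holds the m recurrent matrices, ``V`` the m-1 inter-layer matrices,
    ``R`` the input matrix, ``U`` the readout, and ``b`` the m+1 bias vectors
    (b_0..b_{m-1} feed layers 1..m, b_m is the output bias).
    """

    W: list[np.ndarray]
    V: list[np.ndarray]
    R: np.ndarray
    U: np.ndarray
    b: list[np.ndarray]

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def arrays(self) -> list[np.ndarray]:
        """Flat list view, in a stable order, for optimisers."""
        return [*self.W, *self.V, self.R, self.U, *self.b]

    def copy(self) -> "SRNNParams":
        return copy.deepcopy(self)


@dataclass
class TrainingHistory:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    @property
    def n_epochs(self) -> int:
        return len(self.train_losses)


def _spd_unit_spectral(units: int, rng: np.random.Generator) -> np.ndarray:
    """Symmetric positive-definite matrix with top eigenvalue exactly 1."""
    g = rng.standard_normal((units, units))
    s = g @ g.T + 1e-3 * np.eye(units)
    top = np.linalg.eigvalsh(s)[-1]
    return s / top


def init_params(config: SRNNConfig) -> SRNNParams:
    """Deterministic initialisation from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    u, d, o, a = config.units, config.input_dim, config.output_dim, config.init_scale
    W = [_spd_unit_spectral(u, rng) for _ in range(config.n_layers)]
    V = [rng.uniform(-a, a, size=(u, u)) for _ in range(config.n_layers - 1)]
    R = rng.uniform(-a, a, size=(u, d))
    U = rng.uniform(-a, a, size=(o, u))
    b = [np.zeros(u) for _ in range(config.n_layers)] + [np.zeros(o)]
    return SRNNParams(W, V, R, U, b)


def forward(params: SRNNParams, features: FrameFeatureSequence | np.ndarray,
            return_cache: bool = False):
    """Run the recurrence over a feature sequence.

    Returns predictions of shape (T, output_dim); with ``return_cache`` also
    the stacked hidden states H of shape (m, T, units) for backprop.
    """
    X = features.values if isinstance(features, FrameFeatureSequence) else \
        np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.R.shape[1]:
        raise ValueError(
            f"feature dim {X.shape} incompatible with input matrix "
            f"{params.R.shape}")
    m = params.n_layers
    T = X.shape[0]
    units = params.W[0].shape[0]
    H = np.zeros((m, T, units))
    h_prev = np.zeros((m, units))
    for t in range(T):
        z = params.W[0] @ h_prev[0] + params.R @ X[t] + params.b[0]
        H[0, t] = np.maximum(z, 0.0)
        for k in range(1, m):
            z = params.W[k] @ h_prev[k] + params.V[k - 1] @ H[k - 1, t] \
                + params.b[k]
            H[k, t] = np.maximum(z, 0.0)
        h_prev = H[:, t]
    Y = H[m - 1] @ params.U.T + params.b[m]
    if return_cache:
        return Y, H
    return Y


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error over all frames and output axes."""
    return float(np.mean((pred - target) ** 2))


def backward(params: SRNNParams, X: np.ndarray, target: np.ndarray,
             Y: np.ndarray, H: np.ndarray) -> SRNNParams:
    """Gradients of the MSE loss via backpropagation through time.

    Returns an :class:`SRNNParams` holding dL/d(parameter) in each slot.
    """
    m, T, units = H.shape
    gW = [np.zeros_like(w) for w in params.W]
    gV = [np.zeros_like(v) for v in params.V]
    gR = np.zeros_like(params.R)
    gU = np.zeros_like(params.U)
    gb = [np.zeros_like(bi) for bi in params.b]

    dY = 2.0 * (Y - target) / Y.size
    gU += dY.T @ H[m - 1]
    gb[m] += dY.sum(axis=0)

    carry = np.zeros((m, units))        # dL/dh_k(t) from the future
    for t in range(T - 1, -1, -1):
        h_tm1 = H[:, t - 1] if t > 0 else np.zeros((m, units))
        dh_top = params.U.T @ dY[t] + carry[m - 1]
        for k in range(m - 1, -1, -1):
            dh = dh_top if k == m - 1 else dh_next
            e = dh * (H[k, t] > 0)      # relu'(z) with relu'(0)=0
            gW[k] += np.outer(e, h_tm1[k])
            gb[k] += e
            if k > 0:
                gV[k - 1] += np.outer(e, H[k - 1, t])
                dh_next = params.V[k - 1].T @ e + carry[k - 1]
            else:
                gR += np.outer(e, X[t])
            carry[k] = params.W[k].T @ e
    return SRNNParams(gW, gV, gR, gU, gb)


class _Adam:
    """Per-parameter adaptive gradient descent (Adam)."""

    def __init__(self, params: SRNNParams, config: SRNNConfig):
        self.cfg = config
        self.m = [np.zeros_like(a) for a in params.arrays()]
        self.v = [np.zeros_like(a) for a in params.arrays()]
        self.t = 0

    def step(self, params: SRNNParams, grads: SRNNParams) -> None:
        c = self.cfg
        self.t += 1
        for i, (p, g) in enumerate(zip(params.arrays(), grads.arrays())):
            self.m[i] = c.beta1 * self.m[i] + (1 - c.beta1) * g
            self.v[i] = c.beta2 * self.v[i] + (1 - c.beta2) * g * g
            mhat = self.m[i] / (1 - c.beta1 ** self.t)
            vhat = self.v[i] / (1 - c.beta2 ** self.t)
            p -= c.learning_rate * mhat / (np.sqrt(vhat) + c.eps)


def _dataset_loss(params: SRNNParams, dataset) -> float:
    """Frame-pooled MSE over a list of (X, Y) sequence pairs."""
    sq, n = 0.0, 0
    for X, Y in dataset:
        pred = forward(params, X)
        sq += float(np.sum((pred - Y) ** 2))
        n += Y.size
    return sq / n


def train(params: SRNNParams, train_set, val_set, config: SRNNConfig,
          ) -> tuple[SRNNParams, TrainingHistory]:
    """Fit by sequence-wise BPTT with Adam and early stopping.

    ``train_set``/``val_set`` are lists of (X, Y) pairs with X of shape
    (T, input_dim) and Y of shape (T, output_dim); sequences may have unequal
    length.  Returns the parameters of the epoch with minimum validation loss
    and the loss history.  Stops after ``patience`` epochs without validation
    improvement, or at ``max_epochs``.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")

    def _as_xy(pair):
        X, Y = pair
        if isinstance(X, FrameFeatureSequence):
            X = X.values
        return np.asarray(X, dtype=float), np.asarray(Y, dtype=float)

    train_set = [_as_xy(p) for p in train_set]
    val_set = [_as_xy(p) for p in val_set]
    rng = np.random.default_rng(config.seed + 1)
    opt = _Adam(params, config)
    hist = TrainingHistory()
    best = params.copy()
    best_val = np.inf
    since_best = 0
    order = np.arange(len(train_set))
    for epoch in range(config.max_epochs):
        rng.shuffle(order)
        for i in order:
            X, Yt = train_set[i]
            Y, H = forward(params, X, return_cache=True)
            opt.step(params, backward(params, X, Yt, Y, H))
        tr = _dataset_loss(params, train_set)
        va = _dataset_loss(params, val_set)
        if not np.isfinite(tr) or not np.isfinite(va):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: train={tr}, val={va}; "
                "try a smaller learning rate")
        hist.train_losses.append(tr)
        hist.val_losses.append(va)
        if va < best_val:
            best_val = va
            best = params.copy()
            hist.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                hist.stop_reason = f"early stop (patience {config.patience})"
                break
    else:
        hist.stop_reason = f"max epochs ({config.max_epochs})"
    return best, hist


def predict(params: SRNNParams, features: FrameFeatureSequence | np.ndarray
            ) -> np.ndarray:
    """Scaled-space trajectory prediction, shape (T, output_dim)."""
    return forward(params, features)


def predict_pixels(params: SRNNParams,
                   features: FrameFeatureSequence | np.ndarray,
                   target_scaler: TargetScaler,
                   reference: HyoidAnnotation,
                   box_side: float = DEFAULT_BOX_SIDE,
                   ) -> tuple[np.ndarray, list[BoundingBox]]:
    """Predict and map back to image pixels with hyoid bounding boxes.

    The scaled output is inverted through the target scaler, re-anchored at
    the reference annotation's first-frame standardized position (the model
    predicts movement, not absolute position), and mapped through the
    participant's vertebral frame.
    """
    if not target_scaler.fitted:
        raise ValueError("target scaler has not been fitted")
    scaled = forward(params, features)
    T = scaled.shape[0]
    if T > reference.n_frames:
        raise ValueError("more predicted frames than reference frames")
    y_traj = target_scaler.unscale(scaled)
    std0 = standardize_by_vertebra(reference)[0]
    std = y_traj + std0
    px = pixels_from_standardized(std, reference.c2[:T], reference.c4[:T])
    return px, trajectory_to_boxes(px, box_side)


# -- serialisation ----------------------------------------------------------

def save_params(path: str | Path, params: SRNNParams,
                config: SRNNConfig | None = None) -> None:
    """Write parameters (and optionally config) to one .npz-style archive."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    arrays = {f"W{k}": w for k, w in enumerate(params.W)}
    arrays |= {f"V{k}": v for k, v in enumerate(params.V)}
    arrays |= {"R": params.R, "U": params.U}
    arrays |= {f"b{k}": bi for k, bi in enumerate(params.b)}
    np.savez(path, **arrays)
    if config is not None:
        with zipfile.ZipFile(path, "a") as zf:
            zf.writestr("config.json", json.dumps(asdict(config)))


def load_params(path: str | Path) -> tuple[SRNNParams, SRNNConfig | None]:
    path = Path(path)
    if path.suffix != ".npz" and not path.exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path) as z:
        m = sum(1 for k in z.files if k.startswith("W"))
        W = [z[f"W{k}"] for k in range(m)]
        V = [z[f"V{k}"] for k in range(m - 1)]
        b = [z[f"b{k}"] for k in range(m + 1)]
        params = SRNNParams(W, V, z["R"], z["U"], b)
    config = None
    with zipfile.ZipFile(path) as zf:
        if "config.json" in zf.namelist():
            config = SRNNConfig(**json.loads(zf.read("config.json")))
    return params, config
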