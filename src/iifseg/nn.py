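"""A compact, fully deterministic neural-network core in NumPy.

The pipeline's three trainable components (tissue segmenter, patch analysis
net, esophagus pattern classifier) are small multi-head perceptrons over
engineered image features. Everything needed to train them lives here:
dense layers with manual backprop, the Adam optimizer, and the loss
functions used by the pipelines — generalized Dice, categorical
cross-entropy, binary cross-entropy and mean squared error.

Losses are written against pre-activation head outputs ``z`` and return
``(loss, dL/dz)`` so the chain rule through softmax/sigmoid stays in one
place. The standalone :func:`generalized_dice_loss` evaluates the published
Dice formulation on probability arrays directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import numpy as np

__all__ = [
    "MultiHeadMLP",
    "HeadSpec",
    "HeadTask",
    "Adam",
    "train_mlp",
    "generalized_dice_loss",
    "softmax",
    "sigmoid",
    "softmax_cross_entropy",
    "softmax_generalized_dice",
    "sigmoid_bce",
    "mse_loss",
]

MODEL_FORMAT_VERSION = 1


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# losses


def generalized_dice_loss(pred_probs: np.ndarray, truth_onehot: np.ndarray) -> float:
    """Generalized Dice loss with inverse-squared-volume class weights.

    ``pred_probs`` and ``truth_onehot`` carry the class axis last; all other
    axes are flattened into the pixel index. With ``r`` the reference and
    ``p`` the prediction,

        GDL = 1 - 2 * (sum_l w_l sum_n r_ln p_ln) / (sum_l w_l sum_n (r_ln + p_ln))

    where ``w_l = 1 / max(sum_n r_ln, 1)**2``. The volume clamp keeps
    classes absent from the reference from dividing by zero. The value lies
    in [0, 1]: 0 for a perfect prediction, 1 for zero overlap on every
    non-empty class.
    """
    r = np.asarray(truth_onehot, dtype=np.float64)
    p = np.asarray(pred_probs, dtype=np.float64)
    if r.shape != p.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    r = r.reshape(-1, r.shape[-1])
    p = p.reshape(-1, p.shape[-1])
    vol = r.sum(axis=0)
    w = 1.0 / np.maximum(vol, 1.0) ** 2
    num = float(np.sum(w * (r * p).sum(axis=0)))
    den = float(np.sum(w * (r + p).sum(axis=0)))
    if den == 0.0:
        return 0.0
    return 1.0 - 2.0 * num / den


def _gdl_grad_wrt_probs(p: np.ndarray, r: np.ndarray) -> np.ndarray:
    vol = r.sum(axis=0)
    w = 1.0 / np.maximum(vol, 1.0) ** 2
    a = float(np.sum(w * (r * p).sum(axis=0)))
    b = float(np.sum(w * (r + p).sum(axis=0)))
    if b == 0.0:
        return np.zeros_like(p)
    # d/dp [1 - 2A/B] = -2 (A'B - AB') / B^2, A' = w_l r, B' = w_l
    return -2.0 * (w[None, :] * r * b - a * w[None, :]) / b ** 2


def _softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    inner = (probs * dprobs).sum(axis=-1, keepdims=True)
    return probs * (dprobs - inner)


def softmax_generalized_dice(z: np.ndarray, truth_onehot: np.ndarray,
                             sample_weight: Optional[np.ndarray] = None):
    p = softmax(z)
    r = np.asarray(truth_onehot, dtype=np.float64)
    loss = generalized_dice_loss(p, r)
    dz = _softmax_backward(p, _gdl_grad_wrt_probs(p, r))
    return loss, dz


def softmax_cross_entropy(z: np.ndarray, truth_onehot: np.ndarray,
                          sample_weight: Optional[np.ndarray] = None):
    p = softmax(z)
    r = np.asarray(truth_onehot, dtype=np.float64)
    n = z.shape[0]
    if sample_weight is None:
        sw = np.ones(n)
    else:
        sw = np.asarray(sample_weight, dtype=np.float64)
    denom = max(float(sw.sum()), 1e-12)
    loss = float(-(sw * (r * np.log(np.clip(p, 1e-12, None))).sum(axis=-1)).sum() / denom)
    dz = sw[:, None] * (p - r) / denom
    return loss, dz


def sigmoid_bce(z: np.ndarray, target: np.ndarray,
                sample_weight: Optional[np.ndarray] = None):
    p = sigmoid(z)
    t = np.asarray(target, dtype=np.float64)
    n = z.shape[0]
    sw = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=np.float64)
    denom = max(float(sw.sum()), 1e-12) * z.shape[-1]
    pc = np.clip(p, 1e-12, 1 - 1e-12)
    loss = float(-(sw[:, None] * (t * np.log(pc) + (1 - t) * np.log(1 - pc))).sum() / denom)
    dz = sw[:, None] * (p - t) / denom
    return loss, dz


def mse_loss(z: np.ndarray, target: np.ndarray,
             sample_weight: Optional[np.ndarray] = None):
    t = np.asarray(target, dtype=np.float64).reshape(z.shape)
    n = z.shape[0]
    sw = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=np.float64)
    denom = max(float(sw.sum()), 1e-12) * z.shape[-1]
    diff = z - t
    loss = float((sw[:, None] * diff ** 2).sum() / denom)
    dz = 2.0 * sw[:, None] * diff / denom
    return loss, dz


LOSSES: dict[str, Callable] = {
    "generalized_dice": softmax_generalized_dice,
    "categorical_cross_entropy": softmax_cross_entropy,
    "binary_cross_entropy": sigmoid_bce,
    "mse": mse_loss,
}

_HEAD_ACTIVATIONS = {
    "generalized_dice": softmax,
    "categorical_cross_entropy": softmax,
    "binary_cross_entropy": sigmoid,
    "mse": lambda z: z,
}


# ---------------------------------------------------------------------------
# model


@dataclass
class HeadSpec:
    """An output head: name, width and the activation implied by its loss."""

    name: str
    n_out: int
    kind: str  # 'softmax' | 'sigmoid' | 'linear'


class MultiHeadMLP:
    """Shared ReLU trunk with one or more output heads.

    Head weights are zero-initialized, so an untrained model yields the
    uniform distribution under softmax (and 0.5 under sigmoid) for any
    input — a useful calibration-free starting point for tiny datasets.
    """

    def __init__(self, n_in: int, hidden: tuple[int, ...],
                 heads: list[HeadSpec], seed: int = 0,
                 feature_names: Optional[list[str]] = None):
        self.n_in = int(n_in)
        self.hidden = tuple(int(h) for h in hidden)
        self.heads = list(heads)
        self.seed = int(seed)
        self.feature_names = feature_names
        self.norm_mean = np.zeros(n_in)
        self.norm_scale = np.ones(n_in)
        rng = np.random.default_rng(seed)
        self.Ws: list[np.ndarray] = []
        self.bs: list[np.ndarray] = []
        prev = self.n_in
        for h in self.hidden:
            self.Ws.append(rng.normal(0.0, np.sqrt(2.0 / prev), size=(prev, h)))
            self.bs.append(np.zeros(h))
            prev = h
        self.head_Ws = {hs.name: np.zeros((prev, hs.n_out)) for hs in self.heads}
        self.head_bs = {hs.name: np.zeros(hs.n_out) for hs in self.heads}
        self.meta: dict = {}

    # -- normalization ----------------------------------------------------
    def set_normalization(self, X: np.ndarray) -> None:
        self.norm_mean = X.mean(axis=0)
        self.norm_scale = np.maximum(X.std(axis=0), 1e-6)

    # -- forward/backward -------------------------------------------------
    def _trunk(self, X: np.ndarray):
        a = (np.asarray(X, dtype=np.float64) - self.norm_mean) / self.norm_scale
        acts = [a]
        for W, b in zip(self.Ws, self.bs):
            a = np.maximum(a @ W + b, 0.0)
            acts.append(a)
        return acts

    def forward(self, X: np.ndarray) -> dict[str, np.ndarray]:
        """Pre-activation head outputs ``z`` for a batch of feature rows."""
        h = self._trunk(X)[-1]
        return {hs.name: h @ self.head_Ws[hs.name] + self.head_bs[hs.name]
                for hs in self.heads}

    def predict(self, X: np.ndarray) -> dict[str, np.ndarray]:
        """Activated head outputs (probabilities / regression values)."""
        zs = self.forward(X)
        out = {}
        for hs in self.heads:
            z = zs[hs.name]
            if hs.kind == "softmax":
                out[hs.name] = softmax(z)
            elif hs.kind == "sigmoid":
                out[hs.name] = sigmoid(z)
            else:
                out[hs.name] = z
        return out

    def _forward_cached(self, X: np.ndarray):
        acts = self._trunk(X)
        zs = {hs.name: acts[-1] @ self.head_Ws[hs.name] + self.head_bs[hs.name]
              for hs in self.heads}
        return acts, zs

    def _backward(self, acts, dzs: dict[str, np.ndarray]):
        h = acts[-1]
        gW = [np.zeros_like(W) for W in self.Ws]
        gb = [np.zeros_like(b) for b in self.bs]
        ghW, ghb = {}, {}
        dh = np.zeros_like(h)
        for hs in self.heads:
            dz = dzs.get(hs.name)
            if dz is None:
                ghW[hs.name] = np.zeros_like(self.head_Ws[hs.name])
                ghb[hs.name] = np.zeros_like(self.head_bs[hs.name])
                continue
            ghW[hs.name] = h.T @ dz
            ghb[hs.name] = dz.sum(axis=0)
            dh = dh + dz @ self.head_Ws[hs.name].T
        da = dh
        for i in range(len(self.Ws) - 1, -1, -1):
            da = da * (acts[i + 1] > 0)
            gW[i] = acts[i].T @ da
            gb[i] = da.sum(axis=0)
            da = da @ self.Ws[i].T
        return gW, gb, ghW, ghb

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {"format_version": np.array([MODEL_FORMAT_VERSION]),
                  "n_in": np.array([self.n_in]),
                  "hidden": np.array(self.hidden, dtype=np.int64),
                  "seed": np.array([self.seed]),
                  "norm_mean": self.norm_mean, "norm_scale": self.norm_scale}
        head_desc = [f"{hs.name}:{hs.n_out}:{hs.kind}" for hs in self.heads]
        arrays["head_desc"] = np.array(head_desc)
        for i, (W, b) in enumerate(zip(self.Ws, self.bs)):
            arrays[f"W{i}"], arrays[f"b{i}"] = W, b
        for hs in self.heads:
            arrays[f"headW_{hs.name}"] = self.head_Ws[hs.name]
            arrays[f"headb_{hs.name}"] = self.head_bs[hs.name]
        for k, v in self.meta.items():
            arrays[f"meta_{k}"] = np.asarray(v)
        np.savez(Path(path), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "MultiHeadMLP":
        data = np.load(Path(path), allow_pickle=False)
        if int(data["format_version"][0]) != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        heads = []
        for desc in data["head_desc"]:
            name, n_out, kind = str(desc).split(":")
            heads.append(HeadSpec(name, int(n_out), kind))
        model = cls(int(data["n_in"][0]), tuple(data["hidden"].tolist()),
                    heads, seed=int(data["seed"][0]))
        model.norm_mean = data["norm_mean"]
        model.norm_scale = data["norm_scale"]
        model.Ws = [data[f"W{i}"] for i in range(len(model.hidden))]
        model.bs = [data[f"b{i}"] for i in range(len(model.hidden))]
        for hs in heads:
            model.head_Ws[hs.name] = data[f"headW_{hs.name}"]
            model.head_bs[hs.name] = data[f"headb_{hs.name}"]
        model.meta = {k[len("meta_"):]: data[k] for k in data.files if k.startswith("meta_")}
        return model


class Adam:
    """Adaptive moment estimation over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class HeadTask:
    """Training task for one head: loss name, targets, optional per-sample
    weights, and the head's weight in the total loss."""

    loss: str
    target: np.ndarray
    sample_weight: Optional[np.ndarray] = None
    loss_weight: float = 1.0


def train_mlp(model: MultiHeadMLP, X: np.ndarray, tasks: dict[str, HeadTask],
              epochs: int = 30, batch_size: int = 256, lr: float = 1e-2,
              seed: int = 0, set_normalization: bool = True) -> list[float]:
    """Minibatch Adam training; returns the per-epoch mean total loss.

    Fully deterministic for a fixed seed: shuffling uses its own PCG64
    stream and all arithmetic is plain NumPy.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if set_normalization:
        model.set_normalization(X)
    params = (model.Ws + model.bs
              + [model.head_Ws[h.name] for h in model.heads]
              + [model.head_bs[h.name] for h in model.heads])
    opt = Adam(params, lr=lr)
    rng = np.random.default_rng(seed)
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            acts, zs = model._forward_cached(X[idx])
            total, dzs = 0.0, {}
            for name, task in tasks.items():
                loss_fn = LOSSES[task.loss]
                sw = None if task.sample_weight is None else task.sample_weight[idx]
                loss, dz = loss_fn(zs[name], np.asarray(task.target)[idx], sw)
                total += task.loss_weight * loss
                dzs[name] = task.loss_weight * dz
            gW, gb, ghW, ghb = model._backward(acts, dzs)
            grads = (gW + gb + [ghW[h.name] for h in model.heads]
                     + [ghb[h.name] for h in model.heads])
            opt.step(grads)
            epoch_loss += total
            n_batches += 1
        history.append(epoch_loss / max(n_batches, 1))
    return history
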