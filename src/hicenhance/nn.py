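"""The three-layer valid-convolution network and its training loop.

The mapping from a low-depth window ``X`` to a high-depth window is

    F1(X) = max(0, w1 * X + b1)      pattern extraction, n1 filters f1 x f1
    F2(X) = max(0, w2 * F1(X) + b2)  non-linear 1x1 channel mapping
    F3(X) = w3 * F2(X) + b3          linear recombination, one f3 x f3 filter

where ``*`` is valid cross-correlation (no zero padding anywhere), so each
layer shrinks the window by ``f - 1`` bins per axis and one output cell sees
an ``(f1 + f2 + f3 - 2)``-wide input footprint.  Defaults n1 = n2 = 16,
f1 = 5, f2 = 1 and f3 = 9 consume 12 bins of border in total (40 -> 28) and
give a 13 x 13 receptive field.  Weights start Glorot-uniform, biases at
zero, and training minimises mean squared error by mini-batch stochastic
gradient descent with hand-derived gradients; all convolutions (forward and
both gradient passes) are evaluated exactly through zero-padded FFTs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import scipy.fft as sfft

from .contacts import ContactMatrix
from .patches import Patch, PatchGeometry, extract_patches, merge_patches

__all__ = [
    "ConvNetParams",
    "TrainConfig",
    "LossHistory",
    "conv2d_valid",
    "forward",
    "receptive_field",
    "mse_loss",
    "init_glorot",
    "train",
    "enhance",
    "save_params",
    "load_params",
]

# ---------------------------------------------------------------------------
# convolution primitive and its gradients
#
# All three quantities (forward output, weight gradient, input gradient) are
# linear correlations/convolutions and are evaluated through zero-padded
# 2-D FFTs of the layer-input size (H, W): with that transform size the
# circular products below contain the exact linear results with no
# wrap-around in the regions that are kept.
# ---------------------------------------------------------------------------

_IM2COL_MAX = 200  # use the direct patch-matrix path when C * f * f is this small


def _im2col(x: np.ndarray, f: int) -> np.ndarray:
    """(B, C, H, W) -> (B*H'*W', C*f*f) patch matrix, H' = H - f + 1."""
    win = np.lib.stride_tricks.sliding_window_view(x, (f, f), axis=(2, 3))
    b, c, hh, ww, _, _ = win.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b * hh * ww, c * f * f)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched valid cross-correlation: (B,C,H,W) x (K,C,f,f) -> (B,K,H',W')."""
    bs, c, h, wd = x.shape
    k, _, f, _ = w.shape
    if f == 1:  # pointwise convolution is a pure channel mixing
        xm = x.transpose(0, 2, 3, 1).reshape(-1, c)
        out = (xm @ w[:, :, 0, 0].T).reshape(bs, h, wd, k).transpose(0, 3, 1, 2)
        return out + b.reshape(1, -1, 1, 1)
    if c * f * f <= _IM2COL_MAX:
        col = _im2col(x, f)
        hh = h - f + 1
        out = (col @ w.reshape(k, -1).T).reshape(bs, hh, wd - f + 1, k).transpose(0, 3, 1, 2)
        return out + b.reshape(1, -1, 1, 1)
    fx = sfft.rfft2(x, s=(h, wd))
    fw = sfft.rfft2(w, s=(h, wd))
    # circular correlation summed over channels; rows/cols 0..H-f are wrap-free
    out = sfft.irfft2(np.einsum("bcij,kcij->bkij", fx, fw.conj()), s=(h, wd))
    return np.ascontiguousarray(out[:, :, : h - f + 1, : wd - f + 1]) + b.reshape(1, -1, 1, 1)


def _conv_backward(
    x: np.ndarray, w: np.ndarray, dout: np.ndarray, need_dx: bool = True
) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    """Gradients of a valid cross-correlation w.r.t. input, weights, biases."""
    k, c, f, _ = w.shape
    bs, _, h, wd = x.shape
    db = dout.sum(axis=(0, 2, 3))
    dom = dout.transpose(0, 2, 3, 1).reshape(-1, k)  # (B*H'*W', K)
    if f == 1:
        xm = x.transpose(0, 2, 3, 1).reshape(-1, c)
        dw = (dom.T @ xm)[:, :, None, None]
        dx = None
        if need_dx:
            dx = (dom @ w[:, :, 0, 0]).reshape(bs, h, wd, c).transpose(0, 3, 1, 2)
        return dx, dw, db
    if c * f * f <= _IM2COL_MAX:
        dw = (dom.T @ _im2col(x, f)).reshape(k, c, f, f)
        if not need_dx:
            return None, dw, db
    else:
        fx = sfft.rfft2(x, s=(h, wd))
        fd = sfft.rfft2(dout, s=(h, wd))
        # dw[k,c,u,v] = sum_b corr(x[b,c], dout[b,k])[u,v]; valid for u,v < f
        dw = sfft.irfft2(np.einsum("bcij,bkij->kcij", fx, fd.conj()), s=(h, wd))[:, :, :f, :f]
        if not need_dx:
            return None, dw, db
    # dx[b,c] = sum_k full-conv(dout[b,k], w[k,c]); linear size H'+f-1 == H
    fd = sfft.rfft2(dout, s=(h, wd))
    fw = sfft.rfft2(w, s=(h, wd))
    dx = sfft.irfft2(np.einsum("bkij,kcij->bcij", fd, fw), s=(h, wd))
    return dx, dw, db


def conv2d_valid(x: np.ndarray, filters: np.ndarray, biases: np.ndarray) -> np.ndarray:
    """Valid cross-correlation of one sample.

    Parameters
    ----------
    x : (C, H, W) array
    filters : (K, C, f, f) array
    biases : (K,) array

    Returns
    -------
    (K, H - f + 1, W - f + 1) array with
    ``out[k, y, x] = b_k + sum_{c,u,v} filters[k,c,u,v] * input[c, y+u, x+v]``.
    """
    x = np.asarray(x, dtype=float)
    filters = np.asarray(filters, dtype=float)
    biases = np.asarray(biases, dtype=float)
    if x.ndim != 3 or filters.ndim != 4:
        raise ValueError("expected input (C,H,W) and filters (K,C,f,f)")
    k, c, f, f2 = filters.shape
    if f != f2 or f % 2 == 0:
        raise ValueError("filters must be square with odd side")
    if c != x.shape[0]:
        raise ValueError(f"channel mismatch: input has {x.shape[0]}, filters expect {c}")
    if f > min(x.shape[1], x.shape[2]):
        raise ValueError(
            f"filter side {f} exceeds input spatial size {x.shape[1]}x{x.shape[2]}"
        )
    return _conv_forward(x[None], filters, biases)[0]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConvNetParams:
    """All learnable parameters Theta = {w1, w2, w3, b1, b2, b3}."""

    w1: np.ndarray  # (n1, 1, f1, f1)
    b1: np.ndarray  # (n1,)
    w2: np.ndarray  # (n2, n1, f2, f2)
    b2: np.ndarray  # (n2,)
    w3: np.ndarray  # (1, n2, f3, f3)
    b3: np.ndarray  # (1,)

    def __post_init__(self) -> None:
        for name in ("w1", "w2", "w3"):
            w = getattr(self, name)
            if w.ndim != 4 or w.shape[2] != w.shape[3] or w.shape[2] % 2 == 0:
                raise ValueError(f"{name}: filters must be 4-d with odd square side")
        if self.w2.shape[1] != self.w1.shape[0] or self.w3.shape[1] != self.w2.shape[0]:
            raise ValueError("channel counts of consecutive layers do not match")

    @property
    def filter_sizes(self) -> tuple[int, int, int]:
        return self.w1.shape[2], self.w2.shape[2], self.w3.shape[2]

    @property
    def padding_consumed(self) -> int:
        """Total border loss in bins: sum of (f - 1) over the three layers."""
        f1, f2, f3 = self.filter_sizes
        return (f1 - 1) + (f2 - 1) + (f3 - 1)

    def copy(self) -> "ConvNetParams":
        return ConvNetParams(*(a.copy() for a in self._arrays()))

    def _arrays(self) -> tuple[np.ndarray, ...]:
        return self.w1, self.b1, self.w2, self.b2, self.w3, self.b3

    def n_parameters(self) -> int:
        return int(sum(a.size for a in self._arrays()))


def receptive_field(params: ConvNetParams) -> int:
    """Side of the input footprint of one output cell: f1 + f2 + f3 - 2."""
    f1, f2, f3 = params.filter_sizes
    return f1 + f2 + f3 - 2


def init_glorot(
    n1: int = 16,
    f1: int = 5,
    n2: int = 16,
    f2: int = 1,
    f3: int = 9,
    seed: int | None = 0,
) -> ConvNetParams:
    """Glorot-uniform weights, zero biases.

    Each weight of a layer with ``C`` input channels, ``K`` filters and side
    ``f`` is drawn uniformly from ``[-a, a]`` with
    ``a = sqrt(6 / (fan_in + fan_out))``, ``fan_in = C f^2``,
    ``fan_out = K f^2``.  The same seed reproduces the same parameters.
    """
    rng = np.random.default_rng(seed)

    def layer(k: int, c: int, f: int) -> np.ndarray:
        a = np.sqrt(6.0 / (c * f * f + k * f * f))
        return rng.uniform(-a, a, size=(k, c, f, f))

    return ConvNetParams(
        w1=layer(n1, 1, f1),
        b1=np.zeros(n1),
        w2=layer(n2, n1, f2),
        b2=np.zeros(n2),
        w3=layer(1, n2, f3),
        b3=np.zeros(1),
    )


# ---------------------------------------------------------------------------
# forward / loss / backward
# ---------------------------------------------------------------------------

def _forward_batch(params: ConvNetParams, x: np.ndarray, keep: bool = False):
    """Forward pass on (B, 1, N, N); optionally keep activations for backprop."""
    z1 = _conv_forward(x, params.w1, params.b1)
    h1 = np.maximum(z1, 0.0)
    z2 = _conv_forward(h1, params.w2, params.b2)
    h2 = np.maximum(z2, 0.0)
    out = _conv_forward(h2, params.w3, params.b3)
    if keep:
        return out, (x, z1, h1, z2, h2)
    return out


def forward(params: ConvNetParams, x: np.ndarray) -> np.ndarray:
    """Predict one high-depth window from one low-depth window.

    ``x`` may be ``(N, N)`` or ``(1, N, N)``; the result is
    ``(N - padding, N - padding)`` with ReLU after layers 1 and 2 only.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3 or x.shape[0] != 1:
        raise ValueError("expected a single-channel (N, N) or (1, N, N) window")
    n = x.shape[1]
    if n != x.shape[2]:
        raise ValueError(f"window must be square, got {x.shape[1]}x{x.shape[2]}")
    if n - params.padding_consumed < 1:
        raise ValueError(
            f"window side {n} too small for filters {params.filter_sizes} "
            f"(needs >= {params.padding_consumed + 1})"
        )
    return _forward_batch(params, x[None])[0, 0]


def _backward_batch(params: ConvNetParams, cache, dout: np.ndarray):
    x, z1, h1, z2, h2 = cache
    dh2, dw3, db3 = _conv_backward(h2, params.w3, dout)
    dz2 = dh2 * (z2 > 0)
    dh1, dw2, db2 = _conv_backward(h1, params.w2, dz2)
    dz1 = dh1 * (z1 > 0)
    _, dw1, db1 = _conv_backward(x, params.w1, dz1, need_dx=False)
    return dw1, db1, dw2, db2, dw3, db3


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean over all cells of the squared difference."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean((pred - target) ** 2))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainConfig:
    """Optimiser settings for mini-batch SGD on the MSE objective.

    Defaults are tuned for standardised windows (see
    :class:`hicenhance.model.ContactEnhancer`): learning rate 1e-2 with
    classical momentum 0.9, batches of 256 windows, at most 300 epochs with
    early stopping once the validation MSE has not improved for
    ``patience`` epochs.  On raw un-standardised counts a much smaller
    learning rate (~1e-4) is needed for stability.
    ``validation_fraction`` is used only when no explicit validation set is
    supplied.
    """

    learning_rate: float = 1e-2
    batch_size: int = 256
    max_epochs: int = 300
    seed: int = 0
    validation_fraction: float = 0.1
    patience: int = 20
    momentum: float = 0.9

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in [0, 1)")


@dataclasses.dataclass
class LossHistory:
    """Per-epoch training and validation MSE."""

    train: list[float]
    validation: list[float]
    best_epoch: int

    @property
    def n_epochs(self) -> int:
        return len(self.train)


def _stack(patches: list[Patch]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.input for p in patches])[:, None].astype(float)
    if any(p.target is None for p in patches):
        raise ValueError("training patches must carry targets")
    y = np.stack([p.target for p in patches])[:, None].astype(float)
    return x, y


def train(
    patches: list[Patch],
    cfg: TrainConfig = TrainConfig(),
    geom: PatchGeometry = PatchGeometry(),
    validation_patches: list[Patch] | None = None,
    params: ConvNetParams | None = None,
) -> tuple[ConvNetParams, LossHistory]:
    """Fit the network on paired windows by mini-batch SGD.

    Returns the parameters from the epoch with the lowest validation MSE
    together with the full loss history.  Fully reproducible given
    ``cfg.seed``: initialisation, the validation split (when carved from
    ``patches``) and batch shuffling all derive from it.

    Raises on an empty patch list and on divergence (non-finite loss), the
    latter with a hint to lower the learning rate.
    """
    if not patches:
        raise ValueError("no training patches")
    rng = np.random.default_rng(cfg.seed)
    if params is None:
        f_geom = {"f1": 5, "f2": 1, "f3": 9}
        if (f_geom["f1"] - 1) + (f_geom["f2"] - 1) + (f_geom["f3"] - 1) != geom.padding:
            raise ValueError(
                f"default filter sizes consume 12 bins of border but geometry has "
                f"padding={geom.padding}; pass explicit params"
            )
        params = init_glorot(seed=rng.integers(2**31))
    if params.padding_consumed != geom.padding:
        raise ValueError(
            f"filters consume {params.padding_consumed} bins but geometry has "
            f"padding={geom.padding}"
        )

    if validation_patches is None and cfg.validation_fraction > 0 and len(patches) > 1:
        idx = rng.permutation(len(patches))
        n_val = max(1, int(round(cfg.validation_fraction * len(patches))))
        val_idx, train_idx = idx[:n_val], idx[n_val:]
        validation_patches = [patches[i] for i in val_idx]
        patches = [patches[i] for i in train_idx]
    x, y = _stack(patches)
    xv, yv = _stack(validation_patches) if validation_patches else (None, None)

    vel = [np.zeros_like(a) for a in params._arrays()]
    hist_train: list[float] = []
    hist_val: list[float] = []
    best = params.copy()
    best_val = np.inf
    best_epoch = 0
    since_best = 0
    n = x.shape[0]
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for s in range(0, n, cfg.batch_size):
            sel = order[s : s + cfg.batch_size]
            xb, yb = x[sel], y[sel]
            out, cache = _forward_batch(params, xb, keep=True)
            resid = out - yb
            with np.errstate(over="ignore"):  # overflow -> inf is caught below
                batch_loss = float(np.mean(resid**2))
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    "training diverged (non-finite loss); try a smaller learning rate"
                )
            epoch_loss += batch_loss * len(sel)
            grads = _backward_batch(params, cache, 2.0 * resid / resid.size)
            for v, a, g in zip(vel, params._arrays(), grads):
                v *= cfg.momentum
                v -= cfg.learning_rate * g
                a += v
        hist_train.append(epoch_loss / n)
        if xv is not None:
            val_loss = float(np.mean((_forward_batch(params, xv) - yv) ** 2))
        else:
            val_loss = hist_train[-1]
        hist_val.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best = params.copy()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    return best, LossHistory(hist_train, hist_val, best_epoch)


# ---------------------------------------------------------------------------
# whole-chromosome enhancement
# ---------------------------------------------------------------------------

def enhance(
    low: ContactMatrix,
    params: ConvNetParams,
    geom: PatchGeometry = PatchGeometry(),
) -> ContactMatrix:
    """Enhance a whole low-depth chromosome matrix.

    Extracts overlapping input windows, runs the network on each, and merges
    the predicted windows back into a chromosome-wide symmetric matrix, with
    the low-depth input filling the never-covered border frame and the
    out-of-band region.
    """
    patches = extract_patches(low, None, geom)
    x = np.stack([p.input for p in patches])[:, None].astype(float)
    preds = _forward_batch(params, x)
    for p, pred in zip(patches, preds):
        p.target = pred[0]
    return merge_patches(patches, low.n_bins, geom, fallback=low)


# ---------------------------------------------------------------------------
# serialization: one self-describing .npz file
# ---------------------------------------------------------------------------

def save_params(
    params: ConvNetParams,
    path: str | Path,
    geom: PatchGeometry = PatchGeometry(),
    meta: dict | None = None,
) -> None:
    header = {
        "format": "hicenhance-convnet-v1",
        "geometry": {
            "N": geom.N,
            "padding": geom.padding,
            "stride": geom.stride,
            "max_dist_bins": geom.max_dist_bins,
        },
        "filter_sizes": list(params.filter_sizes),
        **(meta or {}),
    }
    arrays = dict(zip(("w1", "b1", "w2", "b2", "w3", "b3"), params._arrays()))
    np.savez(path, meta=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_params(path: str | Path) -> tuple[ConvNetParams, PatchGeometry, dict]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]))
        params = ConvNetParams(
            npz["w1"], npz["b1"], npz["w2"], npz["b2"], npz["w3"], npz["b3"]
        )
    g = meta["geometry"]
    geom = PatchGeometry(g["N"], g["padding"], g["stride"], g["max_dist_bins"])
    return params, geom, meta
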