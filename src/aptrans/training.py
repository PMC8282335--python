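"""Joint loss, hand-derived reverse-mode gradients, ADAM updates and the
mini-batch training loop with validation-based early stopping.

The total loss is the unweighted sum of the batch-mean translation MSE and
the batch-mean classification cross-entropy.  Gradients are computed by
exact backpropagation through the fully connected heads and through time
across the stacked LSTM layers; tests verify them against central finite
differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .network import ForwardCache, NetParams, forward_cached

__all__ = [
    "TrainConfig",
    "OptimizerState",
    "mse_loss",
    "cross_entropy",
    "total_loss",
    "adam_update",
    "loss_and_gradients",
    "train",
]

_CLIP = 1e-7  # probability clip for the cross-entropy log


@dataclass
class TrainConfig:
    alpha: float = 0.001       # ADAM learning rate
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 64
    epochs: int = 300
    dropout: float = 0.2
    patience: int = 20         # early-stop patience on validation total loss
    min_delta: float = 0.0     # improvement below this does not reset patience
    eval_every: int = 1        # evaluate train/val metrics every N epochs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("learning rate must be > 0")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("momentum coefficients must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


@dataclass
class OptimizerState:
    """Per-parameter first/second moments, zero-initialized; t counts steps."""

    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0

    @classmethod
    def for_params(cls, params: dict) -> "OptimizerState":
        return cls(
            m={k: np.zeros_like(a) for k, a in params.items()},
            v={k: np.zeros_like(a) for k, a in params.items()},
            t=0,
        )


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def mse_loss(predicted: np.ndarray, target: np.ndarray) -> float:
    """Mean squared difference over the samples of one trace (or a batch)."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float(np.mean((p - t) ** 2))


def cross_entropy(label: float, probability: float) -> float:
    """Binary cross-entropy; the probability is clipped to [1e-7, 1-1e-7]."""
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    p = min(max(float(probability), _CLIP), 1.0 - _CLIP)
    return float(-(label * math.log(p) + (1.0 - label) * math.log(1.0 - p)))


def total_loss(
    predicted: np.ndarray,
    targets: np.ndarray,
    labels: Sequence[int],
    probabilities: Sequence[float],
) -> float:
    """Batch-mean cross-entropy plus batch-mean translation MSE."""
    preds = np.atleast_2d(np.asarray(predicted, dtype=float))
    targs = np.atleast_2d(np.asarray(targets, dtype=float))
    labels = np.atleast_1d(labels)
    probs = np.atleast_1d(probabilities)
    if len(labels) == 0:
        raise ValueError("empty batch")
    mse = np.mean([mse_loss(p, t) for p, t in zip(preds, targs)])
    ce = np.mean([cross_entropy(int(y), p) for y, p in zip(labels, probs)])
    return float(mse + ce)


# ---------------------------------------------------------------------------
# ADAM
# ---------------------------------------------------------------------------

def adam_update(
    params: dict,
    gradients: dict,
    state: OptimizerState,
    config: TrainConfig,
) -> OptimizerState:
    """One ADAM step, in place on the parameter arrays.

    m_t = (1-b1) g + b1 m_{t-1};  v_t = (1-b2) g^2 + b2 v_{t-1};
    bias-corrected by (1 - b1^t), (1 - b2^t);
    theta <- theta - alpha * m_hat / (sqrt(v_hat) + eps).
    """
    state.t += 1
    b1, b2 = config.beta1, config.beta2
    c1 = 1.0 - b1 ** state.t
    c2 = 1.0 - b2 ** state.t
    for name, theta in params.items():
        g = gradients[name]
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient for parameter {name!r}")
        m = state.m[name]
        v = state.v[name]
        m *= b1
        m += (1.0 - b1) * g
        v *= b2
        v += (1.0 - b2) * g * g
        theta -= config.alpha * (m / c1) / (np.sqrt(v / c2) + config.eps)
    return state


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def _lstm_backward(layer_cache: dict, lp, dH: np.ndarray):
    """Backprop through time for one LSTM layer.

    ``dH`` is the gradient w.r.t. the layer's hidden-state sequence
    (B, T, H).  Returns (dWx, dWh, db, dInp).
    """
    from ._lstm_kernels import lstm_backward_kernel

    inp = layer_cache["inp"]
    F, I, S, O = layer_cache["F"], layer_cache["I"], layer_cache["S"], layer_cache["O"]
    C, tC, Hs = layer_cache["C"], layer_cache["tanhC"], layer_cache["H"]
    B, T, H = dH.shape
    dz_all = np.empty((B, T, 4 * H), dtype=inp.dtype)
    lstm_backward_kernel(np.ascontiguousarray(dH.astype(inp.dtype, copy=False)),
                         F, I, S, O, C, tC,
                         np.ascontiguousarray(lp.Wh.T), dz_all)
    BT = B * T
    in_sz = inp.shape[2]
    dz2 = dz_all.reshape(BT, 4 * H)
    dWx = inp.reshape(BT, in_sz).T @ dz2
    Hprev = np.concatenate([np.zeros((B, 1, H)), Hs[:, :-1]], axis=1)
    dWh = Hprev.reshape(BT, H).T @ dz2
    db = dz2.sum(axis=0)
    dInp = (dz2 @ lp.Wx.T).reshape(B, T, in_sz)
    return dWx, dWh, db, dInp


def loss_and_gradients(
    params: NetParams,
    x: np.ndarray,
    y_target: np.ndarray,
    labels: Optional[np.ndarray],
    training: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict, dict]:
    """Forward + exact backward over one mini-batch.

    Returns (metrics, gradients); metrics has keys mse, ce, total.  For a
    translation-only network (no classification head) the cross-entropy
    term is absent and total equals the MSE.
    """
    dtype = params.lstm[0].Wx.dtype
    x = np.atleast_2d(np.asarray(x, dtype=dtype))
    y_target = np.atleast_2d(np.asarray(y_target, dtype=dtype))
    B, T = x.shape
    y_trans, p_clf, cache = forward_cached(x, params, training=training, rng=rng)
    y_trans = np.atleast_2d(y_trans)

    resid = y_trans - y_target
    mse = float(np.mean(resid ** 2))
    metrics = {"mse": mse}
    dY = 2.0 * resid / (B * T)

    grads: dict = {}
    da0 = np.zeros_like(cache.a0)

    # translation head
    tr = params.trans
    a1d = cache.trans["a1d"]; a1 = cache.trans["a1"]
    grads["trans.W2"] = a1d.T @ dY
    grads["trans.b2"] = dY.sum(axis=0)
    da1d = dY @ tr.W2.T
    m = cache.masks.get("trans")
    da1 = da1d if m is None else da1d * m
    dz1 = da1 * (a1 > 0)
    grads["trans.W1"] = cache.a0.T @ dz1
    grads["trans.b1"] = dz1.sum(axis=0)
    da0 += dz1 @ tr.W1.T

    if params.clf is not None:
        if labels is None:
            raise ValueError("labels required for a multitask network")
        y = np.asarray(labels, dtype=dtype).reshape(B)
        p = np.clip(cache.clf["p"], _CLIP, 1.0 - _CLIP)
        ce = float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))
        metrics["ce"] = ce
        dlogit = ((cache.clf["p"] - y) / B)[:, None]
        cl = params.clf
        a1cd = cache.clf["a1d"]; a1c = cache.clf["a1"]
        grads["clf.W2"] = a1cd.T @ dlogit
        grads["clf.b2"] = dlogit.sum(axis=0)
        da1cd = dlogit @ cl.W2.T
        mc = cache.masks.get("clf")
        da1c = da1cd if mc is None else da1cd * mc
        dz1c = da1c * (a1c > 0)
        grads["clf.W1"] = cache.a0.T @ dz1c
        grads["clf.b1"] = dz1c.sum(axis=0)
        da0 += dz1c @ cl.W1.T
        metrics["total"] = mse + ce
    else:
        metrics["total"] = mse

    # into the stacked LSTM
    H = params.lstm[-1].hidden_size
    dSeq = da0.reshape(B, T, H)
    for li in range(len(params.lstm) - 1, -1, -1):
        mask = cache.masks.get(f"lstm{li}")
        if mask is not None:
            dSeq = dSeq * mask
        dWx, dWh, db, dInp = _lstm_backward(cache.layers[li], params.lstm[li], dSeq)
        grads[f"lstm{li}.Wx"] = dWx
        grads[f"lstm{li}.Wh"] = dWh
        grads[f"lstm{li}.b"] = db
        dSeq = dInp
    return metrics, grads


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _epoch_eval(params, X, Y, labels, batch: int = 256) -> dict:
    """Dropout-off metrics over a dataset."""
    n = len(X)
    mse_sum = 0.0
    ce_sum = 0.0
    correct = 0
    has_clf = params.clf is not None
    for lo in range(0, n, batch):
        xb = X[lo:lo + batch]
        yb = Y[lo:lo + batch]
        yt, pc = forward_cached(xb, params, training=False)[:2]
        yt = np.atleast_2d(yt)
        mse_sum += float(np.sum(np.mean((yt - yb) ** 2, axis=1)))
        if has_clf:
            lb = labels[lo:lo + batch].astype(float)
            p = np.clip(np.atleast_1d(pc), _CLIP, 1.0 - _CLIP)
            ce_sum += float(np.sum(-(lb * np.log(p) + (1 - lb) * np.log(1 - p))))
            correct += int(np.sum((p >= 0.5).astype(int) == lb.astype(int)))
    out = {"mse": mse_sum / n}
    if has_clf:
        out["ce"] = ce_sum / n
        out["acc"] = correct / n
        out["total"] = out["mse"] + out["ce"]
    else:
        out["total"] = out["mse"]
    return out


def train(
    data: dict,
    params: NetParams,
    config: TrainConfig,
    verbose: bool = False,
) -> tuple[NetParams, list]:
    """Mini-batch training with ADAM and validation-based early stopping.

    ``data`` holds normalized arrays: X_train/Y_train/labels_train and the
    corresponding validation arrays (labels may be None for a
    translation-only network).  Runs at most ``config.epochs`` epochs;
    stops early when the validation total loss has not improved for
    ``config.patience`` epochs, and returns the parameters from the best
    validation epoch together with the per-epoch history.
    """
    X, Y = data["X_train"], data["Y_train"]
    lab = data.get("labels_train")
    Xv, Yv = data["X_val"], data["Y_val"]
    labv = data.get("labels_val")
    if len(Xv) == 0:  # tiny smoke runs: monitor on the training set
        warnings.warn("validation split is empty; monitoring training loss")
        Xv, Yv, labv = X, Y, lab
    rng = np.random.default_rng(config.seed)
    flat = params.flat()
    state = OptimizerState.for_params(flat)
    n = len(X)
    best = {"loss": np.inf, "params": params.copy(), "epoch": -1}
    history = []
    since_best = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            metrics, grads = loss_and_gradients(
                params, X[idx], Y[idx],
                None if lab is None else lab[idx],
                training=True, rng=rng,
            )
            if not np.isfinite(metrics["total"]):
                raise FloatingPointError(
                    f"training loss diverged at epoch {epoch}"
                )
            adam_update(flat, grads, state, config)
        if (epoch + 1) % config.eval_every and epoch != config.epochs - 1:
            continue
        tr_m = _epoch_eval(params, X, Y, lab)
        va_m = _epoch_eval(params, Xv, Yv, labv)
        rec = {"epoch": epoch}
        rec.update({f"train_{k}": v for k, v in tr_m.items()})
        rec.update({f"val_{k}": v for k, v in va_m.items()})
        history.append(rec)
        if verbose:
            print(f"epoch {epoch:3d} train {tr_m['total']:.5f} "
                  f"val {va_m['total']:.5f}")
        if va_m["total"] < best["loss"] - config.min_delta:
            best = {"loss": va_m["total"], "params": params.copy(), "epoch": epoch}
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    return best["params"], history
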