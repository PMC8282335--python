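"""Multitask recurrent network: two stacked LSTM layers scanning the
701-sample AP sequence, feeding two fully connected heads — a linear
translation head producing the 701-sample adult AP, and a sigmoid
classification head producing the drug probability.

Everything is plain numpy with float64 parameters.  The forward pass is
written so that an exact hand-derived reverse-mode backward pass (in
:mod:`aptrans.training`) can consume the cached intermediates.

LSTM cell (per time step t, gate order f, i, s, o):

    F_t = sigmoid(w_f x_t + w_f' h_{t-1} + b_f)        forget gate
    I_t = sigmoid(w_i x_t + w_i' h_{t-1} + b_i)        input gate
    S_t = tanh   (w_s x_t + w_s' h_{t-1} + b_s)        candidate state
    C_t = F_t * C_{t-1} + I_t * S_t                    cell state
    O_t = sigmoid(w_o x_t + w_o' h_{t-1} + b_o)        output gate
    h_t = O_t * tanh(C_t)                              hidden state

The heads consume the *full* flattened hidden sequence h_1..h_m of the
second layer.  Dropout (inverted scaling) is applied to the LSTM output
sequences and the fully connected hidden activations during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "NetConfig",
    "LSTMParams",
    "FCParams",
    "NetParams",
    "init_params",
    "sigmoid",
    "lstm_step",
    "lstm_scan",
    "fc_forward",
    "forward",
    "forward_cached",
    "save_params",
    "load_params",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class NetConfig:
    window: int = 701
    hidden_size: int = 64
    num_lstm_layers: int = 2
    trans_hidden: int = 256
    clf_hidden: int = 64
    dropout: float = 0.2
    include_classifier: bool = True
    dtype: str = "float64"  # "float32" roughly halves training time

    def __post_init__(self) -> None:
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.num_lstm_layers not in (1, 2):
            raise ValueError("one or two stacked LSTM layers supported")


@dataclass
class LSTMParams:
    """Gate weights applied to (x_t, h_{t-1}) plus biases; gate order f,i,s,o."""

    Wx: np.ndarray  # (input_size, 4H)
    Wh: np.ndarray  # (H, 4H)
    b: np.ndarray   # (4H,)

    @property
    def hidden_size(self) -> int:
        return self.Wh.shape[0]

    @property
    def input_size(self) -> int:
        return self.Wx.shape[0]

    def check(self) -> None:
        H = self.hidden_size
        if self.Wx.shape[1] != 4 * H or self.Wh.shape != (H, 4 * H) or self.b.shape != (4 * H,):
            raise ValueError("inconsistent LSTM parameter shapes")


@dataclass
class FCParams:
    """One ReLU hidden layer followed by a linear (or sigmoid) output layer."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    def check(self, n_features: int) -> None:
        if self.W1.shape[0] != n_features or self.W1.shape[1] != self.b1.shape[0]:
            raise ValueError("inconsistent FC layer-1 shapes")
        if self.W2.shape[0] != self.W1.shape[1] or self.W2.shape[1] != self.b2.shape[0]:
            raise ValueError("inconsistent FC layer-2 shapes")


@dataclass
class NetParams:
    config: NetConfig
    lstm: list  # list[LSTMParams], stacked
    trans: FCParams
    clf: Optional[FCParams] = None

    def n_features(self) -> int:
        return self.config.window * self.lstm[-1].hidden_size

    def flat(self) -> dict:
        """Named view of every parameter array (shared memory)."""
        out = {}
        for li, lp in enumerate(self.lstm):
            out[f"lstm{li}.Wx"] = lp.Wx
            out[f"lstm{li}.Wh"] = lp.Wh
            out[f"lstm{li}.b"] = lp.b
        for head, fp in (("trans", self.trans), ("clf", self.clf)):
            if fp is None:
                continue
            out[f"{head}.W1"] = fp.W1
            out[f"{head}.b1"] = fp.b1
            out[f"{head}.W2"] = fp.W2
            out[f"{head}.b2"] = fp.b2
        return out

    def copy(self) -> "NetParams":
        import copy as _copy
        lstm = [LSTMParams(l.Wx.copy(), l.Wh.copy(), l.b.copy()) for l in self.lstm]
        trans = FCParams(self.trans.W1.copy(), self.trans.b1.copy(),
                         self.trans.W2.copy(), self.trans.b2.copy())
        clf = None
        if self.clf is not None:
            clf = FCParams(self.clf.W1.copy(), self.clf.b1.copy(),
                           self.clf.W2.copy(), self.clf.b2.copy())
        return NetParams(_copy.deepcopy(self.config), lstm, trans, clf)

    def n_parameters(self) -> int:
        return sum(a.size for a in self.flat().values())


def _init_lstm(rng: np.random.Generator, input_size: int, H: int) -> LSTMParams:
    sx = 1.0 / np.sqrt(max(input_size, 1))
    sh = 1.0 / np.sqrt(H)
    Wx = rng.uniform(-sx, sx, size=(input_size, 4 * H))
    Wh = rng.uniform(-sh, sh, size=(H, 4 * H))
    b = np.zeros(4 * H)
    b[:H] = 1.0  # forget-gate bias: retain memory early in training
    return LSTMParams(Wx=Wx, Wh=Wh, b=b)


def _init_fc(rng: np.random.Generator, n_in: int, n_hidden: int, n_out: int) -> FCParams:
    s1 = 1.0 / np.sqrt(n_in)
    s2 = 1.0 / np.sqrt(n_hidden)
    return FCParams(
        W1=rng.uniform(-s1, s1, size=(n_in, n_hidden)),
        b1=np.zeros(n_hidden),
        W2=rng.uniform(-s2, s2, size=(n_hidden, n_out)),
        b2=np.zeros(n_out),
    )


def init_params(config: NetConfig, seed: int = 0) -> NetParams:
    rng = np.random.default_rng(seed)
    H = config.hidden_size
    lstm = [_init_lstm(rng, 1, H)]
    if config.num_lstm_layers == 2:
        lstm.append(_init_lstm(rng, H, H))
    n_feat = config.window * H
    trans = _init_fc(rng, n_feat, config.trans_hidden, config.window)
    clf = _init_fc(rng, n_feat, config.clf_hidden, 1) if config.include_classifier else None
    params = NetParams(config=config, lstm=lstm, trans=trans, clf=clf)
    if config.dtype == "float32":
        for lp in params.lstm:
            lp.Wx = lp.Wx.astype(np.float32)
            lp.Wh = lp.Wh.astype(np.float32)
            lp.b = lp.b.astype(np.float32)
        for head in (params.trans, params.clf):
            if head is None:
                continue
            head.W1 = head.W1.astype(np.float32)
            head.b1 = head.b1.astype(np.float32)
            head.W2 = head.W2.astype(np.float32)
            head.b2 = head.b2.astype(np.float32)
    return params


# ---------------------------------------------------------------------------
# forward primitives
# ---------------------------------------------------------------------------

def lstm_step(
    x_t: np.ndarray, h_prev: np.ndarray, C_prev: np.ndarray, params: LSTMParams
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update; inputs may be single vectors or batches."""
    params.check()
    x_t = np.atleast_2d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    C_prev = np.atleast_2d(np.asarray(C_prev, dtype=float))
    if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(h_prev))
            and np.all(np.isfinite(C_prev))):
        raise ValueError("non-finite input to lstm_step")
    H = params.hidden_size
    if x_t.shape[1] != params.input_size or h_prev.shape[1] != H:
        raise ValueError("lstm_step shape mismatch")
    z = x_t @ params.Wx + h_prev @ params.Wh + params.b
    F = sigmoid(z[:, :H])
    I = sigmoid(z[:, H:2 * H])
    S = np.tanh(z[:, 2 * H:3 * H])
    O = sigmoid(z[:, 3 * H:])
    C = F * C_prev + I * S
    h = O * np.tanh(C)
    return h.squeeze(), C.squeeze()


def lstm_scan(sequence: np.ndarray, layers: list) -> np.ndarray:
    """Run stacked LSTM layers over a (T,) or (B, T) input sequence.

    Initial hidden and cell states are zero; returns the final layer's
    hidden-state sequence with shape (T, H) or (B, T, H).
    """
    x = np.asarray(sequence, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    B, T = x.shape
    inp = x[:, :, None]
    for lp in layers:
        lp.check()
        if lp.input_size != inp.shape[2]:
            raise ValueError("layer input size mismatch")
        H = lp.hidden_size
        h = np.zeros((B, H))
        C = np.zeros((B, H))
        XW = inp.reshape(B * T, -1) @ lp.Wx
        XW = XW.reshape(B, T, 4 * H) + lp.b
        out = np.empty((B, T, H))
        for t in range(T):
            z = XW[:, t, :] + h @ lp.Wh
            F = sigmoid(z[:, :H])
            I = sigmoid(z[:, H:2 * H])
            S = np.tanh(z[:, 2 * H:3 * H])
            O = sigmoid(z[:, 3 * H:])
            C = F * C + I * S
            h = O * np.tanh(C)
            out[:, t, :] = h
        inp = out
    return out[0] if single else out


def fc_forward(features: np.ndarray, params: FCParams, output: str = "linear") -> np.ndarray:
    """Two-layer fully connected head: ReLU hidden layer, then linear or
    sigmoid output."""
    a = np.atleast_2d(np.asarray(features, dtype=float))
    params.check(a.shape[1])
    a1 = np.maximum(a @ params.W1 + params.b1, 0.0)
    z2 = a1 @ params.W2 + params.b2
    out = sigmoid(z2) if output == "sigmoid" else z2
    return out.squeeze()


# ---------------------------------------------------------------------------
# full forward pass (with cache for the backward pass)
# ---------------------------------------------------------------------------

class ForwardCache:
    """Intermediates needed by the hand-derived backward pass."""

    __slots__ = ("x", "layers", "masks", "a0", "trans", "clf", "y_trans", "p_clf")

    def __init__(self):
        self.layers = []   # per LSTM layer: dict of stacked gate tensors
        self.masks = {}    # dropout masks (inverted scaling included)
        self.trans = {}
        self.clf = {}


def _scan_cached(inp, lp, cache_store):
    from ._lstm_kernels import lstm_forward_kernel

    B, T, _ = inp.shape
    H = lp.hidden_size
    dt = lp.Wx.dtype
    XW = (inp.reshape(B * T, -1) @ lp.Wx).reshape(B, T, 4 * H) + lp.b
    F = np.empty((B, T, H), dt); I = np.empty((B, T, H), dt)
    S = np.empty((B, T, H), dt); O = np.empty((B, T, H), dt)
    Cs = np.empty((B, T, H), dt); tC = np.empty((B, T, H), dt)
    Hs = np.empty((B, T, H), dt)
    lstm_forward_kernel(XW, lp.Wh, F, I, S, O, Cs, tC, Hs)
    cache_store.append({"inp": inp, "F": F, "I": I, "S": S, "O": O,
                        "C": Cs, "tanhC": tC, "H": Hs})
    return Hs


def forward_cached(
    x: np.ndarray,
    params: NetParams,
    training: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, Optional[np.ndarray], ForwardCache]:
    """Batched forward pass returning (translation, drug probability, cache).

    With ``training`` True, dropout masks are drawn from ``rng`` and
    surviving activations are rescaled by 1/(1-p) (inverted dropout), so
    evaluation applies no rescaling.
    """
    dtype = params.lstm[0].Wx.dtype
    x = np.asarray(x, dtype=dtype)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    B, T = x.shape
    cfg = params.config
    if T != cfg.window:
        raise ValueError(f"input length {T} != configured window {cfg.window}")
    p = cfg.dropout if training else 0.0
    if training and p > 0 and rng is None:
        raise ValueError("training forward with dropout needs an RNG")

    def mask(shape):
        if p == 0:
            return None
        return (((rng.random(shape) >= p)) / (1.0 - p)).astype(dtype)

    cache = ForwardCache()
    cache.x = x
    seq = x[:, :, None]
    for li, lp in enumerate(params.lstm):
        Hs = _scan_cached(seq, lp, cache.layers)
        m = mask(Hs.shape)
        cache.masks[f"lstm{li}"] = m
        seq = Hs if m is None else Hs * m
    a0 = seq.reshape(B, -1)
    cache.a0 = a0

    # translation head
    z1 = a0 @ params.trans.W1 + params.trans.b1
    a1 = np.maximum(z1, 0.0)
    m = mask(a1.shape)
    cache.masks["trans"] = m
    a1d = a1 if m is None else a1 * m
    y_trans = a1d @ params.trans.W2 + params.trans.b2
    cache.trans = {"a1": a1, "a1d": a1d}
    if not np.all(np.isfinite(y_trans)):
        raise FloatingPointError("non-finite activation in the translation head")

    p_clf = None
    if params.clf is not None:
        z1c = a0 @ params.clf.W1 + params.clf.b1
        a1c = np.maximum(z1c, 0.0)
        mc = mask(a1c.shape)
        cache.masks["clf"] = mc
        a1cd = a1c if mc is None else a1c * mc
        logit = a1cd @ params.clf.W2 + params.clf.b2
        p_clf = sigmoid(logit[:, 0])
        cache.clf = {"a1": a1c, "a1d": a1cd, "logit": logit, "p": p_clf}
        if not np.all(np.isfinite(logit)):
            raise FloatingPointError("non-finite activation in the classification head")

    cache.y_trans = y_trans
    cache.p_clf = p_clf
    if single:
        return y_trans[0], (None if p_clf is None else float(p_clf[0])), cache
    return y_trans, p_clf, cache


def forward(
    x: np.ndarray,
    params: NetParams,
    training: bool = False,
    rng: Optional[np.random.Generator] = None,
):
    """Forward pass without keeping the backward cache.

    Returns (translated normalized trace, drug probability); the
    probability is None for translation-only networks.
    """
    y, prob, _ = forward_cached(x, params, training=training, rng=rng)
    return y, prob


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_params(params: NetParams, path) -> None:
    """Single portable .npz file with a shape manifest."""
    arrays = {k: v for k, v in params.flat().items()}
    meta = dict(vars(params.config))
    np.savez(
        path,
        __meta__=np.array([repr(meta)]),
        **arrays,
    )


def load_params(path) -> NetParams:
    import ast

    with np.load(path, allow_pickle=False) as data:
        meta = ast.literal_eval(str(data["__meta__"][0]))
        cfg = NetConfig(**meta)
        params = init_params(cfg, seed=0)
        for k, arr in params.flat().items():
            if k not in data:
                raise ValueError(f"missing parameter {k!r} in checkpoint")
            stored = data[k]
            if stored.shape != arr.shape:
                raise ValueError(
                    f"shape mismatch for {k!r}: checkpoint {stored.shape}, "
                    f"expected {arr.shape}"
                )
            arr[...] = stored
    return params
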