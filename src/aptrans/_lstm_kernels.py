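"""Numba inner loops for the LSTM forward scan and backward-through-time
pass.  Semantics are identical to the plain-numpy reference loops in
:mod:`aptrans.network`/:mod:`aptrans.training`; tests compare the two."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lstm_forward_kernel(XW, Wh, F, I, S, O, C, tC, Hs):
    """In-place forward scan.

    XW: (B, T, 4H) input projections + bias; Wh: (H, 4H).  Fills the gate
    tensors and hidden/cell sequences (all (B, T, H)).  Gate slice order
    along the last axis of XW: f, i, s, o.
    """
    B, T, H4 = XW.shape
    H = H4 // 4
    h = np.zeros((B, H), XW.dtype)
    c = np.zeros((B, H), XW.dtype)
    for t in range(T):
        z = XW[:, t] + np.dot(h, Wh)
        for b in range(B):
            for j in range(H):
                f = 1.0 / (1.0 + np.exp(-z[b, j]))
                i = 1.0 / (1.0 + np.exp(-z[b, H + j]))
                s = np.tanh(z[b, 2 * H + j])
                o = 1.0 / (1.0 + np.exp(-z[b, 3 * H + j]))
                cc = f * c[b, j] + i * s
                tc = np.tanh(cc)
                hh = o * tc
                F[b, t, j] = f
                I[b, t, j] = i
                S[b, t, j] = s
                O[b, t, j] = o
                C[b, t, j] = cc
                tC[b, t, j] = tc
                Hs[b, t, j] = hh
                c[b, j] = cc
                h[b, j] = hh
    return 0


@njit(cache=True)
def lstm_backward_kernel(dH, F, I, S, O, C, tC, WhT, dz_all):
    """In-place backward-through-time pass.

    dH: (B, T, H) gradient w.r.t. the hidden sequence (already including
    any dropout mask).  Fills dz_all (B, T, 4H), the gradient w.r.t. the
    gate pre-activations; weight/bias/input gradients are assembled from
    it outside with large matmuls.
    """
    B, T, H = dH.shape
    dh_rec = np.zeros((B, H), dH.dtype)
    dC = np.zeros((B, H), dH.dtype)
    for t in range(T - 1, -1, -1):
        for b in range(B):
            for j in range(H):
                dh = dH[b, t, j] + dh_rec[b, j]
                o = O[b, t, j]
                tc = tC[b, t, j]
                do = dh * tc
                dc = dC[b, j] + dh * o * (1.0 - tc * tc)
                c_prev = C[b, t - 1, j] if t > 0 else 0.0
                f = F[b, t, j]
                i = I[b, t, j]
                s = S[b, t, j]
                dz_all[b, t, j] = dc * c_prev * f * (1.0 - f)
                dz_all[b, t, H + j] = dc * s * i * (1.0 - i)
                dz_all[b, t, 2 * H + j] = dc * i * (1.0 - s * s)
                dz_all[b, t, 3 * H + j] = do * o * (1.0 - o)
                dC[b, j] = dc * f
        dh_rec = np.dot(np.ascontiguousarray(dz_all[:, t]), WhT)
    return 0
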