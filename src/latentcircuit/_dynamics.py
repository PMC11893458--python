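"""Shared numerical core: rectified-linear Euler dynamics and Adam.

Both the high-dimensional network and the latent circuit follow the same
discretized dynamics

    y_t = (1 - alpha) * y_{t-1} + alpha * relu(W_rec y_{t-1} + W_in u_t + s_t)

where ``s_t`` collects recurrent noise and any externally injected current.
The backward pass implements backpropagation through time for this update
and is used by both the network trainer and the latent-circuit fitter.
"""

from __future__ import annotations

import numpy as np

__all__ = ["recurrent_noise", "forward", "backward", "Adam"]


def recurrent_noise(rng: np.random.Generator, shape, alpha: float, sigma: float):
    """Additive current noise sqrt(2/alpha)*sigma*xi with xi ~ N(0, 1).

    Returns ``None`` when sigma == 0 so callers can skip the addition.
    """
    if sigma == 0.0:
        return None
    out = rng.standard_normal(shape, dtype=np.float32).astype(np.float64)
    out *= np.sqrt(2.0 / alpha) * sigma
    return out


def forward(W_rec, W_in, u, alpha, noise=None, ext=None, y0=None):
    """Simulate the dynamics for a batch of input sequences.

    Parameters
    ----------
    W_rec : (N, N), W_in : (N, C)
    u : (K, T, C) input sequences.
    noise, ext : optional (K, T, N) currents added inside the rectification.
    y0 : optional (N,) or (K, N) initial state; zeros by default.

    Returns
    -------
    y : (K, T+1, N) with ``y[:, 0] = y0``; ``y[:, t+1]`` is the state after
        consuming input ``u[:, t]``.
    d : (K, T, N) bool, rectifier mask (preactivation > 0) per step.
    """
    K, T, _ = u.shape
    N = W_rec.shape[0]
    y = np.zeros((K, T + 1, N))
    if y0 is not None:
        y[:, 0] = y0
    d = np.zeros((K, T, N), dtype=bool)
    drive = u @ W_in.T
    if noise is not None:
        drive = drive + noise
    if ext is not None:
        drive = drive + ext
    Wr_T = np.ascontiguousarray(W_rec.T)
    om_a = 1.0 - alpha
    a = np.empty((K, N))
    for t in range(T):
        np.matmul(y[:, t], Wr_T, out=a)
        a += drive[:, t]
        pos = a > 0
        d[:, t] = pos
        a *= pos  # rectify in place
        a *= alpha
        a += om_a * y[:, t]
        y[:, t + 1] = a
    return y, d


def backward(W_rec, y, d, u, alpha, gy):
    """BPTT: accumulate loss gradients w.r.t. W_rec and W_in.

    Parameters
    ----------
    y, d : arrays returned by :func:`forward`.
    gy : (K, T, N) direct gradient dL/dy_t (``gy[:, t]`` pairs with
        ``y[:, t+1]``); recurrent contributions are accumulated here.

    Returns
    -------
    gW_rec : (N, N), gW_in : (N, C)
    """
    K, T, N = gy.shape
    C = u.shape[2]
    gW_rec = np.zeros_like(W_rec)
    gW_in = np.zeros((N, C))
    g = np.zeros((K, N))
    ga = np.empty((K, N))
    tmp_r = np.empty((N, N))
    tmp_i = np.empty((N, C))
    tmp_g = np.empty((K, N))
    om_a = 1.0 - alpha
    for t in range(T - 1, -1, -1):
        g += gy[:, t]
        np.multiply(g, d[:, t], out=ga)
        ga *= alpha
        np.matmul(ga.T, y[:, t], out=tmp_r)
        gW_rec += tmp_r
        np.matmul(ga.T, u[:, t], out=tmp_i)
        gW_in += tmp_i
        g *= om_a
        np.matmul(ga, W_rec, out=tmp_g)
        g += tmp_g
    return gW_rec, gW_in


class Adam:
    """Adam with L2 weight decay folded into the gradient (PyTorch style).

    Parameters are a dict of named arrays updated in place by :meth:`step`.
    """

    def __init__(self, params, lr, weight_decay=0.0, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads):
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            if self.wd:
                g = g + self.wd * p
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
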