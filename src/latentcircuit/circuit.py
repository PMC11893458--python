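"""Latent circuit model: a small rectified-linear recurrent circuit whose
trajectories, embedded through an orthonormal matrix Q, reproduce
high-dimensional neural responses and behavioral outputs.

Model:  y = Q x (+ b),   tau*dx/dt = -x + [w_rec x + w_in u]_+,   z = w_out x,
with Q^T Q = I enforced exactly through the Cayley transform
Q = (I + A)(I - A)^{-1} pi_n, A = B - B^T, which turns the constrained
problem into unconstrained optimization over the square matrix B.

Node identity is pinned by structural zeros: input channel i drives node i
only, and the last two nodes alone drive the two outputs. This removes the
permutation symmetry of the latent nodes, so fitted connectivity matrices
can be compared entry-by-entry across fits.

Gradients are computed analytically: backpropagation through time for the
circuit dynamics and an exact chain rule through the Cayley map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from ._dynamics import Adam, backward, forward, recurrent_noise
from .task import TrialBatch

__all__ = [
    "LatentCircuit",
    "FitConfig",
    "FitMetrics",
    "FitResult",
    "cayley_embed",
    "cayley_embed_backward",
    "simulate_latent",
    "fit_latent",
    "fit_ensemble",
    "fit_neural",
    "lambda_grid_search",
]


def cayley_embed(B: np.ndarray, n: int) -> np.ndarray:
    """Orthonormal (N, n) matrix: first n columns of (I+A)(I-A)^{-1}, A = B - B^T.

    Skew symmetry of A makes (I - A) always invertible, so the map is total;
    Q^T Q = I holds to machine precision.
    """
    N = B.shape[0]
    if n > N:
        raise ValueError("n must not exceed the ambient dimension")
    A = B - B.T
    eye = np.eye(N)
    C = np.linalg.solve((eye - A).T, (eye + A).T).T
    return C[:, :n]


def cayley_embed_backward(B: np.ndarray, gQ: np.ndarray) -> np.ndarray:
    """Gradient of a scalar loss w.r.t. B given its gradient gQ w.r.t. Q.

    With C = (I+A)M, M = (I-A)^{-1}: dC = (I + C) dA M, hence
    dL/dA = (I+C)^T G M^T (G = gQ zero-padded to N x N) and
    dL/dB = dL/dA - (dL/dA)^T.
    """
    N = B.shape[0]
    n = gQ.shape[1]
    A = B - B.T
    eye = np.eye(N)
    M = np.linalg.inv(eye - A)
    C = (eye + A) @ M
    G = np.zeros((N, N))
    G[:, :n] = gQ
    gA = (eye + C).T @ G @ M.T
    return gA - gA.T


@dataclass
class LatentCircuit:
    """An n-node circuit plus the auxiliary matrix parameterizing its embedding."""

    w_rec: np.ndarray  # (n, n)
    w_in: np.ndarray  # (n, 6), nonnegative, structurally diagonal
    w_out: np.ndarray  # (2, n), nonnegative, reads the last two nodes
    B_cayley: np.ndarray  # (N, N)
    b: np.ndarray | None = None  # (N,) intercept, neural-data mode only
    alpha: float = 0.2
    sigma_rec: float = 0.15

    @property
    def n(self) -> int:
        return self.w_rec.shape[0]

    @property
    def N(self) -> int:
        return self.B_cayley.shape[0]

    @property
    def Q(self) -> np.ndarray:
        return cayley_embed(self.B_cayley, self.n)

    def copy(self) -> "LatentCircuit":
        return replace(
            self,
            w_rec=self.w_rec.copy(),
            w_in=self.w_in.copy(),
            w_out=self.w_out.copy(),
            B_cayley=self.B_cayley.copy(),
            b=None if self.b is None else self.b.copy(),
        )


@dataclass
class FitConfig:
    learning_rate: float = 0.02
    weight_decay: float = 0.001
    minibatch: int = 128
    patience: int = 25
    improvement: float = 0.001
    max_epochs: int = 500
    lam: float = 0.5  # data/task tradeoff, neural-data loss only
    lambda_orth: float = 0.0  # optional input/output orthogonality penalty
    lr_min: float | None = None  # cosine-anneal the learning rate to this floor
    betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0


@dataclass
class FitMetrics:
    r2_total: float  # coefficient of determination, Qx (+b) vs y, held out
    r_Q2: float  # ||y - QQ^T y||^2 / ||y||^2
    r_x2: float  # ||Q^T(y - b) - x||^2 / ||Q^T y||^2
    r_z2: float  # ||z - w_out x||^2 / ||z||^2
    task_r2: float  # outputs vs task targets in the penalized epochs

    def as_dict(self):
        return {
            "r2_total": self.r2_total,
            "r_Q2": self.r_Q2,
            "r_x2": self.r_x2,
            "r_z2": self.r_z2,
            "task_r2": self.task_r2,
        }


@dataclass
class FitResult:
    circuit: LatentCircuit
    loss_trace: list[float]
    metrics: FitMetrics
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    converged: bool = True


def simulate_latent(
    lc: LatentCircuit, batch: TrialBatch, seed: int | None = 0, noise: bool = True
) -> np.ndarray:
    """Latent trajectories x (trials, timesteps, n), same Euler/rectified
    update and noise model as the high-dimensional network."""
    if batch.u.shape[2] != lc.w_in.shape[1]:
        raise ValueError("batch channel count does not match w_in")
    rng = np.random.default_rng(seed)
    K, T, _ = batch.u.shape
    noise_arr = (
        recurrent_noise(rng, (K, T, lc.n), lc.alpha, lc.sigma_rec) if noise else None
    )
    x_full, _ = forward(lc.w_rec, lc.w_in, batch.u, lc.alpha, noise=noise_arr)
    return x_full[:, 1:]


def _structural_masks(n: int, n_channels: int):
    """Input channel i -> node i; the last two nodes -> the two outputs."""
    m_in = np.zeros((n, n_channels))
    for i in range(min(n, n_channels)):
        m_in[i, i] = 1.0
    m_out = np.zeros((2, n))
    m_out[0, n - 2] = 1.0
    m_out[1, n - 1] = 1.0
    return m_in, m_out


def _init_params(n: int, N: int, n_channels: int, rng: np.random.Generator):
    """Initialization: w_rec uniform centered on 0 with sd 1/n, w_in/w_out
    zero except positive structural entries, B uniform on [0, 1]."""
    half = np.sqrt(3.0) / n  # uniform(-half, half) has sd 1/n
    w_rec = rng.uniform(-half, half, size=(n, n))
    m_in, m_out = _structural_masks(n, n_channels)
    w_in = m_in * rng.uniform(0.0, 1.0, size=(n, n_channels))
    w_out = m_out * rng.uniform(0.0, 1.0, size=(2, n))
    B = rng.uniform(0.0, 1.0, size=(N, N))
    return w_rec, w_in, w_out, B


def split_trials(
    conditions, seed: int | None = 0, test_fraction: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """50/50 train/test split of trial indices, stratified by condition."""
    rng = np.random.default_rng(seed)
    keys = [(c.context, c.motion_coherence, c.color_coherence) for c in conditions]
    by_key: dict = {}
    for i, k in enumerate(keys):
        by_key.setdefault(k, []).append(i)
    train, test = [], []
    for idx in by_key.values():
        idx = np.array(idx)
        rng.shuffle(idx)
        n_test = int(round(len(idx) * test_fraction))
        test.extend(idx[:n_test])
        train.extend(idx[n_test:])
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(test, dtype=int))


def _r2(pred: np.ndarray, data: np.ndarray) -> float:
    """Pooled coefficient of determination (SST about the pooled mean)."""
    resid = float(np.sum((data - pred) ** 2))
    total = float(np.sum((data - data.mean()) ** 2))
    return 1.0 - resid / total


def evaluate_fit(
    lc: LatentCircuit,
    y: np.ndarray,
    z: np.ndarray,
    batch: TrialBatch,
    idx: np.ndarray,
    seed: int | None = 0,
) -> FitMetrics:
    """Fit-quality metrics on the trials ``idx``, using the noiseless latent
    trajectories as the circuit's prediction."""
    sub = TrialBatch(
        u=batch.u[idx],
        z_target=batch.z_target[idx],
        mask=batch.mask[idx],
        conditions=[batch.conditions[i] for i in idx],
        dt_ms=batch.dt_ms,
    )
    x = simulate_latent(lc, sub, seed=seed, noise=False)
    Q = lc.Q
    b = 0.0 if lc.b is None else lc.b
    yd = y[idx]
    pred = x @ Q.T + b
    proj = (yd - b) @ Q
    eps = 1e-12
    r_Q2 = float(np.sum((yd - proj @ Q.T - b) ** 2) / (np.sum(yd**2) + eps))
    r_x2 = float(np.sum((proj - x) ** 2) / (np.sum((yd @ Q) ** 2) + eps))
    zc = x @ lc.w_out.T
    r_z2 = float(np.sum((z[idx] - zc) ** 2) / (np.sum(z[idx] ** 2) + eps))
    m = sub.mask[:, :, None] & np.ones_like(zc, dtype=bool)
    task = _r2(zc[m], sub.z_target[m])
    return FitMetrics(
        r2_total=_r2(pred, yd), r_Q2=r_Q2, r_x2=r_x2, r_z2=r_z2, task_r2=task
    )


def _fit_loss_grads(B, w_rec, w_in, w_out, u, yd, zd, alpha, noise, lambda_orth=0.0):
    """Loss and analytic gradients for one minibatch of the response fit.

    Loss = mean((y - Qx)^2) + mean((z - w_out x)^2) with x simulated from
    the circuit dynamics under the supplied (frozen) noise realization.
    """
    n = w_rec.shape[0]
    Q = cayley_embed(B, n)
    x_full, d = forward(w_rec, w_in, u, alpha, noise=noise)
    x = x_full[:, 1:]
    R1 = yd - x @ Q.T
    R2 = zd - x @ w_out.T
    s1, s2 = R1.size, R2.size
    loss = float(np.sum(R1**2)) / s1 + float(np.sum(R2**2)) / s2
    gQ = (-2.0 / s1) * np.einsum("ktN,ktn->Nn", R1, x)
    gx = (-2.0 / s1) * (R1 @ Q) + (-2.0 / s2) * (R2 @ w_out)
    gw_out = (-2.0 / s2) * np.einsum("kti,ktn->in", R2, x)
    gw_rec, gw_in = backward(w_rec, x_full, d, u, alpha, gx)
    if lambda_orth:
        from .rnn import _orth_penalty

        o_loss, g_o_in, g_o_out = _orth_penalty(w_in, w_out, lambda_orth)
        loss += o_loss
        gw_in = gw_in + g_o_in
        gw_out = gw_out + g_o_out
    grads = {
        "B": cayley_embed_backward(B, gQ),
        "w_rec": gw_rec,
        "w_in": gw_in,
        "w_out": gw_out,
    }
    return loss, grads


def fit_latent(
    y: np.ndarray,
    z: np.ndarray,
    batch: TrialBatch,
    cfg: FitConfig,
    n: int = 8,
    alpha: float = 0.2,
    sigma_rec: float = 0.15,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> FitResult:
    """Fit a latent circuit to responses ``y`` and outputs ``z``.

    Minimizes the mean squared error between y and the embedded latent
    trajectories Qx plus the error between z and the circuit's readout
    w_out x, over (B, w_rec, w_in, w_out) with Adam. Fresh recurrent noise
    is drawn for the latent dynamics at every minibatch; metrics are
    computed on held-out trials.
    """
    N = y.shape[2]
    if n > N:
        raise ValueError("latent dimension exceeds ambient dimension")
    ss = np.random.SeedSequence(cfg.seed)
    s_init, s_noise, s_eval = (int(x) for x in ss.generate_state(3))
    rng = np.random.default_rng(s_init)
    noise_rng = np.random.default_rng(s_noise)
    if split is None:
        split = split_trials(batch.conditions, seed=s_init)
    train_idx, test_idx = split
    w_rec, w_in, w_out, B = _init_params(n, N, batch.u.shape[2], rng)
    m_in, m_out = _structural_masks(n, batch.u.shape[2])
    params = {"B": B, "w_rec": w_rec, "w_in": w_in, "w_out": w_out}
    opt = Adam(params, cfg.learning_rate, cfg.weight_decay, cfg.betas)
    K = len(train_idx)
    mb = min(cfg.minibatch, K)
    trace: list[float] = []
    best = np.inf
    best_epoch = 0
    converged = True
    for epoch in range(cfg.max_epochs):
        if cfg.lr_min is not None:
            frac = 0.5 * (1 + np.cos(np.pi * epoch / max(cfg.max_epochs - 1, 1)))
            opt.lr = cfg.lr_min + (cfg.learning_rate - cfg.lr_min) * frac
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        n_mb = 0
        for start in range(0, K, mb):
            idx = order[start : start + mb]
            noise = recurrent_noise(
                noise_rng, (len(idx), batch.n_timesteps, n), alpha, sigma_rec
            )
            loss, grads = _fit_loss_grads(
                B, w_rec, w_in, w_out, batch.u[idx], y[idx], z[idx],
                alpha, noise, cfg.lambda_orth,
            )
            opt.step(grads)
            np.multiply(w_in, m_in, out=w_in)
            np.multiply(w_out, m_out, out=w_out)
            np.clip(w_in, 0.0, None, out=w_in)
            np.clip(w_out, 0.0, None, out=w_out)
            epoch_loss += loss
            n_mb += 1
        epoch_loss /= n_mb
        if not np.isfinite(epoch_loss):
            converged = False
            warnings.warn(f"latent fit diverged at epoch {epoch}")
            break
        trace.append(epoch_loss)
        if epoch_loss < best - cfg.improvement:
            best = epoch_loss
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            break
    lc = LatentCircuit(
        w_rec=w_rec, w_in=w_in, w_out=w_out, B_cayley=B, alpha=alpha, sigma_rec=sigma_rec
    )
    metrics = evaluate_fit(lc, y, z, batch, test_idx, seed=s_eval)
    return FitResult(
        circuit=lc,
        loss_trace=trace,
        metrics=metrics,
        train_idx=train_idx,
        test_idx=test_idx,
        seed=cfg.seed,
        converged=converged,
    )


def fit_ensemble(
    y: np.ndarray,
    z: np.ndarray,
    batch: TrialBatch,
    n_inits: int = 20,
    top_k: int = 10,
    cfg: FitConfig | None = None,
    n: int = 8,
    **kwargs,
) -> list[FitResult]:
    """Fit ``n_inits`` latent circuits with distinct seeds and return the
    ``top_k`` ranked by held-out r2_total (ties broken by lower final loss).

    All fits share one train/test split so held-out metrics are comparable.
    """
    if n_inits < top_k:
        raise ValueError("n_inits must be >= top_k")
    cfg = cfg or FitConfig()
    seeds = [int(s) for s in np.random.SeedSequence(cfg.seed).generate_state(n_inits)]
    split = split_trials(batch.conditions, seed=cfg.seed)
    fits = []
    for s in seeds:
        res = fit_latent(y, z, batch, replace(cfg, seed=s % 2**31), n=n, split=split, **kwargs)
        if res.converged and np.isfinite(res.metrics.r2_total):
            fits.append(res)
    if not fits:
        raise RuntimeError("all latent fits diverged")
    fits.sort(key=lambda r: (-r.metrics.r2_total, r.loss_trace[-1]))
    return fits[:top_k]


# ---------------------------------------------------------------------------
# Neural-data mode: condition-averaged responses, normalized three-term loss
# ---------------------------------------------------------------------------


def _neural_loss_grads(B, w_rec, w_in, w_out, b, u, yd, zt, obs, resp, alpha, noise, lam):
    """Loss and analytic gradients for one minibatch of the neural-data fit.

    Three normalized squared-residual terms per condition and timestep:
    lam*||(y-b) - QQ^T (y-b)||^2/||y||^2 on observed steps, ||Q^T(y-b) -
    x||^2 / ||Q^T y||^2 on observed steps, and ||z - w_out x||^2/||z||^2
    on response steps; summed and divided by the minibatch size. The
    subspace term is centered on the intercept so that b is identified in
    all directions (for centered recordings b is near zero and this
    coincides with the uncentered form).
    """
    n = w_rec.shape[0]
    eps = 1e-12
    Q = cayley_embed(B, n)
    x_full, d = forward(w_rec, w_in, u, alpha, noise=noise)
    x = x_full[:, 1:]
    yo = yd[:, obs]
    yb = yo - b
    w1 = np.maximum(np.sum(yo**2, axis=2), eps)
    proj = yo @ Q
    projb = yb @ Q
    r1 = yb - projb @ Q.T
    t1 = lam * np.sum(np.sum(r1**2, axis=2) / w1)
    den2 = np.maximum(np.sum(proj**2, axis=2), eps)
    s2v = projb - x[:, obs]
    num2 = np.sum(s2v**2, axis=2)
    t2 = np.sum(num2 / den2)
    zr = x[:, resp] @ w_out.T
    r3 = zt[:, resp] - zr
    w3 = np.maximum(np.sum(zt[:, resp] ** 2, axis=2), eps)
    t3 = np.sum(np.sum(r3**2, axis=2) / w3)
    kk = u.shape[0]
    loss = float(t1 + t2 + t3) / kk
    # term 1 w.r.t. Q (r1 is orthogonal to the span of Q, so only the
    # left factor contributes) and w.r.t. b
    gQ = (-2.0 * lam / kk) * np.einsum("ktN,ktn->Nn", r1 / w1[:, :, None], projb)
    gb = (-2.0 * lam / kk) * np.einsum("ktN->N", r1 / w1[:, :, None])
    # term 2 numerator, then its denominator's dependence on Q
    gQ += (2.0 / kk) * np.einsum("ktN,ktn->Nn", yb / den2[:, :, None], s2v)
    gQ += (-2.0 / kk) * np.einsum(
        "ktN,ktn->Nn", yo * (num2 / den2**2)[:, :, None], proj
    )
    gb += (-2.0 / kk) * np.einsum("ktn,Nn->N", s2v / den2[:, :, None], Q)
    gx = np.zeros_like(x)
    gx[:, obs] = (-2.0 / kk) * (s2v / den2[:, :, None])
    gx[:, resp] += (-2.0 / kk) * ((r3 / w3[:, :, None]) @ w_out)
    gw_out = (-2.0 / kk) * np.einsum("kti,ktn->in", r3 / w3[:, :, None], x[:, resp])
    gw_rec, gw_in = backward(w_rec, x_full, d, u, alpha, gx)
    grads = {
        "B": cayley_embed_backward(B, gQ),
        "w_rec": gw_rec,
        "w_in": gw_in,
        "w_out": gw_out,
        "b": gb,
    }
    return loss, grads


def fit_neural(
    pop,
    cfg: FitConfig,
    n: int = 8,
    alpha: float = 0.2,
    sigma_rec: float = 0.15,
) -> FitResult:
    """Fit the model y = Qx + b to condition-averaged responses.

    ``pop`` is a :class:`latentcircuit.neural.RatePopulation`: rates
    (conditions, timesteps, units) observed only at ``pop.observed_mask``
    timesteps, with task inputs/targets on the full simulation grid. The
    loss balances three normalized terms: the variance of y outside the
    embedding subspace (weight ``cfg.lam``), the mismatch between projected
    responses and latent trajectories, and the task error of the readout
    (penalized only in the response window).
    """
    y = pop.rates
    u = pop.u
    zt = pop.z_target
    obs = pop.observed_mask
    resp = pop.response_mask
    K, T, N = y.shape
    if n > N:
        raise ValueError("latent dimension exceeds ambient dimension")
    ss = np.random.SeedSequence(cfg.seed)
    s_init, s_noise = (int(x) for x in ss.generate_state(2))
    rng = np.random.default_rng(s_init)
    noise_rng = np.random.default_rng(s_noise)
    w_rec, w_in, w_out, B = _init_params(n, N, u.shape[2], rng)
    b = np.zeros(N)
    m_in, m_out = _structural_masks(n, u.shape[2])
    params = {"B": B, "w_rec": w_rec, "w_in": w_in, "w_out": w_out, "b": b}
    opt = Adam(params, cfg.learning_rate, cfg.weight_decay, cfg.betas)
    trace: list[float] = []
    best = np.inf
    best_epoch = 0
    converged = True
    mb = min(cfg.minibatch, K)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(K)
        epoch_loss = 0.0
        n_mb = 0
        for start in range(0, K, mb):
            idx = order[start : start + mb]
            noise = recurrent_noise(noise_rng, (len(idx), T, n), alpha, sigma_rec)
            loss, grads = _neural_loss_grads(
                B, w_rec, w_in, w_out, b, u[idx], y[idx], zt[idx],
                obs, resp, alpha, noise, cfg.lam,
            )
            opt.step(grads)
            np.multiply(w_in, m_in, out=w_in)
            np.multiply(w_out, m_out, out=w_out)
            np.clip(w_in, 0.0, None, out=w_in)
            np.clip(w_out, 0.0, None, out=w_out)
            epoch_loss += loss
            n_mb += 1
        epoch_loss /= n_mb
        if not np.isfinite(epoch_loss):
            converged = False
            warnings.warn(f"neural fit diverged at epoch {epoch}")
            break
        trace.append(epoch_loss)
        if epoch_loss < best - cfg.improvement:
            best = epoch_loss
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            break
    lc = LatentCircuit(
        w_rec=w_rec,
        w_in=w_in,
        w_out=w_out,
        B_cayley=B,
        b=b,
        alpha=alpha,
        sigma_rec=sigma_rec,
    )
    metrics = _evaluate_neural(lc, pop, alpha)
    all_idx = np.arange(K)
    return FitResult(
        circuit=lc,
        loss_trace=trace,
        metrics=metrics,
        train_idx=all_idx,
        test_idx=all_idx,
        seed=cfg.seed,
        converged=converged,
    )


def _evaluate_neural(lc: LatentCircuit, pop, alpha: float) -> FitMetrics:
    x_full, _ = forward(lc.w_rec, lc.w_in, pop.u, alpha)
    x = x_full[:, 1:]
    Q = lc.Q
    obs = pop.observed_mask
    resp = pop.response_mask
    yo = pop.rates[:, obs]
    b = lc.b if lc.b is not None else 0.0
    pred = x[:, obs] @ Q.T + b
    eps = 1e-12
    proj = yo @ Q
    yb = yo - b
    r_Q2 = float(np.sum((yb - (yb @ Q) @ Q.T) ** 2) / (np.sum(yo**2) + eps))
    r_x2 = float(np.sum(((yo - b) @ Q - x[:, obs]) ** 2) / (np.sum(proj**2) + eps))
    zc = x[:, resp] @ lc.w_out.T
    zt = pop.z_target[:, resp]
    r_z2 = float(np.sum((zt - zc) ** 2) / (np.sum(zt**2) + eps))
    return FitMetrics(
        r2_total=_r2(pred, yo),
        r_Q2=r_Q2,
        r_x2=r_x2,
        r_z2=r_z2,
        task_r2=_r2(zc, zt),
    )


def lambda_grid_search(
    pop,
    cfg: FitConfig,
    lam_grid=None,
    n: int = 8,
    min_task_r2: float = 0.8,
    **kwargs,
) -> tuple[float, list[tuple[float, FitMetrics]]]:
    """Select the data/task tradeoff lambda over a grid (default [0, 1.5]).

    Returns the lambda maximizing the explained subspace variance and
    projection fit (minimizing r_Q2 + r_x2) among fits whose readout still
    performs the task (task_r2 >= min_task_r2, falling back to the best
    task_r2 if none qualify), together with all (lambda, metrics) pairs.
    """
    if lam_grid is None:
        lam_grid = [0.0, 0.25, 0.5, 0.75, 1.0, 1.5]
    results = []
    for lam in lam_grid:
        res = fit_neural(pop, replace(cfg, lam=lam), n=n, **kwargs)
        results.append((lam, res.metrics))
    ok = [r for r in results if r[1].task_r2 >= min_task_r2]
    pool = ok if ok else [max(results, key=lambda r: r[1].task_r2)]
    best = min(pool, key=lambda r: r[1].r_Q2 + r[1].r_x2)
    return best[0], results
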