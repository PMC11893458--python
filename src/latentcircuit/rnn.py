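"""Dale-constrained rectified-linear RNNs: simulation, training, behavior.

The network follows tau*dy/dt = -y + [W_rec y + W_in u]_+ discretized with a
first-order Euler step (alpha = dt/tau) and additive recurrent noise inside
the rectification. 80% of units are excitatory and 20% inhibitory; after
every training update, recurrent weights that violate the sign of their
presynaptic unit are clipped to zero, and input/output weights are clamped
nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import task as task_mod
from ._dynamics import Adam, backward, forward, recurrent_noise
from .task import TrialBatch

__all__ = [
    "RNNParams",
    "TrainConfig",
    "init_rnn",
    "simulate_rnn",
    "outputs",
    "train_rnn",
    "decide",
    "psychometric",
    "task_r2",
]


@dataclass
class RNNParams:
    W_rec: np.ndarray  # (N, N)
    W_in: np.ndarray  # (N, 6), nonnegative
    W_out: np.ndarray  # (2, N), nonnegative
    dale_mask: np.ndarray  # (N,), +1 excitatory / -1 inhibitory
    tau: float = 200.0  # ms
    dt: float = 40.0  # ms
    sigma_rec: float = 0.15

    @property
    def alpha(self) -> float:
        return self.dt / self.tau

    @property
    def N(self) -> int:
        return self.W_rec.shape[0]

    def copy(self) -> "RNNParams":
        return replace(
            self,
            W_rec=self.W_rec.copy(),
            W_in=self.W_in.copy(),
            W_out=self.W_out.copy(),
            dale_mask=self.dale_mask.copy(),
        )

    def dale_violation(self) -> float:
        """Largest magnitude of a recurrent weight violating Dale's law."""
        signed = self.W_rec * self.dale_mask[None, :]
        return float(np.maximum(-signed, 0.0).max())


@dataclass
class TrainConfig:
    """Training hyperparameters.

    The loss here is normalized per term (task error averaged over penalized
    entries, rate penalty averaged over all entries). On this scale the
    conventional decay of 0.001 — defined against a summed loss — would be
    several orders of magnitude too strong (it stalls learning well below
    task performance), so the equivalent decoupled decay is ~1e-7 and the
    default is 0.
    """

    learning_rate: float = 0.01
    weight_decay: float = 0.0
    grad_clip: float = 1.0  # global gradient-norm clip; None disables
    lambda_r: float = 0.05
    lambda_orth: float = 1.0
    minibatch: int = 128
    n_trials: int = 1800
    max_epochs: int = 400
    patience: int = 25
    improvement: float = 0.001
    betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0


def init_rnn(N: int = 50, seed: int | None = 0, frac_exc: float = 0.8) -> RNNParams:
    """Initialize a Dale-constrained RNN.

    Excitatory recurrent weights are |Gaussian| with mean 1/sqrt(N) and
    variance 1/N, inhibitory with mean 4/sqrt(N); W_rec is then rescaled to a
    spectral radius of 1.5. Input/output weights are small nonnegative values.
    """
    n_exc = int(round(N * frac_exc))
    if N < 2 or n_exc <= 0 or n_exc >= N or abs(n_exc - N * frac_exc) > 1e-9:
        raise ValueError(f"N={N} does not admit an exact {frac_exc:.0%} excitatory split")
    rng = np.random.default_rng(seed)
    dale = np.ones(N)
    dale[n_exc:] = -1.0
    sd = 1.0 / np.sqrt(N)
    W = np.empty((N, N))
    W[:, :n_exc] = rng.normal(1.0 / np.sqrt(N), sd, size=(N, n_exc))
    W[:, n_exc:] = rng.normal(4.0 / np.sqrt(N), sd, size=(N, N - n_exc))
    W = np.abs(W) * dale[None, :]
    radius = np.abs(np.linalg.eigvals(W)).max()
    W *= 1.5 / radius
    W_in = np.abs(rng.normal(0.0, sd, size=(N, task_mod.N_CHANNELS)))
    W_out = np.abs(rng.normal(0.0, sd, size=(2, N)))
    return RNNParams(W_rec=W, W_in=W_in, W_out=W_out, dale_mask=dale)


def simulate_rnn(
    p: RNNParams,
    batch: TrialBatch,
    seed: int | None = 0,
    ext: np.ndarray | None = None,
    return_cache: bool = False,
):
    """Simulate responses y (trials, timesteps, N) for a batch of trials.

    ``ext`` optionally injects extra current (trials, timesteps, N) inside
    the rectification (used for activity stimulation experiments).
    """
    if batch.u.shape[2] != p.W_in.shape[1]:
        raise ValueError("batch channel count does not match W_in")
    rng = np.random.default_rng(seed)
    K, T, _ = batch.u.shape
    noise = recurrent_noise(rng, (K, T, p.N), p.alpha, p.sigma_rec)
    y_full, d = forward(p.W_rec, p.W_in, batch.u, p.alpha, noise=noise, ext=ext)
    if return_cache:
        return y_full, d
    return y_full[:, 1:]


def outputs(p: RNNParams, y: np.ndarray) -> np.ndarray:
    """Readout z = W_out y."""
    return y @ p.W_out.T


def _orth_penalty(W_in, W_out, lam):
    """Penalty lam*||off-diag(B^T B)||_F on the column-normalized concatenation
    B = [W_in, W_out^T], with its gradient w.r.t. W_in and W_out."""
    V = np.concatenate([W_in, W_out.T], axis=1)
    norms = np.maximum(np.linalg.norm(V, axis=0), 1e-12)
    Bn = V / norms
    C = Bn.T @ Bn
    np.fill_diagonal(C, 0.0)
    val = np.linalg.norm(C)
    if val < 1e-12:
        z = np.zeros_like(W_in), np.zeros_like(W_out)
        return 0.0, *z
    gBn = (2.0 / val) * (Bn @ C)
    gV = (gBn - Bn * np.sum(Bn * gBn, axis=0, keepdims=True)) / norms
    n_in = W_in.shape[1]
    return lam * val, lam * gV[:, :n_in], lam * gV[:, n_in:].T


def train_rnn(
    p: RNNParams,
    cfg: TrainConfig,
    batch: TrialBatch | None = None,
    callback=None,
) -> tuple[RNNParams, list[float]]:
    """Train an RNN on the context-dependent task; returns (params, loss trace).

    Minimizes the masked task error (mean over penalized entries) plus the
    rate penalty lambda_r*mean(y^2) plus the input/output orthogonality
    penalty, with Adam.
    Dale's law and nonnegativity of W_in/W_out are re-imposed after every
    update. Stops early when the epoch loss has not improved by
    ``cfg.improvement`` within ``cfg.patience`` epochs.
    """
    if batch is None:
        batch = task_mod.training_batch(cfg.n_trials, seed=cfg.seed, alpha=p.alpha)
    p = p.copy()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    params = {"W_rec": p.W_rec, "W_in": p.W_in, "W_out": p.W_out}
    opt = Adam(params, cfg.learning_rate, cfg.weight_decay, cfg.betas)
    exc = p.dale_mask > 0
    K = batch.n_trials
    mb = min(cfg.minibatch, K)
    trace: list[float] = []
    best = np.inf
    best_epoch = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(K)
        epoch_loss = 0.0
        n_mb = 0
        for start in range(0, K, mb):
            idx = order[start : start + mb]
            u = batch.u[idx]
            zt = batch.z_target[idx]
            m = batch.mask[idx]
            noise = recurrent_noise(rng, (len(idx),) + u.shape[1:2] + (p.N,), p.alpha, p.sigma_rec)
            y_full, d = forward(p.W_rec, p.W_in, u, p.alpha, noise=noise)
            y = y_full[:, 1:]
            z = y @ p.W_out.T
            n_pen = max(int(m.sum()) * 2, 1)
            err = (z - zt) * m[:, :, None]
            task_loss = float(np.sum(err**2)) / n_pen
            rate_loss = cfg.lambda_r * float(np.mean(y**2))
            # direct dL/dy and dL/dW_out
            gy = (2.0 / n_pen) * (err @ p.W_out) + (2.0 * cfg.lambda_r / y.size) * y
            gW_out = (2.0 / n_pen) * np.einsum("kti,ktj->ij", err, y)
            gW_rec, gW_in = backward(p.W_rec, y_full, d, u, p.alpha, gy)
            orth_loss, gin_o, gout_o = _orth_penalty(p.W_in, p.W_out, cfg.lambda_orth)
            grads = {
                "W_rec": gW_rec,
                "W_in": gW_in + gin_o,
                "W_out": gW_out + gout_o,
            }
            if cfg.grad_clip is not None:
                gnorm = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
                if gnorm > cfg.grad_clip:
                    scale = cfg.grad_clip / gnorm
                    grads = {k: g * scale for k, g in grads.items()}
            opt.step(grads)
            # project onto the constraint set
            p.W_rec[:, exc] = np.maximum(p.W_rec[:, exc], 0.0)
            p.W_rec[:, ~exc] = np.minimum(p.W_rec[:, ~exc], 0.0)
            np.clip(p.W_in, 0.0, None, out=p.W_in)
            np.clip(p.W_out, 0.0, None, out=p.W_out)
            epoch_loss += task_loss + rate_loss + orth_loss
            n_mb += 1
        epoch_loss /= n_mb
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        trace.append(epoch_loss)
        if callback is not None:
            callback(epoch, epoch_loss, p)
        if epoch_loss < best - cfg.improvement:
            best = epoch_loss
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            break
    return p, trace


def decide(z: np.ndarray, seed: int | None = 0):
    """Choices from outputs: right iff z1 - z2 > 0 at the final step.

    Exact ties are broken by a seeded fair coin and flagged.

    Returns
    -------
    choices : (trials,) int, +1 right / -1 left.
    ties : (trials,) bool, True where the tie-break path was taken.
    """
    diff = z[:, -1, 0] - z[:, -1, 1]
    choices = np.where(diff > 0, 1, -1)
    ties = diff == 0
    if ties.any():
        rng = np.random.default_rng(seed)
        choices[ties] = np.where(rng.random(int(ties.sum())) < 0.5, 1, -1)
    return choices, ties


def psychometric(
    p: RNNParams, n_per_condition: int = 20, seed: int | None = 0, ext_axis=None, ext_mag=0.0
) -> pd.DataFrame:
    """Fraction of right choices per (context, motion, color) condition.

    ``ext_axis``/``ext_mag`` optionally stimulate activity along a unit axis
    during the stimulus epoch (see connectivity.stimulate_along_axis).
    """
    ss = np.random.SeedSequence(seed).generate_state(3)
    batch = task_mod.make_batch(
        task_mod.enumerate_conditions(), n_per_condition, seed=int(ss[0]), alpha=p.alpha
    )
    ext = None
    if ext_axis is not None and ext_mag != 0.0:
        ext = np.zeros((batch.n_trials, batch.n_timesteps, p.N))
        stim = task_mod._step(task_mod.STIM_ON_MS, batch.dt_ms)
        ext[:, stim:, :] = ext_mag * np.asarray(ext_axis)[None, None, :]
    y = simulate_rnn(p, batch, seed=int(ss[1]), ext=ext)
    z = outputs(p, y)
    choices, _ = decide(z, seed=int(ss[2]))
    df = batch.condition_frame()
    df["right"] = choices > 0
    out = (
        df.groupby(["context", "motion_coherence", "color_coherence"], as_index=False)
        .agg(frac_right=("right", "mean"), n_trials=("right", "size"))
    )
    return out


def task_r2(p: RNNParams, batch: TrialBatch, seed: int | None = 0) -> float:
    """Coefficient of determination between outputs and targets in the
    penalized epochs (pooled over trials, time and output units)."""
    y = simulate_rnn(p, batch, seed=seed)
    z = outputs(p, y)
    m = batch.mask[:, :, None] & np.ones_like(z, dtype=bool)
    resid = float(np.sum((z[m] - batch.z_target[m]) ** 2))
    total = float(np.sum((batch.z_target[m] - batch.z_target[m].mean()) ** 2))
    return 1.0 - resid / total
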