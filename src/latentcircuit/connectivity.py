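"""Relating latent and ambient connectivity.

If Q embeds the latent circuit into the network's state space, then
Q^T W_rec Q equals the latent recurrent connectivity w_rec (and Q^T W_in
equals w_in) wherever the fit is exact. Conversely, a change delta to the
latent connection (i <- j) corresponds to the rank-one ambient perturbation
delta * q_i q_j^T, satisfying the dot-product identity
w . delta_ij = W . (Q delta_ij Q^T) for any W.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rnn import RNNParams, psychometric

__all__ = [
    "PerturbationSpec",
    "conjugate",
    "complete_basis",
    "map_perturbation",
    "apply_perturbation",
    "stimulate_along_axis",
]


def _check_orthonormal(Q: np.ndarray, tol: float = 1e-6):
    err = np.abs(Q.T @ Q - np.eye(Q.shape[1])).max()
    if err > tol:
        raise ValueError(f"Q is not orthonormal (max deviation {err:.2e})")


@dataclass
class PerturbationSpec:
    """A latent connection change (target i <- source j, weight delta) and
    its rank-one high-dimensional image delta * q_i q_j^T."""

    source: int
    target: int
    delta: float
    image: np.ndarray  # (N, N), rank one


def conjugate(W_rec: np.ndarray, W_in: np.ndarray | None, Q: np.ndarray):
    """Project ambient connectivity into the embedding: (Q^T W_rec Q, Q^T W_in)."""
    _check_orthonormal(Q)
    w_rec = Q.T @ W_rec @ Q
    if W_in is None:
        return w_rec
    return w_rec, Q.T @ W_in


def complete_basis(Q: np.ndarray, seed: int | None = 0) -> np.ndarray:
    """Extend orthonormal Q (N, n) to a full orthonormal basis (N, N).

    The complement is a seeded random Gaussian block orthogonalized against
    Q, with each completed column's largest-magnitude entry made positive.
    """
    _check_orthonormal(Q)
    N, n = Q.shape
    if n == N:
        return Q.copy()
    rng = np.random.default_rng(seed)
    R = rng.standard_normal((N, N - n))
    R -= Q @ (Q.T @ R)
    comp, _ = np.linalg.qr(R)
    if np.linalg.matrix_rank(np.concatenate([Q, comp], axis=1)) < N:
        raise ValueError("rank-deficient completion; Q may be degenerate")
    signs = np.sign(comp[np.abs(comp).argmax(axis=0), np.arange(N - n)])
    comp *= np.where(signs == 0, 1.0, signs)[None, :]
    return np.concatenate([Q, comp], axis=1)


def map_perturbation(Q: np.ndarray, i: int, j: int, delta: float) -> PerturbationSpec:
    """Rank-one ambient image of changing latent connection (i <- j) by delta."""
    N, n = Q.shape
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError("latent node index out of range")
    image = delta * np.outer(Q[:, i], Q[:, j])
    return PerturbationSpec(source=j, target=i, delta=delta, image=image)


def apply_perturbation(p: RNNParams, spec: PerturbationSpec, scale: float = 1.0) -> RNNParams:
    """Network with W_rec + scale * image; Dale's law is intentionally NOT
    re-imposed (the perturbation is a probe, not training)."""
    q = p.copy()
    q.W_rec = q.W_rec + scale * spec.image
    return q


def stimulate_along_axis(
    p: RNNParams,
    axis: np.ndarray,
    magnitude: float,
    n_per_condition: int = 20,
    seed: int | None = 0,
):
    """Psychometric table under stimulation of activity along a unit axis.

    ``magnitude * axis`` is injected as extra current inside the
    rectification at every step of the stimulus epoch.
    """
    axis = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("zero-norm stimulation axis")
    axis = axis / nrm
    return psychometric(
        p, n_per_condition=n_per_condition, seed=seed, ext_axis=axis, ext_mag=magnitude
    )
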