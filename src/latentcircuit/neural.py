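"""Condition-averaged firing-rate data: preprocessing and synthetic surrogates.

Recorded populations are reduced to condition-averaged, z-scored, smoothed
firing rates with the condition-independent mean removed and projected onto
the principal components carrying half the variance. The same container
feeds the neural-data latent circuit fitter.

The synthetic generator emulates the statistical structure of such
recordings: a small ground-truth circuit drives a low-variance task
subspace embedded at random in a high-dimensional population, on top of
task-irrelevant smooth dynamics and observation noise, over the 72
conditions of the context-dependent task.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import task as task_mod
from ._dynamics import forward
from .circuit import LatentCircuit

__all__ = [
    "RatePopulation",
    "neural_task_inputs",
    "preprocess_rates",
    "generate_synthetic_population",
    "suppression_circuit",
    "load_external_recording",
]

# Simulation grid for neural-data fitting: 150 steps of 10 ms; contextual
# input on for the whole 1,500 ms, stimulus input from 750 ms; targets
# penalized in the last 250 ms; responses observed on the last 15 steps.
NEURAL_DT_MS = 10.0
NEURAL_T = 150
NEURAL_CTX_ON = 0
NEURAL_STIM_ON = 75
NEURAL_RESPONSE_STEPS = 25
NEURAL_OBSERVED_STEPS = 15
NEURAL_ALPHA = 0.2


@dataclass
class RatePopulation:
    """Condition-averaged population rates plus the task structure needed to
    fit a latent circuit to them."""

    rates: np.ndarray  # (conditions, timesteps, units); meaningful where observed
    conditions: pd.DataFrame  # context, motion_coherence, color_coherence, choice
    u: np.ndarray  # (conditions, timesteps, 6) task inputs on the model grid
    z_target: np.ndarray  # (conditions, timesteps, 2)
    observed_mask: np.ndarray  # (timesteps,) bool
    response_mask: np.ndarray  # (timesteps,) bool
    dt_ms: float = NEURAL_DT_MS
    split: str = "train"
    meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.rates.shape[2]


def neural_task_inputs(conditions: pd.DataFrame):
    """Inputs and targets on the 150-step grid for a condition table.

    Context cue channels carry 1.2/0.2 for the whole trial; sensory
    channels carry (1 +/- coherence)/2 from 750 ms; no baseline term is
    added (recorded rates are centered, so the model fits deviations).
    Targets are 1.2/0.2 by choice, penalized in the last 250 ms.
    """
    K = len(conditions)
    u = np.zeros((K, NEURAL_T, 6))
    z = np.full((K, NEURAL_T, 2), task_mod.TARGET_LOW)
    for k, row in enumerate(conditions.itertuples(index=False)):
        hi, lo = task_mod.CUE_AMP_HIGH, task_mod.CUE_AMP_LOW
        if row.context == "motion":
            u[k, NEURAL_CTX_ON:, 0] = hi
            u[k, NEURAL_CTX_ON:, 1] = lo
        else:
            u[k, NEURAL_CTX_ON:, 0] = lo
            u[k, NEURAL_CTX_ON:, 1] = hi
        mc, cc = row.motion_coherence, row.color_coherence
        u[k, NEURAL_STIM_ON:, 2] = (1 - mc) / 2
        u[k, NEURAL_STIM_ON:, 3] = (1 + mc) / 2
        u[k, NEURAL_STIM_ON:, 4] = (1 - cc) / 2
        u[k, NEURAL_STIM_ON:, 5] = (1 + cc) / 2
        if row.choice == "right":
            z[k, -NEURAL_RESPONSE_STEPS:, 0] = task_mod.TARGET_HIGH
        else:
            z[k, -NEURAL_RESPONSE_STEPS:, 1] = task_mod.TARGET_HIGH
    observed = np.zeros(NEURAL_T, dtype=bool)
    observed[-NEURAL_OBSERVED_STEPS:] = True
    response = np.zeros(NEURAL_T, dtype=bool)
    response[-NEURAL_RESPONSE_STEPS:] = True
    return u, z, observed, response


def preprocess_rates(
    counts: np.ndarray,
    trial_table: pd.DataFrame,
    bin_ms: float = 50.0,
    smooth_sigma_ms: float = 40.0,
    var_keep: float = 0.5,
    min_trials: int = 4,
    seed: int | None = 0,
) -> tuple[RatePopulation, RatePopulation]:
    """Reduce single-trial spike counts to denoised condition averages.

    Parameters
    ----------
    counts : (units, trials, bins) spike counts in ``bin_ms`` windows
        covering the observed epoch (15 bins for the standard layout).
    trial_table : one row per trial with columns context, motion_coherence,
        color_coherence, choice.
    var_keep : cumulative variance fraction retained by the principal
        component projection (components are chosen on the train split).

    Trials of each condition are split into two equal disjoint sets; within
    each split the rates are trial-averaged per condition, z-scored per
    unit, Gaussian-smoothed over time, and the cross-condition mean at each
    timestep is removed. Conditions with fewer than ``min_trials`` trials
    are dropped with a warning, as are units with zero variance.

    Returns (train, test) populations sharing the same unit basis.
    """
    U, n_trials, n_bins = counts.shape
    rng = np.random.default_rng(seed)
    keys = list(
        zip(trial_table["context"], trial_table["motion_coherence"], trial_table["color_coherence"])
    )
    choice_of = {}
    by_cond: dict = {}
    for i, k in enumerate(keys):
        by_cond.setdefault(k, []).append(i)
        choice_of[k] = trial_table["choice"].iloc[i]
    kept = {k: v for k, v in by_cond.items() if len(v) >= min_trials}
    if len(kept) < len(by_cond):
        warnings.warn(f"dropped {len(by_cond) - len(kept)} conditions with < {min_trials} trials")
    cond_keys = sorted(kept)
    halves = ([], [])
    for k in cond_keys:
        idx = np.array(kept[k])
        rng.shuffle(idx)
        half = len(idx) // 2
        avg0 = counts[:, idx[:half]].mean(axis=1)
        avg1 = counts[:, idx[half:]].mean(axis=1)
        halves[0].append(avg0)
        halves[1].append(avg1)
    pops = []
    smooth_bins = smooth_sigma_ms / bin_ms
    live = None
    components = None
    cond_df = pd.DataFrame(
        {
            "context": [k[0] for k in cond_keys],
            "motion_coherence": [k[1] for k in cond_keys],
            "color_coherence": [k[2] for k in cond_keys],
            "choice": [choice_of[k] for k in cond_keys],
        }
    )
    u, z, observed, response = neural_task_inputs(cond_df)
    for split_id, stack in enumerate(halves):
        R = np.stack(stack)  # (conditions, units, bins)
        mu = R.mean(axis=(0, 2), keepdims=True)
        sd = R.std(axis=(0, 2), keepdims=True)
        if live is None:
            live = sd[0, :, 0] > 0
            if not live.all():
                warnings.warn(f"dropped {int((~live).sum())} constant-rate units")
        Rz = (R[:, live] - mu[:, live]) / np.maximum(sd[:, live], 1e-12)
        Rz = gaussian_filter1d(Rz, smooth_bins, axis=2, mode="nearest")
        Rz -= Rz.mean(axis=0, keepdims=True)  # condition-independent term per timestep
        X = Rz.transpose(0, 2, 1).reshape(-1, int(live.sum()))  # (cond*time, units)
        if components is None:
            Xc = X
            _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
            frac = np.cumsum(s**2) / np.sum(s**2)
            n_comp = int(np.searchsorted(frac, var_keep) + 1)
            components = Vt[:n_comp]
        scores = X @ components.T
        rates_obs = scores.reshape(len(cond_keys), n_bins, -1)
        rates = np.zeros((len(cond_keys), NEURAL_T, rates_obs.shape[2]))
        rates[:, observed] = rates_obs[:, -NEURAL_OBSERVED_STEPS:]
        pops.append(
            RatePopulation(
                rates=rates,
                conditions=cond_df,
                u=u,
                z_target=z,
                observed_mask=observed,
                response_mask=response,
                split="train" if split_id == 0 else "test",
                meta={"n_components": rates_obs.shape[2], "var_keep": var_keep},
            )
        )
    return pops[0], pops[1]


def suppression_circuit(
    n: int = 8,
    N: int = 8,
    inhibition: float = -0.4,
    excitation: float = 0.35,
    self_excitation: float = 0.3,
    alpha: float = NEURAL_ALPHA,
    sigma_rec: float = 0.0,
) -> LatentCircuit:
    """Hand-built ground-truth circuit implementing the suppression mechanism.

    Context nodes inhibit the sensory nodes that are irrelevant in their
    context; sensory nodes excite their associated choice node; choice
    nodes mutually inhibit. Used as a planted ground truth for recovery
    tests and synthetic populations.
    """
    w = np.zeros((n, n))
    np.fill_diagonal(w, self_excitation)
    # motion-context node 0 inhibits color nodes 4, 5; color-context node 1
    # inhibits motion nodes 2, 3
    w[4, 0] = w[5, 0] = inhibition
    w[2, 1] = w[3, 1] = inhibition
    # sensory -> choice: motion-R (3) and color-red (5) drive right (6);
    # motion-L (2) and color-green (4) drive left (7)
    w[6, 3] = w[6, 5] = excitation
    w[7, 2] = w[7, 4] = excitation
    # mutual inhibition between choice nodes
    w[6, 7] = w[7, 6] = -0.2
    w_in = np.zeros((n, 6))
    np.fill_diagonal(w_in[:6], 1.0)
    w_out = np.zeros((2, n))
    w_out[0, n - 2] = 1.0
    w_out[1, n - 1] = 1.0
    return LatentCircuit(
        w_rec=w,
        w_in=w_in,
        w_out=w_out,
        B_cayley=np.zeros((N, N)),
        alpha=alpha,
        sigma_rec=sigma_rec,
    )


def generate_synthetic_population(
    ground_truth: LatentCircuit,
    N_units: int = 40,
    task_variance_fraction: float = 0.1,
    noise_sd: float = 0.05,
    n_distractor: int = 12,
    seed: int | None = 0,
) -> tuple[RatePopulation, dict]:
    """Synthetic condition-averaged population with known ground truth.

    Simulates the ground-truth circuit over all 72 conditions on the
    neural-data grid, embeds the centered latent trajectories through a
    random orthonormal map into ``N_units`` dimensions scaled to occupy
    ``task_variance_fraction`` of the total variance, and adds smooth
    task-irrelevant latent dimensions plus white observation noise.

    Returns the population and a record of the generating parameters
    (including the embedding used).
    """
    if not 0 < task_variance_fraction <= 1:
        raise ValueError("task_variance_fraction must be in (0, 1]")
    n = ground_truth.n
    if N_units < n:
        raise ValueError("N_units must be at least the circuit size")
    rng = np.random.default_rng(seed)
    conds = task_mod.enumerate_conditions()
    cond_df = pd.DataFrame(
        {
            "context": [c.context for c in conds],
            "motion_coherence": [c.motion_coherence for c in conds],
            "color_coherence": [c.color_coherence for c in conds],
            "choice": [c.correct_choice for c in conds],
        }
    )
    u, z, observed, response = neural_task_inputs(cond_df)
    x_full, _ = forward(ground_truth.w_rec, ground_truth.w_in, u, ground_truth.alpha)
    x = x_full[:, 1:]
    x_obs = x[:, observed]
    x_c = x_obs - x_obs.mean(axis=(0, 1), keepdims=True)
    # random orthonormal embedding of the task subspace
    E, _ = np.linalg.qr(rng.standard_normal((N_units, N_units)))
    E_task = E[:, :n]
    n_distractor = min(n_distractor, N_units - n)
    E_dist = E[:, n : n + n_distractor]
    signal = x_c @ E_task.T
    # smooth task-irrelevant latents, shared structure across conditions
    T_obs = x_obs.shape[1]
    dist = rng.standard_normal((len(conds), T_obs, n_distractor))
    dist = gaussian_filter1d(dist, 2.0, axis=1, mode="nearest")
    dist -= dist.mean(axis=(0, 1), keepdims=True)
    v_sig = signal.var()
    v_dist_target = v_sig * (1.0 - task_variance_fraction) / task_variance_fraction
    dist_emb = dist @ E_dist.T
    cur = dist_emb.var()
    if cur > 0 and task_variance_fraction < 1:
        dist_emb *= np.sqrt(v_dist_target / cur)
    else:
        dist_emb[:] = 0.0
    rates_obs = signal + dist_emb + noise_sd * rng.standard_normal(signal.shape)
    rates = np.zeros((len(conds), NEURAL_T, N_units))
    rates[:, observed] = rates_obs
    pop = RatePopulation(
        rates=rates,
        conditions=cond_df,
        u=u,
        z_target=z,
        observed_mask=observed,
        response_mask=response,
        meta={
            "synthetic": True,
            "task_variance_fraction": task_variance_fraction,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )
    record = {
        "circuit": ground_truth,
        "embedding": E_task,
        "distractor_basis": E_dist,
        "task_variance_fraction": task_variance_fraction,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return pop, record


def load_external_recording(path):
    """Converter stub for external recording archives in their native layout.

    The archived primate dataset ships in a lab-specific format that this
    package does not parse. Export your recordings to the documented inputs
    of :func:`preprocess_rates` (a units x trials x bins count array plus a
    trial table with context, motion_coherence, color_coherence, choice)
    and call that function directly.
    """
    raise NotImplementedError(
        "External recordings must be converted to the preprocess_rates layout: "
        "counts[units, trials, bins] and a trial table with columns context, "
        "motion_coherence, color_coherence, choice. See preprocess_rates."
    )
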