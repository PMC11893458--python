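"""Context-dependent decision-making task.

Each trial presents a context cue (motion or color) followed, after a short
delay, by a compound sensory stimulus carrying motion and color evidence.
The correct choice is determined by the sign of the coherence of the cued
(relevant) feature: positive coherence (right motion / red color) maps to
the right choice.

The network receives six input channels, in this order:

    0: u_m    motion-context cue
    1: u_c    color-context cue
    2: u_mL   motion-left evidence
    3: u_mR   motion-right evidence
    4: u_cG   color-green evidence
    5: u_cR   color-red evidence

and must drive two outputs (z1 = right, z2 = left) toward 1.2 / 0.2 at the
end of the trial, while staying at 0.2 on both outputs during the cue epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

COHERENCES = (-0.2, -0.12, -0.04, 0.04, 0.12, 0.2)
CONTEXTS = ("motion", "color")
N_CHANNELS = 6

# Epoch layout (ms). The trial end is not tied to any stimulus event; the
# response window is the last 750 ms and targets switch on at 2,250 ms, so a
# 3,000-ms trial places the target onset exactly at the response window start.
DT_MS = 40.0
TRIAL_MS = 3000.0
CUE_ON_MS, CUE_OFF_MS = 320.0, 1000.0
STIM_ON_MS = 1200.0
TARGET_ON_MS = 2250.0
RESPONSE_MS = 750.0

CUE_AMP_HIGH, CUE_AMP_LOW = 1.2, 0.2
TARGET_HIGH, TARGET_LOW = 1.2, 0.2
BASELINE = 0.2
SIGMA_IN = 0.01


def _step(ms: float, dt_ms: float) -> int:
    """Snap a time (ms) to the nearest step on a grid closed at the start."""
    return int(round(ms / dt_ms))


def n_steps(dt_ms: float = DT_MS, trial_ms: float = TRIAL_MS) -> int:
    return _step(trial_ms, dt_ms)


@dataclass(frozen=True)
class TrialCondition:
    """One of the 72 task conditions (2 contexts x 6 x 6 coherences)."""

    context: str
    motion_coherence: float
    color_coherence: float

    def __post_init__(self):
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")

    @property
    def relevant_coherence(self) -> float:
        return self.motion_coherence if self.context == "motion" else self.color_coherence

    @property
    def correct_choice(self) -> str:
        return "right" if self.relevant_coherence > 0 else "left"


@dataclass
class TrialBatch:
    """A batch of task trials: inputs, targets, loss mask and metadata."""

    u: np.ndarray  # (trials, timesteps, 6)
    z_target: np.ndarray  # (trials, timesteps, 2)
    mask: np.ndarray  # (trials, timesteps) bool; True where task error is penalized
    conditions: list[TrialCondition]
    dt_ms: float = DT_MS
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return self.u.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.u.shape[1]

    def condition_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "context": [c.context for c in self.conditions],
                "motion_coherence": [c.motion_coherence for c in self.conditions],
                "color_coherence": [c.color_coherence for c in self.conditions],
                "correct_choice": [c.correct_choice for c in self.conditions],
            }
        )


def enumerate_conditions() -> list[TrialCondition]:
    """All 72 unique conditions: 2 contexts x 6 motion x 6 color coherences."""
    return [
        TrialCondition(ctx, mc, cc)
        for ctx in CONTEXTS
        for mc in COHERENCES
        for cc in COHERENCES
    ]


def stimulus_profile(
    cond: TrialCondition,
    dt_ms: float = DT_MS,
    trial_ms: float = TRIAL_MS,
    baseline: float = BASELINE,
    baseline_on_cue: bool = True,
) -> np.ndarray:
    """Noiseless input time series (timesteps, 6) for one condition.

    The context cue (1.2 cued / 0.2 other) is on from 320 to 1,000 ms; the
    four sensory channels carry (1 +/- coherence)/2 from 1,200 ms to trial
    end; a baseline u0 = 0.2 is added to every channel at every step (set
    ``baseline_on_cue=False`` to leave the cue channels at their nominal
    amplitude during the cue epoch).
    """
    T = n_steps(dt_ms, trial_ms)
    u = np.full((T, N_CHANNELS), baseline)
    cue = slice(_step(CUE_ON_MS, dt_ms), _step(CUE_OFF_MS, dt_ms))
    stim = slice(_step(STIM_ON_MS, dt_ms), T)
    hi, lo = CUE_AMP_HIGH, CUE_AMP_LOW
    if cond.context == "motion":
        cue_amp = (hi, lo)
    else:
        cue_amp = (lo, hi)
    off = baseline if baseline_on_cue else 0.0
    u[cue, 0] = cue_amp[0] + off
    u[cue, 1] = cue_amp[1] + off
    mc, cc = cond.motion_coherence, cond.color_coherence
    u[stim, 2] = (1.0 - mc) / 2.0 + baseline
    u[stim, 3] = (1.0 + mc) / 2.0 + baseline
    u[stim, 4] = (1.0 - cc) / 2.0 + baseline
    u[stim, 5] = (1.0 + cc) / 2.0 + baseline
    return u


def target_profile(
    cond: TrialCondition, dt_ms: float = DT_MS, trial_ms: float = TRIAL_MS
) -> tuple[np.ndarray, np.ndarray]:
    """Target outputs (timesteps, 2) and loss mask (timesteps,) for a condition.

    Both outputs are held at 0.2 during the cue epoch; from 2,250 ms the
    targets are (1.2, 0.2) for right choices and (0.2, 1.2) for left. The
    mask is True exactly during the cue epoch and the final 750 ms.
    """
    T = n_steps(dt_ms, trial_ms)
    z = np.full((T, 2), TARGET_LOW)
    tgt = slice(_step(TARGET_ON_MS, dt_ms), T)
    if cond.correct_choice == "right":
        z[tgt, 0] = TARGET_HIGH
    else:
        z[tgt, 1] = TARGET_HIGH
    mask = np.zeros(T, dtype=bool)
    mask[_step(CUE_ON_MS, dt_ms) : _step(CUE_OFF_MS, dt_ms)] = True
    mask[_step(trial_ms - RESPONSE_MS, dt_ms) : T] = True
    return z, mask


def make_batch(
    conditions: list[TrialCondition],
    n_per_condition: int = 1,
    seed: int | None = 0,
    sigma_in: float = SIGMA_IN,
    alpha: float = 0.2,
    dt_ms: float = DT_MS,
    trial_ms: float = TRIAL_MS,
) -> TrialBatch:
    """Assemble a batch with ``n_per_condition`` noisy trials per condition.

    Input noise sqrt(2/alpha)*sigma_in*eta_t is added independently to every
    channel at every step; the batch is deterministic given the seed.
    """
    if not conditions:
        raise ValueError("empty condition list")
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    rng = np.random.default_rng(seed)
    trial_conds = [c for c in conditions for _ in range(n_per_condition)]
    u = np.stack([stimulus_profile(c, dt_ms, trial_ms) for c in trial_conds])
    zs, ms = zip(*(target_profile(c, dt_ms, trial_ms) for c in trial_conds))
    if sigma_in > 0:
        u = u + np.sqrt(2.0 / alpha) * sigma_in * rng.standard_normal(u.shape)
    return TrialBatch(
        u=u,
        z_target=np.stack(zs),
        mask=np.stack(ms),
        conditions=trial_conds,
        dt_ms=dt_ms,
        seed=seed,
    )


def training_batch(
    n_trials: int,
    seed: int | None = 0,
    sigma_in: float = SIGMA_IN,
    alpha: float = 0.2,
    dt_ms: float = DT_MS,
    trial_ms: float = TRIAL_MS,
) -> TrialBatch:
    """Batch of trials with conditions sampled uniformly from the 72-cell grid."""
    rng = np.random.default_rng(seed)
    conds = enumerate_conditions()
    picks = [conds[i] for i in rng.integers(0, len(conds), size=n_trials)]
    u = np.stack([stimulus_profile(c, dt_ms, trial_ms) for c in picks])
    zs, ms = zip(*(target_profile(c, dt_ms, trial_ms) for c in picks))
    if sigma_in > 0:
        u = u + np.sqrt(2.0 / alpha) * sigma_in * rng.standard_normal(u.shape)
    return TrialBatch(
        u=u,
        z_target=np.stack(zs),
        mask=np.stack(ms),
        conditions=picks,
        dt_ms=dt_ms,
        seed=seed,
    )
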