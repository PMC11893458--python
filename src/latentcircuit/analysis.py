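"""Axis projections, linear decoding, solution-space statistics.

The columns of the embedding Q define behaviorally meaningful axes in the
population state space (context, choice, motion, color), each the
normalized difference of the two columns corresponding to a node pair.
This module also quantifies the solution space across fits and networks:
PCA + Gaussian-mixture clustering of fitted connectivity, best-vs-rest
uniqueness correlations, the across/within-network variance ratio, and a
permutation (shuffle) test of whether neural responses constrain the
inferred connectivity beyond the task itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression
from sklearn.mixture import GaussianMixture

from . import task as task_mod
from .circuit import FitConfig, fit_latent, split_trials

__all__ = [
    "AxisSet",
    "DecoderResult",
    "SolutionSpace",
    "ShuffleTestResult",
    "project_onto_axes",
    "condition_average",
    "suppression_ratio",
    "suppression_test",
    "train_decoder",
    "cluster_solutions",
    "uniqueness",
    "variance_ratio",
    "shuffle_test",
    "psychometric_slopes",
]

# latent node layout (see circuit._structural_masks / task channel order)
NODE_MOTION_CTX, NODE_COLOR_CTX = 0, 1
NODE_MOTION_L, NODE_MOTION_R = 2, 3
NODE_COLOR_G, NODE_COLOR_R = 4, 5
NODE_RIGHT, NODE_LEFT = 6, 7


@dataclass
class AxisSet:
    """Task axes from the embedding: each a normalized difference of two
    columns of Q (motion-ctx - color-ctx, right - left, motion R - L,
    color red - green)."""

    context: np.ndarray
    choice: np.ndarray
    motion: np.ndarray
    color: np.ndarray

    @classmethod
    def from_embedding(cls, Q: np.ndarray) -> "AxisSet":
        def diff(i, j):
            v = Q[:, i] - Q[:, j]
            return v / np.linalg.norm(v)

        return cls(
            context=diff(NODE_MOTION_CTX, NODE_COLOR_CTX),
            choice=diff(NODE_RIGHT, NODE_LEFT),
            motion=diff(NODE_MOTION_R, NODE_MOTION_L),
            color=diff(NODE_COLOR_R, NODE_COLOR_G),
        )

    def items(self):
        return [
            ("context", self.context),
            ("choice", self.choice),
            ("motion", self.motion),
            ("color", self.color),
        ]


def project_onto_axes(y: np.ndarray, axes: AxisSet, conditions) -> pd.DataFrame:
    """Per-condition mean and s.d. of axis projections over time.

    Returns a long-form frame with columns axis, context, motion_coherence,
    color_coherence, timestep, mean, sd.
    """
    ctx = np.array([c.context for c in conditions])
    mc = np.array([c.motion_coherence for c in conditions])
    cc = np.array([c.color_coherence for c in conditions])
    rows = []
    for name, axis in axes.items():
        proj = y @ axis  # (K, T)
        df = pd.DataFrame(
            {"context": ctx, "motion_coherence": mc, "color_coherence": cc}
        )
        for key, grp in df.groupby(["context", "motion_coherence", "color_coherence"]):
            p = proj[grp.index.values]
            m = p.mean(axis=0)
            s = p.std(axis=0)
            for t in range(p.shape[1]):
                rows.append(
                    {
                        "axis": name,
                        "context": key[0],
                        "motion_coherence": key[1],
                        "color_coherence": key[2],
                        "timestep": t,
                        "mean": m[t],
                        "sd": s[t],
                    }
                )
    return pd.DataFrame(rows)


def condition_average(proj: np.ndarray, labels: np.ndarray) -> dict:
    """Average a (trials, T) projection within groups given per-trial labels."""
    return {v: proj[labels == v].mean(axis=0) for v in np.unique(labels)}


def _stim_slice(dt_ms: float, T: int) -> slice:
    return slice(task_mod._step(task_mod.STIM_ON_MS, dt_ms), T)


def _coherence_variance(proj, conditions, feature, context, stim):
    """Across-coherence variance of per-coherence mean projections in one
    context, averaged over the stimulus epoch."""
    ctx = np.array([c.context for c in conditions])
    coh = np.array(
        [
            c.motion_coherence if feature == "motion" else c.color_coherence
            for c in conditions
        ]
    )
    sel = ctx == context
    means = np.stack(
        [proj[sel & (coh == v)].mean(axis=0) for v in np.unique(coh[sel])]
    )  # (levels, T)
    return float(means.var(axis=0)[stim].mean())


def suppression_ratio(
    y: np.ndarray, axis: np.ndarray, conditions, feature: str, dt_ms: float = task_mod.DT_MS
) -> float:
    """Variance of the axis projection across coherences of ``feature`` in
    the irrelevant context divided by the relevant context (< 1 indicates
    suppression of the irrelevant stimulus representation)."""
    proj = y @ axis
    stim = _stim_slice(dt_ms, y.shape[1])
    relevant = feature  # the feature is relevant in its namesake context
    irrelevant = "color" if feature == "motion" else "motion"
    v_rel = _coherence_variance(proj, conditions, feature, relevant, stim)
    v_irr = _coherence_variance(proj, conditions, feature, irrelevant, stim)
    return v_irr / v_rel


def suppression_test(
    y: np.ndarray, axis: np.ndarray, conditions, feature: str, dt_ms: float = task_mod.DT_MS
):
    """One-sided Mann-Whitney test that per-condition projections along the
    axis deviate less from their context mean in the irrelevant context.

    Each condition contributes the stimulus-epoch average of its absolute
    deviation from the context-mean trajectory (36 conditions per context).
    """
    proj = y @ axis
    stim = _stim_slice(dt_ms, y.shape[1])
    ctx = np.array([c.context for c in conditions])
    key = np.array(
        [(c.context, c.motion_coherence, c.color_coherence) for c in conditions],
        dtype=object,
    )
    scores = {"motion": [], "color": []}
    for context in task_mod.CONTEXTS:
        sel = ctx == context
        ctx_mean = proj[sel].mean(axis=0)
        conds = {tuple(k) for k in key[sel]}
        for k in sorted(conds):
            mask = sel & np.array([tuple(q) == k for q in key])
            dev = np.abs(proj[mask].mean(axis=0) - ctx_mean)[stim].mean()
            scores[context].append(dev)
    irrelevant = "color" if feature == "motion" else "motion"
    u, p = stats.mannwhitneyu(
        scores[irrelevant], scores[feature], alternative="less"
    )
    return float(u), float(p)


@dataclass
class DecoderResult:
    beta: np.ndarray  # (N,)
    intercept: float
    r2_train: float
    r2_test: float
    axis: np.ndarray  # beta normalized to unit length


def train_decoder(
    y: np.ndarray,
    coherence: np.ndarray,
    dt_ms: float = task_mod.DT_MS,
    test_fraction: float = 0.5,
    seed: int | None = 0,
) -> DecoderResult:
    """Linear regression of signed coherence on stimulus-epoch responses.

    Pools population activity over trials and stimulus-epoch timesteps,
    fits c = beta y + b on a train split of trials, scores both splits.
    """
    if np.unique(coherence).size < 2:
        raise ValueError("need at least two distinct coherence values")
    K, T, N = y.shape
    stim = _stim_slice(dt_ms, T)
    rng = np.random.default_rng(seed)
    order = rng.permutation(K)
    n_test = int(round(K * test_fraction))
    test_idx, train_idx = order[:n_test], order[n_test:]

    def pool(idx):
        Y = y[idx][:, stim].reshape(-1, N)
        c = np.repeat(coherence[idx], y[idx][:, stim].shape[1])
        return Y, c

    Y_tr, c_tr = pool(train_idx)
    if np.allclose(Y_tr.std(axis=0), 0):
        raise ValueError("degenerate design: constant responses")
    Y_te, c_te = pool(test_idx)
    model = LinearRegression().fit(Y_tr, c_tr)
    beta = model.coef_
    return DecoderResult(
        beta=beta,
        intercept=float(model.intercept_),
        r2_train=float(model.score(Y_tr, c_tr)),
        r2_test=float(model.score(Y_te, c_te)),
        axis=beta / np.linalg.norm(beta),
    )


@dataclass
class SolutionSpace:
    projection: np.ndarray  # (fits, 2) principal-component scores
    labels: np.ndarray  # (fits,) mixture component per fit
    cluster_means: list  # per-cluster mean (n, n) connectivity
    within_cluster_corr: list  # mean correlation of members to their cluster mean
    explained_variance_ratio: np.ndarray


def cluster_solutions(
    w_rec_list, n_components: int = 3, seed: int | None = 0
) -> SolutionSpace:
    """PCA projection and Gaussian-mixture partition of fitted connectivity.

    Flattened w_rec matrices are projected onto their first two principal
    components and partitioned with a full-covariance mixture (10 restarts,
    fixed seed)."""
    W = np.stack([np.asarray(w).ravel() for w in w_rec_list])
    if len(W) < n_components:
        raise ValueError("fewer fits than mixture components")
    pca = PCA(n_components=2)
    proj = pca.fit_transform(W)
    gmm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        n_init=10,
        random_state=0 if seed is None else seed % 2**31,
        reg_covar=1e-6,
    )
    labels = gmm.fit_predict(proj)
    shape = np.asarray(w_rec_list[0]).shape
    means, corrs = [], []
    for c in range(n_components):
        members = W[labels == c]
        if len(members) == 0:
            means.append(np.full(shape, np.nan))
            corrs.append(np.nan)
            continue
        mu = members.mean(axis=0)
        means.append(mu.reshape(shape))
        cs = [
            stats.pearsonr(m, mu)[0]
            for m in members
            if np.std(m) > 0 and np.std(mu) > 0
        ]
        corrs.append(float(np.mean(cs)) if cs else np.nan)
    return SolutionSpace(
        projection=proj,
        labels=labels,
        cluster_means=means,
        within_cluster_corr=corrs,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def uniqueness(w_rec_list) -> tuple[float, float, int]:
    """Mean and s.d. of Pearson correlations between the first (best) fit's
    flattened w_rec and each remaining fit; also the count of comparisons
    dropped because a matrix was constant."""
    if len(w_rec_list) < 2:
        raise ValueError("need at least two fits")
    ref = np.asarray(w_rec_list[0]).ravel()
    corrs, dropped = [], 0
    for w in w_rec_list[1:]:
        v = np.asarray(w).ravel()
        if np.std(ref) == 0 or np.std(v) == 0:
            dropped += 1
            continue
        corrs.append(stats.pearsonr(ref, v)[0])
    if not corrs:
        return float("nan"), float("nan"), dropped
    return float(np.mean(corrs)), float(np.std(corrs)), dropped


def variance_ratio(per_network_fits) -> float:
    """Across-network / within-network variance of latent connectivity.

    ``per_network_fits`` is a list (one entry per network) of lists of
    w_rec matrices, best fit first. The numerator is the element-wise
    variance of the best fits across networks (averaged over entries); the
    denominator is the element-wise variance across each network's
    converged fits, averaged over entries and networks.
    """
    if len(per_network_fits) < 2:
        raise ValueError("need at least two networks")
    best = np.stack([np.asarray(fits[0]).ravel() for fits in per_network_fits])
    across = float(best.var(axis=0).mean())
    within = []
    for fits in per_network_fits:
        if len(fits) < 2:
            raise ValueError("need at least two fits per network")
        W = np.stack([np.asarray(w).ravel() for w in fits])
        within.append(W.var(axis=0).mean())
    return across / float(np.mean(within))


@dataclass
class ShuffleTestResult:
    u_statistic: float
    p_value: float
    corr_original: np.ndarray
    corr_shuffled: np.ndarray
    original_task_r2: np.ndarray
    shuffled_task_r2: np.ndarray
    n_failed: int


def shuffle_test(
    y: np.ndarray,
    z: np.ndarray,
    batch,
    n_fits: int = 20,
    cfg: FitConfig | None = None,
    n: int = 8,
    seed: int | None = 0,
    permute: bool = True,
    **kwargs,
) -> ShuffleTestResult:
    """Permutation test of whether responses constrain latent connectivity.

    Fits ``n_fits`` circuits to the original responses and ``n_fits`` to
    responses randomly permuted across trials (inputs and outputs keep
    their pairing, so shuffled-arm circuits can still perform the task).
    Correlations of each fit's w_rec with the best original fit are
    compared with a one-sided rank-sum test (shuffled smaller).

    ``permute=False`` runs the calibration control: both arms fit the
    original data, so the p-value should be null-distributed.
    """
    cfg = cfg or FitConfig()
    ss = np.random.SeedSequence(seed)
    s_perm, s_cfg = (int(v) for v in ss.generate_state(2))
    rng = np.random.default_rng(s_perm)
    perm = rng.permutation(y.shape[0]) if permute else np.arange(y.shape[0])
    y_shuf = y[perm]
    split = split_trials(batch.conditions, seed=s_cfg)
    seeds = [int(v) % 2**31 for v in np.random.SeedSequence(s_cfg).generate_state(2 * n_fits)]
    n_failed = 0

    def run(data, arm_seeds):
        out = []
        nonlocal n_failed
        for s in arm_seeds:
            res = fit_latent(data, z, batch, replace(cfg, seed=s), n=n, split=split, **kwargs)
            if res.converged and np.isfinite(res.metrics.r2_total):
                out.append(res)
            else:
                n_failed += 1
        return out

    orig = run(y, seeds[:n_fits])
    shuf = run(y_shuf, seeds[n_fits:])
    if not orig or not shuf:
        raise RuntimeError("all fits failed in one arm of the shuffle test")
    orig.sort(key=lambda r: -r.metrics.r2_total)
    ref = orig[0].circuit.w_rec.ravel()
    c_orig = np.array([stats.pearsonr(ref, r.circuit.w_rec.ravel())[0] for r in orig[1:]])
    c_shuf = np.array([stats.pearsonr(ref, r.circuit.w_rec.ravel())[0] for r in shuf])
    u, p = stats.mannwhitneyu(c_shuf, c_orig, alternative="less")
    return ShuffleTestResult(
        u_statistic=float(u),
        p_value=float(p),
        corr_original=c_orig,
        corr_shuffled=c_shuf,
        original_task_r2=np.array([r.metrics.task_r2 for r in orig]),
        shuffled_task_r2=np.array([r.metrics.task_r2 for r in shuf]),
        n_failed=n_failed,
    )


def psychometric_slopes(table: pd.DataFrame) -> pd.DataFrame:
    """Per-context regression slopes of fraction-right on the relevant and
    irrelevant coherence (used to quantify decision-boundary rotations)."""
    rows = []
    for context, grp in table.groupby("context"):
        rel = "motion_coherence" if context == "motion" else "color_coherence"
        irr = "color_coherence" if context == "motion" else "motion_coherence"
        rows.append(
            {
                "context": context,
                "relevant_slope": np.polyfit(grp[rel], grp["frac_right"], 1)[0],
                "irrelevant_slope": np.polyfit(grp[irr], grp["frac_right"], 1)[0],
            }
        )
    return pd.DataFrame(rows)
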