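"""Decoding, projections, clustering, uniqueness and the shuffle machinery."""

import numpy as np
import pytest
from scipy import stats

from latentcircuit import analysis, task
from latentcircuit.analysis import (
    AxisSet,
    cluster_solutions,
    suppression_ratio,
    train_decoder,
    uniqueness,
    variance_ratio,
)
from latentcircuit.circuit import cayley_embed


def test_axis_set_is_normalized_differences_of_columns():
    Q = cayley_embed(np.random.default_rng(0).uniform(-1, 1, (12, 12)), 8)
    axes = AxisSet.from_embedding(Q)
    v = Q[:, 3] - Q[:, 2]
    np.testing.assert_allclose(axes.motion, v / np.linalg.norm(v))
    for _, a in axes.items():
        assert np.linalg.norm(a) == pytest.approx(1.0)


def test_projection_antisymmetry_for_balanced_loading():
    # activity loading equally on both nodes of a pair projects to ~0 on
    # their difference axis
    Q = cayley_embed(np.random.default_rng(1).uniform(-1, 1, (10, 10)), 8)
    axes = AxisSet.from_embedding(Q)
    x = np.zeros((4, 6, 8))
    x[:, :, 2] = x[:, :, 3] = np.random.default_rng(2).random((4, 6))
    y = x @ Q.T
    proj = y @ axes.motion
    assert np.abs(proj).max() < 1e-10


def test_projection_invariant_to_consistent_unit_permutation():
    rng = np.random.default_rng(3)
    Q = cayley_embed(rng.uniform(-1, 1, (10, 10)), 8)
    y = rng.standard_normal((5, 7, 10))
    perm = rng.permutation(10)
    a = y @ AxisSet.from_embedding(Q).color
    b = y[:, :, perm] @ AxisSet.from_embedding(Q[perm]).color
    np.testing.assert_allclose(a, b)


def test_decoder_exact_on_noiseless_linear_data():
    rng = np.random.default_rng(4)
    K, T, N = 40, task.n_steps(), 6
    coh = rng.choice(task.COHERENCES, K)
    v = rng.standard_normal(N)
    y = coh[:, None, None] * v[None, None, :] * np.ones((K, T, 1))
    res = train_decoder(y, coh, seed=0)
    assert res.r2_train == pytest.approx(1.0, abs=1e-10)
    assert res.r2_test == pytest.approx(1.0, abs=1e-10)
    beta_dir = res.axis
    v_dir = v / np.linalg.norm(v)
    assert abs(abs(beta_dir @ v_dir) - 1) < 1e-8


def test_decoder_input_validation():
    y = np.zeros((4, task.n_steps(), 3))
    with pytest.raises(ValueError):
        train_decoder(y, np.full(4, 0.2), seed=0)  # single coherence level
    with pytest.raises(ValueError):
        train_decoder(y, np.array([0.2, -0.2, 0.2, -0.2]), seed=0)  # constant y


def test_cluster_recovers_planted_blobs():
    rng = np.random.default_rng(5)
    centers = [rng.standard_normal((8, 8)) * 2 for _ in range(3)]
    ws, truth = [], []
    for c, mu in enumerate(centers):
        for _ in range(12):
            ws.append(mu + 0.05 * rng.standard_normal((8, 8)))
            truth.append(c)
    space = cluster_solutions(ws, n_components=3, seed=0)
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(truth, space.labels) > 0.95
    assert all(c > 0.99 for c in space.within_cluster_corr)
    # determinism with a fixed seed
    again = cluster_solutions(ws, n_components=3, seed=0)
    np.testing.assert_array_equal(space.labels, again.labels)


def test_cluster_handles_degenerate_identical_fits():
    w = np.ones((4, 4))
    ws = [w + 1e-9 * np.random.default_rng(i).standard_normal((4, 4)) for i in range(6)]
    space = cluster_solutions(ws, n_components=3, seed=0)
    assert len(space.labels) == 6


def test_cluster_requires_enough_fits():
    with pytest.raises(ValueError):
        cluster_solutions([np.eye(3)] * 2, n_components=3)


def test_uniqueness_identical_and_null():
    w = np.random.default_rng(6).standard_normal((8, 8))
    mean, sd, dropped = uniqueness([w, w.copy(), w.copy()])
    assert mean == pytest.approx(1.0)
    assert dropped == 0
    rng = np.random.default_rng(7)
    rand = [rng.standard_normal((8, 8)) for _ in range(40)]
    mean, sd, _ = uniqueness(rand)
    assert abs(mean) < 0.1
    # constant matrices are reported as dropped
    _, _, dropped = uniqueness([w, np.zeros((8, 8))])
    assert dropped == 1


def test_variance_ratio_trivial_and_planted():
    w = np.random.default_rng(8).standard_normal((8, 8))
    jitter = lambda s: w + 1e-3 * np.random.default_rng(s).standard_normal((8, 8))
    same = [[jitter(i * 10 + j) for j in range(3)] for i in range(4)]
    assert variance_ratio(same) == pytest.approx(1.0, abs=0.5)
    rng = np.random.default_rng(9)
    fam1, fam2 = rng.standard_normal((8, 8)), rng.standard_normal((8, 8))
    planted = []
    for i, fam in enumerate([fam1, fam2, fam1, fam2]):
        planted.append([fam + 0.01 * rng.standard_normal((8, 8)) for _ in range(3)])
    assert variance_ratio(planted) > 10


def test_rank_sum_matches_brute_force_on_small_samples():
    # the shuffle test relies on the one-sided rank-sum; check the library
    # statistic against an explicit rank computation
    rng = np.random.default_rng(10)
    a, b = rng.standard_normal(6), rng.standard_normal(8) + 0.5
    u, p = stats.mannwhitneyu(a, b, alternative="less")
    brute_u = sum((x > yv) + 0.5 * (x == yv) for x in a for yv in b)
    assert u == pytest.approx(brute_u)


def test_suppression_ratio_on_constructed_projections():
    # construct responses whose coherence dependence exists only in the
    # relevant context
    conds = task.enumerate_conditions()
    N = 6
    axis = np.zeros(N)
    axis[0] = 1.0
    T = task.n_steps()
    y = np.zeros((len(conds), T, N))
    for k, c in enumerate(conds):
        if c.context == "motion":
            y[k, :, 0] = c.motion_coherence  # full modulation when relevant
        else:
            y[k, :, 0] = 0.1 * c.motion_coherence  # suppressed when irrelevant
    ratio = suppression_ratio(y, axis, conds, feature="motion")
    assert ratio == pytest.approx(0.01, abs=1e-6)
    u, p = analysis.suppression_test(y, axis, conds, feature="motion")
    assert p < 0.01


def test_project_onto_axes_table_layout():
    rng = np.random.default_rng(11)
    Q = cayley_embed(rng.uniform(-1, 1, (10, 10)), 8)
    axes = AxisSet.from_embedding(Q)
    conds = task.enumerate_conditions()[:6]
    y = rng.standard_normal((12, 5, 10))
    df = analysis.project_onto_axes(y, axes, [c for c in conds for _ in range(2)])
    assert set(df["axis"]) == {"context", "choice", "motion", "color"}
    assert df["timestep"].max() == 4
    # one row per axis x condition x timestep
    assert len(df) == 4 * 6 * 5
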