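from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from heteropool.gene_depth import (ABSENT, AMPLIFIED, PRESENT,
                                   CopyStateMatrix, GeneDepthMatrix,
                                   classify_copy_state, compute_gene_depth,
                                   depth_absence_regression, group_pav_freq,
                                   pav_length_bias, pav_pca, pav_summaries,
                                   permutation_differentiation_test,
                                   top_differentiated)

from conftest import make_states


def _genes(n, lengths=None):
    if lengths is None:
        lengths = np.full(n, 500)
    starts = np.arange(n) * 10_000
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "chrom": "chr01", "start": starts, "end": starts + np.asarray(lengths),
        "annotation": "hypothetical protein",
    })


# ------------------------------------------------------- compute_gene_depth

def test_uniform_depth_mean():
    track = pd.DataFrame({"chrom": "chr01", "pos": np.arange(100, 200),
                          "depth": 4})
    genes = pd.DataFrame({"gene_id": ["g0"], "chrom": ["chr01"],
                          "start": [100], "end": [200],
                          "annotation": ["x"]})
    out = compute_gene_depth(track, genes)
    assert out.depth[0, 0] == pytest.approx(4.0)


def test_no_reads_zero_depth():
    track = pd.DataFrame({"chrom": ["chr02"], "pos": [5], "depth": [9]})
    genes = pd.DataFrame({"gene_id": ["g0"], "chrom": ["chr01"],
                          "start": [0], "end": [100], "annotation": ["x"]})
    assert compute_gene_depth(track, genes).depth[0, 0] == 0.0


def test_piecewise_track_arithmetic_mean():
    # first half 2x, second half 6x -> mean 4
    pos = np.arange(0, 100)
    depth = np.where(pos < 50, 2, 6)
    track = pd.DataFrame({"chrom": "chr01", "pos": pos, "depth": depth})
    genes = pd.DataFrame({"gene_id": ["g0"], "chrom": ["chr01"],
                          "start": [0], "end": [100], "annotation": ["x"]})
    assert compute_gene_depth(track, genes).depth[0, 0] == pytest.approx(4.0)


def test_positions_missing_from_track_count_as_zero():
    track = pd.DataFrame({"chrom": "chr01", "pos": np.arange(0, 50),
                          "depth": 8})
    genes = pd.DataFrame({"gene_id": ["g0"], "chrom": ["chr01"],
                          "start": [0], "end": [100], "annotation": ["x"]})
    assert compute_gene_depth(track, genes).depth[0, 0] == pytest.approx(4.0)


# ---------------------------------------------------------- classification

def test_zero_depth_absent():
    states = make_states([[0.0, 5.0], [4.0, 4.0], [5.0, 3.0]])
    assert states.states[0, 0] == ABSENT


def test_amplified_above_three_times_median():
    # sample medians are 4.0; 12.1 > 3*4 amplified, 12.0 present (boundary)
    states = make_states([[4.0, 4.0], [12.1, 12.0], [4.0, 4.0]])
    assert states.median_depth[0] == pytest.approx(4.0)
    assert states.states[1, 0] == AMPLIFIED
    assert states.states[1, 1] == PRESENT


def test_median_includes_zero_depth_genes():
    depths = np.array([[0.0], [0.0], [2.0], [4.0], [6.0]])
    states = make_states(depths)
    assert states.median_depth[0] == pytest.approx(2.0)


def test_zero_median_sample_rejected():
    depths = np.zeros((4, 1))
    depths[0, 0] = 1.0
    with pytest.raises(ValueError, match="median gene depth is 0"):
        make_states(depths)


def test_state_partition_complete():
    rng = np.random.default_rng(0)
    depths = rng.gamma(2.0, 2.0, (60, 10))
    depths[rng.random((60, 10)) < 0.1] = 0.0
    states = make_states(depths)
    counts = [(states.states == s).sum() for s in (ABSENT, PRESENT, AMPLIFIED)]
    assert sum(counts) == 600


def test_state_frame_roundtrip():
    rng = np.random.default_rng(5)
    depths = rng.gamma(2.0, 2.0, (30, 6))
    depths[rng.random((30, 6)) < 0.2] = 0.0
    states = make_states(depths)
    back = CopyStateMatrix.from_frame(states.to_frame(), states.genes,
                                      states.median_depth)
    np.testing.assert_array_equal(back.states, states.states)


# -------------------------------------------------------------- summaries

def test_summaries_no_absent():
    states = make_states(np.full((5, 4), 3.0))
    s = pav_summaries(states)
    assert s["per_sample"]["n_absent"].sum() == 0
    assert s["absent_ge1"] == set()


def test_summaries_absent_in_all():
    depths = np.full((4, 3), 3.0)
    depths[1] = 0.0
    s = pav_summaries(make_states(depths))
    assert s["absent_all"] == {"g1"}
    assert s["absent_ge1"] == {"g1"}
    assert s["absent_gt1"] == {"g1"}


def test_summaries_counting_oracle():
    rng = np.random.default_rng(1)
    depths = rng.gamma(2.0, 2.0, (50, 20))
    depths[rng.random((50, 20)) < 0.15] = 0.0
    depths[rng.random((50, 20)) < 0.05] *= 10
    states = make_states(depths)
    s = pav_summaries(states)
    m = states.states
    for j in range(20):
        assert s["per_sample"]["n_absent"].iloc[j] == (m[:, j] == ABSENT).sum()
        assert (s["per_sample"]["n_amplified"].iloc[j]
                == (m[:, j] == AMPLIFIED).sum())
    for i in range(50):
        assert (s["per_gene"]["n_samples_absent"].iloc[i]
                == (m[i] == ABSENT).sum())
    expect_ge1 = {f"g{i}" for i in range(50) if (m[i] == ABSENT).any()}
    assert s["absent_ge1"] == expect_ge1


# ---------------------------------------------------------- group PAV freq

def test_group_pav_sign_convention():
    # absent in all R, none in B -> delta = freq_B - freq_R = -1
    depths = np.full((3, 6), 3.0)
    depths[0, 3:] = 0.0
    groups = np.asarray(["B"] * 3 + ["R"] * 3)
    pav = group_pav_freq(make_states(depths), groups)
    assert pav["delta_absent"].iloc[0] == pytest.approx(-1.0)
    assert pav["delta_absent"].iloc[1] == pytest.approx(0.0)


def test_group_pav_counting_oracle():
    rng = np.random.default_rng(2)
    depths = rng.gamma(2.0, 2.0, (40, 10))
    depths[rng.random((40, 10)) < 0.2] = 0.0
    groups = np.asarray(["B"] * 6 + ["R"] * 4)
    states = make_states(depths)
    pav = group_pav_freq(states, groups)
    m = states.states
    for i in range(40):
        fb = (m[i, :6] == ABSENT).sum() / 6
        fr = (m[i, 6:] == ABSENT).sum() / 4
        assert pav["freq_absent_B"].iloc[i] == pytest.approx(fb)
        assert pav["delta_absent"].iloc[i] == pytest.approx(fb - fr)


def test_top_differentiated_exact_count_and_ties():
    pav = pd.DataFrame({"gene_id": [f"g{i}" for i in range(100)],
                        "delta_absent": np.linspace(0, 1, 100)})
    out = top_differentiated(pav, pct=1)
    assert out["top_absent"].sum() == 1
    tie = pd.DataFrame({"gene_id": ["a", "b"], "delta_absent": [0.5, -0.5]})
    assert top_differentiated(tie, pct=1)["top_absent"].all()


def test_top_differentiated_sort_oracle():
    rng = np.random.default_rng(3)
    deltas = rng.uniform(-1, 1, 73)
    pav = pd.DataFrame({"gene_id": [f"g{i}" for i in range(73)],
                        "delta_absent": deltas})
    out = top_differentiated(pav, pct=10)
    cutoff = np.percentile(np.abs(deltas), 90)
    np.testing.assert_array_equal(out["top_absent"],
                                  np.abs(deltas) >= cutoff)


# --------------------------------------------------------- permutation test

def test_permutation_identity_statistic():
    rng = np.random.default_rng(4)
    depths = rng.gamma(2.0, 2.0, (30, 8))
    depths[rng.random((30, 8)) < 0.3] = 0.0
    groups = np.asarray(["B"] * 4 + ["R"] * 4)
    states = make_states(depths)
    obs, _, _ = permutation_differentiation_test(states, groups, n_perm=5,
                                                 seed=0)
    pav = group_pav_freq(states, groups)
    expected = (pav["delta_absent"].abs() >= 0.2 - 1e-12).sum()
    assert obs == expected


def test_permutation_exact_enumeration_oracle():
    """6 samples (3+3), 4 genes: p must match exact enumeration over all
    C(6,3)=20 label arrangements."""
    depths = np.array([
        [0.0, 0.0, 3.0, 3.0, 3.0, 3.0],
        [3.0, 0.0, 0.0, 3.0, 0.0, 3.0],
        [3.0, 3.0, 3.0, 0.0, 0.0, 0.0],
        [3.0, 3.0, 3.0, 3.0, 3.0, 0.0],
    ])
    groups = np.asarray(["B"] * 3 + ["R"] * 3)
    states = make_states(depths)
    thresh = 0.5
    absent = states.states == ABSENT

    def statistic(cols_b):
        cols_b = list(cols_b)
        cols_r = [c for c in range(6) if c not in cols_b]
        fb = absent[:, cols_b].mean(axis=1)
        fr = absent[:, cols_r].mean(axis=1)
        return (np.abs(fb - fr) >= thresh - 1e-12).sum()

    observed = statistic([0, 1, 2])
    null = [statistic(c) for c in combinations(range(6), 3)]
    exact_p = np.mean([s >= observed for s in null])

    n_perm = 40_000
    _, null_counts, p = permutation_differentiation_test(
        states, groups, diff_threshold=thresh, n_perm=n_perm, seed=7)
    # the add-one estimator converges to the enumeration probability
    assert p == pytest.approx(exact_p, abs=0.01)


def test_permutation_null_p_roughly_uniform():
    rng = np.random.default_rng(8)
    ps = []
    for rep in range(40):
        depths = rng.gamma(2.0, 2.0, (40, 12)) + 0.5
        depths[rng.random((40, 12)) < 0.2] = 0.0
        groups = np.asarray(["B"] * 6 + ["R"] * 6)
        states = make_states(depths)
        _, _, p = permutation_differentiation_test(
            states, groups, n_perm=99, seed=int(rng.integers(2 ** 31)))
        ps.append(p)
    # exchangeable labels: p should not pile up near 0
    assert np.mean(np.asarray(ps) <= 0.05) < 0.25


def test_permutation_planted_signal_beats_every_label_shuffle():
    rng = np.random.default_rng(9)
    depths = rng.gamma(3.0, 2.0, (100, 30)) + 1.0
    # 30% of genes carry R-biased deletions (freq ~0.75 in R, ~0.05 in B)
    del_prob = np.zeros((100, 30))
    del_prob[:30, 15:] = 0.75
    del_prob[:30, :15] = 0.05
    depths[rng.random((100, 30)) < del_prob] = 0.0
    groups = np.asarray(["B"] * 15 + ["R"] * 15)
    states = make_states(depths)
    obs, null_counts, p = permutation_differentiation_test(
        states, groups, diff_threshold=0.5, n_perm=199, seed=1)
    assert obs > null_counts.max()
    assert p == pytest.approx(1 / 200)


# --------------------------------------------------------------- regression

def _normal_equations(X, y):
    return np.linalg.solve(X.T @ X, X.T @ y)


def test_regression_constant_response():
    df = pd.DataFrame({"median_depth": [1, 2, 3, 4, 5, 6.0],
                       "group": ["B"] * 3 + ["R"] * 3,
                       "n_absent": [7] * 6})
    rep = depth_absence_regression(df)
    assert np.isnan(rep.f_depth) and rep.r2_full == 0.0
    assert "constant" in rep.note


def test_regression_perfect_linear_fit():
    depth = np.array([1, 2, 3, 4, 5, 6, 7, 8.0])
    df = pd.DataFrame({"median_depth": depth,
                       "group": ["B"] * 4 + ["R"] * 4,
                       "n_absent": 100 - 10 * depth})
    rep = depth_absence_regression(df)
    assert rep.r2_depth == pytest.approx(1.0)
    # depth already explains everything: group adds no variance
    assert rep.r2_full - rep.r2_depth == pytest.approx(0.0, abs=1e-9)
    assert rep.group_slopes["B"] == pytest.approx(-10.0)


def test_regression_matches_normal_equations_oracle():
    rng = np.random.default_rng(11)
    depth = rng.uniform(2, 15, 12)
    group = np.asarray(["B"] * 6 + ["R"] * 6)
    y = 50 - 3 * depth + np.where(group == "R", 12, 0) + rng.normal(0, 2, 12)
    df = pd.DataFrame({"median_depth": depth, "group": group, "n_absent": y})
    rep = depth_absence_regression(df)

    # oracle: hand-built design matrices and F from residual sums of squares
    X1 = np.column_stack([np.ones(12), depth])
    X2 = np.column_stack([np.ones(12), depth, (group == "R").astype(float)])
    b1 = _normal_equations(X1, y)
    b2 = _normal_equations(X2, y)
    rss1 = ((y - X1 @ b1) ** 2).sum()
    rss2 = ((y - X2 @ b2) ** 2).sum()
    f_group = (rss1 - rss2) / 1 / (rss2 / (12 - 3))
    p_group = stats.f.sf(f_group, 1, 9)
    assert rep.f_group == pytest.approx(f_group, rel=1e-8)
    assert rep.p_group == pytest.approx(p_group, rel=1e-8)
    tss = ((y - y.mean()) ** 2).sum()
    assert rep.r2_full == pytest.approx(1 - rss2 / tss, rel=1e-10)
    # per-group slopes against the normal equations
    for g in ("B", "R"):
        m = group == g
        Xg = np.column_stack([np.ones(m.sum()), depth[m]])
        bg = _normal_equations(Xg, y[m])
        assert rep.group_slopes[g] == pytest.approx(bg[1], rel=1e-8)


# -------------------------------------------------------------- length bias

def test_length_bias_identical_distributions():
    lengths = np.tile([100, 200, 300, 400, 500], 4)
    genes = _genes(20, lengths=lengths)
    depths = np.full((20, 2), 3.0)
    depths[::2, 0] = 0.0      # PAV genes get every other length: same dist
    states = make_states(depths, genes=genes)
    rep = pav_length_bias(states)
    assert rep["p_value"] > 0.5


def test_length_bias_extreme_separation():
    lengths = np.concatenate([np.full(10, 100), np.full(10, 10_000)])
    genes = _genes(20, lengths=lengths)
    depths = np.full((20, 2), 3.0)
    depths[:10, 0] = 0.0      # all short genes are PAV
    states = make_states(depths, genes=genes)
    rep = pav_length_bias(states)
    assert rep["median_pav"] < rep["median_other"]
    assert rep["p_value"] < 1e-4


def test_length_bias_matches_exact_rank_sum():
    lengths = np.array([120, 300, 150, 800, 90, 2000, 50, 400])
    genes = _genes(8, lengths=lengths)
    depths = np.full((8, 2), 3.0)
    depths[[0, 2, 4], 0] = 0.0
    states = make_states(depths, genes=genes)
    rep = pav_length_bias(states)
    oracle = stats.mannwhitneyu(lengths[[0, 2, 4]],
                                lengths[[1, 3, 5, 6, 7]],
                                alternative="two-sided", method="asymptotic")
    assert rep["statistic"] == pytest.approx(oracle.statistic)
    assert rep["p_value"] == pytest.approx(oracle.pvalue)


def test_length_bias_one_class_empty():
    states = make_states(np.full((5, 2), 3.0))
    rep = pav_length_bias(states)
    assert np.isnan(rep["p_value"])


# ------------------------------------------------------------------ pav pca

def test_pav_pca_identical_samples():
    rng = np.random.default_rng(12)
    depths = rng.gamma(2.0, 2.0, (30, 4)) + 0.5
    depths[rng.random(30) < 0.3, :2] = 0.0     # samples 0,1 identical absences
    states = make_states(depths)
    scores, _ = pav_pca(states, n_components=2)
    np.testing.assert_allclose(scores[0], scores[1], atol=1e-8)


def test_pav_pca_separates_planted_groups():
    rng = np.random.default_rng(13)
    depths = rng.gamma(3.0, 2.0, (80, 12)) + 1.0
    depths[:25, 6:] = 0.0
    states = make_states(depths)
    scores, _ = pav_pca(states, n_components=2)
    pc1 = scores[:, 0]
    assert abs(pc1[:6].mean() - pc1[6:].mean()) > 3 * max(pc1[:6].std(),
                                                          pc1[6:].std())


def test_pav_pca_matches_dense_oracle():
    rng = np.random.default_rng(14)
    depths = rng.gamma(2.0, 2.0, (40, 7)) + 0.2
    depths[rng.random((40, 7)) < 0.25] = 0.0
    states = make_states(depths)
    scores, eigvals = pav_pca(states, n_components=7)
    ind = (states.states == ABSENT).astype(float)
    z = (ind - ind.mean(axis=1, keepdims=True))
    z = z[(z ** 2).sum(axis=1) > 0].T
    w = np.linalg.eigvalsh(z @ z.T / (z.shape[0] - 1))[::-1]
    np.testing.assert_allclose(eigvals, w[:7], atol=1e-10)
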