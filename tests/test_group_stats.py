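import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from coastmix import (bivariate_normality, baboon_offset_report,
                      correlate_and_regress, holm_adjust, knnr_test,
                      kruskal_wallis, pairwise_wilcoxon, summarize_groups,
                      wilcoxon_rank_sum)
from coastmix.group_stats import RegressionResult, _knn_indices, knnr_statistic


# --- KNNr ------------------------------------------------------------------

def test_knnr_separated_groups_maximal_statistic():
    pts = np.array([[0.0, i] for i in range(5)] + [[100.0, i] for i in range(5)])
    labels = np.array(["a"] * 5 + ["b"] * 5)
    res = knnr_test(pts, labels, k=1, n_perm=999, seed=1)
    assert res.statistic == 10  # every nearest neighbour shares its label
    # brute-force enumeration over all C(10,5) label assignments: only the two
    # cluster-aligned assignments reach the maximal statistic
    nn = _knn_indices(pts, 1)
    hits = total = 0
    for idx in itertools.combinations(range(10), 5):
        lab = np.array(["b"] * 10)
        lab[list(idx)] = "a"
        total += 1
        hits += knnr_statistic(lab, nn) >= 10
    p_exact = hits / total
    assert hits == 2 and p_exact <= 0.01
    assert res.p_value == pytest.approx(p_exact, abs=0.015)


def test_knnr_matches_full_enumeration_on_small_instance(rng):
    pts = rng.normal(size=(6, 2))
    labels = np.array(["a", "a", "a", "b", "b", "b"])
    nn = _knn_indices(pts, 1)
    observed = knnr_statistic(labels, nn)
    # exact permutation distribution over all 6! orderings
    count = sum(knnr_statistic(labels[list(perm)], nn) >= observed
                for perm in itertools.permutations(range(6)))
    p_exact = count / 720
    res = knnr_test(pts, labels, k=1, n_perm=4999, seed=3)
    assert res.p_value == pytest.approx(p_exact, abs=0.03)


def test_knnr_statistic_invariant_to_point_reordering(rng):
    pts = rng.normal(size=(12, 2))
    labels = np.array(["a"] * 6 + ["b"] * 6)
    res = knnr_test(pts, labels, k=2, n_perm=99, seed=0)
    perm = rng.permutation(12)
    res2 = knnr_test(pts[perm], labels[perm], k=2, n_perm=99, seed=0)
    assert res.statistic == res2.statistic


def test_knnr_preconditions(rng):
    pts = rng.normal(size=(6, 2))
    with pytest.raises(ValueError):
        knnr_test(pts, ["a"] * 6, seed=0)  # single group
    with pytest.raises(ValueError):
        knnr_test(pts, ["a", "a", "a", "b", "b", "b"], k=5, seed=0)
    with pytest.raises(ValueError):
        knnr_test(pts, ["a", "a", "a", "b", "b", "b"], k=1, seed=None)


# --- rank tests ------------------------------------------------------------

def test_wilcoxon_brute_force_pair_counts():
    # W = number of (x_i, y_j) pairs with x_i > y_j
    assert wilcoxon_rank_sum([1, 2], [3, 4]).statistic == 0
    assert wilcoxon_rank_sum([3, 4], [1, 2]).statistic == 4


def test_wilcoxon_identical_multisets_symmetric():
    res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.p_value == pytest.approx(1.0, abs=0.05)


@given(st.lists(st.integers(0, 50), min_size=2, max_size=10, unique=True),
       st.lists(st.integers(51, 120), min_size=2, max_size=10, unique=True))
@settings(derandomize=True, max_examples=40)
def test_wilcoxon_w_complement(x, y):
    wxy = wilcoxon_rank_sum(x, y).statistic
    wyx = wilcoxon_rank_sum(y, x).statistic
    assert wxy + wyx == len(x) * len(y)


def test_kruskal_hand_rank_oracle():
    # 6 tie-free values, rank sums 3/7/11 -> H = 12/42 * (89.5) - 21
    res = kruskal_wallis([1, 2], [3, 4], [5, 6])
    assert res.statistic == pytest.approx(12 / 42 * (9 / 2 + 49 / 2 + 121 / 2) - 21)
    assert res.df == 2


def test_kruskal_identical_groups_zero():
    res = kruskal_wallis([1.0, 2.0], [1.0, 2.0])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_kruskal_two_groups_agrees_with_wilcoxon_on_tie_free_data(rng):
    x, y = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
    kw = kruskal_wallis(x, y)
    w = wilcoxon_rank_sum(x, y)
    assert kw.p_value == pytest.approx(w.p_value, abs=0.02)


def test_holm_step_down_by_hand():
    adj = holm_adjust([0.01, 0.04, 0.03])
    assert adj == pytest.approx([0.03, 0.06, 0.06])
    assert holm_adjust([0.2]) == pytest.approx([0.2])
    assert holm_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
@settings(derandomize=True, max_examples=50)
def test_holm_never_smaller_and_monotone(p):
    adj = holm_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-15)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in sorted p


def test_pairwise_wilcoxon_tidy_frame(rng):
    groups = {g: rng.normal(i * 3, 1, 10) for i, g in enumerate("abc")}
    df = pairwise_wilcoxon(groups)
    assert len(df) == 3
    assert (df["p_holm"] >= df["p"] - 1e-15).all()


# --- bivariate normality ---------------------------------------------------

def test_mvw_rejects_bimodal_cloud(rng):
    cloud = np.vstack([rng.normal([-10, -10], 0.5, (200, 2)),
                       rng.normal([10, 10], 0.5, (200, 2))])
    res = bivariate_normality(cloud)
    assert res.p_value < 0.01


def test_mvw_accepts_gaussian_sample(rng):
    X = rng.multivariate_normal([0, 0], [[2, 1], [1, 2]], 200)
    res = bivariate_normality(X)
    assert 0.9 < res.statistic <= 1.0
    assert res.p_value > 0.01


def test_mvw_preconditions(rng):
    with pytest.raises(ValueError):
        bivariate_normality(rng.normal(size=(4, 2)))
    x = rng.normal(size=10)
    with pytest.raises(ValueError, match="singular"):
        bivariate_normality(np.column_stack([x, 2 * x]))


# --- regression ------------------------------------------------------------

def test_exact_line_recovered():
    x = np.arange(10.0)
    pts = np.column_stack([x, 2 * x + 1])
    res = correlate_and_regress(pts)
    assert res.pearson_r == pytest.approx(1.0)
    assert res.slope == pytest.approx(2.0)
    assert res.intercept == pytest.approx(1.0)


def test_regression_zero_variance_error():
    pts = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]])
    with pytest.raises(ValueError):
        correlate_and_regress(pts)


def test_null_slope_inside_confidence_interval(rng):
    x = rng.normal(size=50)
    y = rng.normal(size=50)  # independent of x
    res = correlate_and_regress(np.column_stack([x, y]))
    se = abs(res.slope) / max(np.sqrt(res.F), 1e-12)
    assert abs(res.slope) < 4 * se or abs(res.slope) < 0.5


def test_baboon_residuals_below_line():
    line = RegressionResult(pearson_r=1.0, r_p_value=0.0, F=np.inf, df=(1, 33),
                            slope=0.9, intercept=26.4)
    resid, lo, hi = baboon_offset_report([(-21.9, 5.4), (-20.0, 8.4)], line)
    # predicted at -21.9 is 6.69 -> residual 1.29; on-line point -> 0
    assert resid[0] == pytest.approx(1.29)
    assert resid[1] == pytest.approx(0.0, abs=1e-12)
    assert (lo, hi) == (pytest.approx(0.0, abs=1e-12), pytest.approx(1.29))


def test_summarize_groups_means_within_sample_range(design):
    from coastmix import generate_sources
    samples = generate_sources(design)
    for g, s in summarize_groups(samples).items():
        vals = [x.d13C for x in samples if x.group == g]
        assert min(vals) <= s.mean_d13C <= max(vals)
        assert s.sd_d13C >= 0 and s.n == design.n_sources_per_group
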