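"""Frequentist characterisation of food groups and consumers.

Covers group separation (K-nearest-neighbour randomization), pairwise and
omnibus rank tests (Wilcoxon rank-sum / Kruskal-Wallis with Holm correction),
bivariate normality (generalized Shapiro-Wilk), and the d15N-on-d13C
correlation/regression used to place consumers along the marine-terrestrial
continuum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .data_io import GROUPS, IsotopeSample


@dataclass
class GroupSummary:
    group: str
    n: int
    mean_d13C: float
    sd_d13C: float
    mean_d15N: float
    sd_d15N: float
    mean_pct_C: float
    mean_pct_N: float


@dataclass
class TestResult:
    statistic_name: str
    statistic: float
    p_value: float
    df: float | None = None
    p_adjusted: float | None = None
    n_per_group: tuple = ()


def summarize_groups(samples: list[IsotopeSample]) -> dict[str, GroupSummary]:
    """Per-group n, mean and SD of both deltas, and mean %C / %N.

    SDs use ddof=1 (sample SD). Missing concentration values are ignored in
    the concentration means (proxy substitution happens downstream).
    """
    out: dict[str, GroupSummary] = {}
    for g in GROUPS:
        members = [s for s in samples if s.group == g]
        if not members:
            continue
        d13 = np.array([s.d13C for s in members])
        d15 = np.array([s.d15N for s in members])
        cC = np.array([s.pct_C for s in members if s.pct_C is not None], dtype=float)
        cN = np.array([s.pct_N for s in members if s.pct_N is not None], dtype=float)
        out[g] = GroupSummary(
            group=g, n=len(members),
            mean_d13C=float(d13.mean()), sd_d13C=float(d13.std(ddof=1)) if len(d13) > 1 else 0.0,
            mean_d15N=float(d15.mean()), sd_d15N=float(d15.std(ddof=1)) if len(d15) > 1 else 0.0,
            mean_pct_C=float(cC.mean()) if len(cC) else float("nan"),
            mean_pct_N=float(cN.mean()) if len(cN) else float("nan"),
        )
    return out


# ---------------------------------------------------------------------------
# K-nearest-neighbour randomization test
# ---------------------------------------------------------------------------

def _knn_indices(points: np.ndarray, k: int) -> np.ndarray:
    """Indices of each point's k Euclidean nearest neighbours (self excluded).

    Distance ties are broken by point index order, so the statistic is
    deterministic even with duplicate coordinates.
    """
    n = len(points)
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    # stable argsort on distance gives index-order tie-breaking
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, :k]


def knnr_statistic(labels: np.ndarray, nn: np.ndarray) -> int:
    return int((labels[nn] == labels[:, None]).sum())


def knnr_test(points, labels, k: int = 1, n_perm: int = 9999,
              seed: int | None = None) -> TestResult:
    """K-nearest-neighbour randomization test of multivariate group separation.

    The statistic is the total, over all points, of same-label points among
    each point's k nearest neighbours (self excluded, Euclidean distance in
    raw permil units). Significance comes from permuting labels over fixed
    point positions: ``p = (1 + #{perm stat >= observed}) / (1 + n_perm)``.

    A mandatory seed keeps the permutation stream reproducible.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if points.ndim != 2:
        raise ValueError("points must be an (n, d) array")
    n = len(points)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 points")
    if k < 1 or k >= n - 1:
        raise ValueError(f"k must satisfy 1 <= k < n - 1 (got k={k}, n={n})")
    if seed is None:
        raise ValueError("seed is mandatory for the permutation stream")

    nn = _knn_indices(points, k)
    observed = knnr_statistic(labels, nn)
    rng = np.random.default_rng(seed)
    # vectorised permutation sweep: permute labels, reuse fixed neighbour lists
    count_ge = 0
    codes = np.searchsorted(uniq, labels)
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if int((perm[nn] == perm[:, None]).sum()) >= observed:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    return TestResult("KNNr_count", float(observed), p,
                      n_per_group=tuple(int(c) for c in counts))


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The statistic W is the Mann-Whitney U of x over y, i.e. the rank sum of x
    minus n_x(n_x+1)/2 — the convention under which W(x,y) + W(y,x) = n_x n_y.
    Exact p for small tie-free samples, normal approximation with continuity
    and tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult("W", float(res.statistic), float(res.pvalue),
                      n_per_group=(len(x), len(y)))


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; df = number of groups - 1."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult("chi2", 0.0, 1.0, df=len(groups) - 1,
                          n_per_group=tuple(len(a) for a in arrays))
    res = stats.kruskal(*arrays)
    return TestResult("chi2", float(res.statistic), float(res.pvalue),
                      df=len(groups) - 1, n_per_group=tuple(len(a) for a in arrays))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment; output order matches input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


def pairwise_wilcoxon(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise rank-sum tests with Holm-adjusted p-values (tidy frame)."""
    names = list(values_by_group)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = wilcoxon_rank_sum(values_by_group[names[i]], values_by_group[names[j]])
            rows.append({"group_a": names[i], "group_b": names[j],
                         "W": r.statistic, "p": r.p_value})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_holm"] = holm_adjust(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Bivariate normality (generalized Shapiro-Wilk)
# ---------------------------------------------------------------------------

def bivariate_normality(points) -> TestResult:
    """Generalized (multivariate) Shapiro-Wilk test.

    The sample is standardized by the empirical mean and an inverse Cholesky
    factor of the covariance; the univariate Shapiro-Wilk statistic is
    computed for each transformed coordinate, and MVW is their mean. Each
    coordinate's Shapiro-Wilk p is mapped to a standard-normal deviate; under
    multivariate normality the transformed coordinates are (approximately
    independent) normal samples, so the sum of squared deviates is referred
    to a chi-square with d degrees of freedom.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be an (n, d) array")
    n, d = X.shape
    if n < 5:
        raise ValueError("need at least 5 observations")
    S = np.cov(X, rowvar=False)
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance matrix") from exc
    Z = np.linalg.solve(L, (X - X.mean(axis=0)).T).T  # decorrelated coordinates
    ws, zs = [], []
    for j in range(d):
        w, p = stats.shapiro(Z[:, j])
        ws.append(w)
        # lower-tail p: small p (non-normal) -> large negative deviate
        zs.append(stats.norm.ppf(np.clip(p, 1e-300, 1 - 1e-16)))
    mvw = float(np.mean(ws))
    chi2 = float(np.sum(np.square(zs)))
    p_value = float(stats.chi2.sf(chi2, df=d))
    return TestResult("MVW", mvw, p_value, df=d)


# ---------------------------------------------------------------------------
# Correlation / regression along the marine-terrestrial continuum
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    pearson_r: float
    r_p_value: float
    F: float
    df: tuple[int, int]
    slope: float
    intercept: float
    ci95_lower: np.ndarray = field(repr=False, default=None)
    ci95_upper: np.ndarray = field(repr=False, default=None)
    x_sorted: np.ndarray = field(repr=False, default=None)

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def correlate_and_regress(points) -> RegressionResult:
    """Pearson correlation and OLS of d15N on d13C with a 95% confidence band."""
    X = np.asarray(points, dtype=float)
    if len(X) < 3:
        raise ValueError("need at least 3 points")
    x, y = X[:, 0], X[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("zero variance in d13C")
    r, r_p = stats.pearsonr(x, y)
    order = np.argsort(x)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    pred = model.get_prediction(sm.add_constant(x[order])).conf_int(alpha=0.05)
    return RegressionResult(
        pearson_r=float(r), r_p_value=float(r_p),
        F=float(model.fvalue), df=(1, int(model.df_resid)),
        slope=float(model.params[1]), intercept=float(model.params[0]),
        ci95_lower=pred[:, 0], ci95_upper=pred[:, 1], x_sorted=x[order],
    )


def baboon_offset_report(baboons, regression: RegressionResult):
    """Residual of each reference consumer *below* the fitted human line.

    Residual = predicted d15N at the animal's d13C minus observed d15N; a
    positive value means the animal sits below the line. Returns
    ``(per_animal_residuals, min, max)``.
    """
    B = np.asarray(baboons, dtype=float)
    resid = regression.predict(B[:, 0]) - B[:, 1]
    return resid, float(resid.min()), float(resid.max())
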