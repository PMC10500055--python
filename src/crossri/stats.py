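"""Statistical decision layer for the crossing-experiment pipeline.

Binary outcomes (copulation, occurrence of offspring) are compared with
Pearson's chi-squared test when every cell of the contingency table
exceeds five, and with Fisher's exact test otherwise; single
comparisons within a significant group test are Bonferroni-corrected.
Count outcomes are compared with familywise-adjusted all-pairs
contrasts (Tukey for well-behaved normal data, a generalised linear
model with overdispersion-robust variance on request, and a
distribution-free permutation engine as the reference route). Sperm
totals are compared with a Welch two-sample t-test when both groups
pass a normality check and a Wilcoxon rank-sum test with continuity
correction otherwise. All tests are two-sided with significance at
p < 0.05.

The r x c Fisher test enumerates the margin-constrained table space
exactly when it is small and falls back to a seeded Monte-Carlo
estimate otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from math import lgamma
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float | None
    p_value: float
    p_adjusted: float | None = None
    groups: tuple[str, ...] = ()
    alpha: float = 0.05
    estimate: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")
        if (self.p_adjusted is not None
                and not math.isnan(self.p_adjusted)
                and self.p_adjusted < self.p_value - 1e-12):
            raise ValueError("adjusted p below raw p")

    @property
    def significant(self) -> bool:
        p = self.p_adjusted if self.p_adjusted is not None else self.p_value
        return bool(p < self.alpha)


# ---------------------------------------------------------------------------
# binary outcomes

def _as_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("contingency table must be a non-empty 2-D array")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("contingency table must hold non-negative integers")
    if arr.sum() == 0:
        raise ValueError("all-zero contingency table")
    return arr.astype(np.int64)


def select_binary_test(table) -> str:
    """Choose the test for a contingency table of binary outcomes.

    ``"chi_squared"`` iff the frequency of every observation (cell)
    exceeds five, else ``"fisher_exact"``.
    """
    arr = _as_table(table)
    return "chi_squared" if np.all(arr > 5) else "fisher_exact"


def run_binary_comparison(table, alpha: float = 0.05,
                          seed: int = 0) -> TestResult:
    """Apply the selection rule and run the chosen test."""
    arr = _as_table(table)
    choice = select_binary_test(arr)
    if choice == "chi_squared":
        # Yates continuity correction on 2x2 only (scipy default)
        res = sps.chi2_contingency(arr)
        return TestResult("chi_squared", float(res.statistic),
                          float(res.pvalue), alpha=alpha,
                          extra={"dof": int(res.dof),
                                 "shape": arr.shape})
    fis = fisher_exact_rc(arr, seed=seed)
    return TestResult("fisher_exact", None, fis.p_value, alpha=alpha,
                      extra={"method": fis.method, "se": fis.se,
                             "shape": arr.shape})


@dataclass
class FisherResult:
    p_value: float
    method: str  # "hypergeometric", "enumeration" or "monte_carlo"
    se: float | None = None  # Monte-Carlo simulation standard error
    n_tables: int | None = None

    def __float__(self) -> float:
        return self.p_value


_REL_TOL = 1e-7  # table probabilities within this of the observed count as extreme


def fisher_exact_rc(table, max_tables: int = 200_000,
                    n_sim: int = 10_000, seed: int = 0) -> FisherResult:
    """Two-sided Fisher's exact test for an r x c contingency table.

    2x2 tables use the hypergeometric closed form. Larger tables are
    enumerated exactly while the margin-constrained table space holds at
    most ``max_tables`` tables; beyond that a seeded Monte-Carlo
    estimate of the exact p is returned together with its simulation
    standard error. The two-sided p sums the null probabilities of all
    tables no more probable than the observed one.
    """
    arr = _as_table(table)
    # all-zero margins carry no information
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        return FisherResult(1.0, "degenerate")
    if arr.shape == (2, 2):
        return FisherResult(_fisher_2x2(arr), "hypergeometric")
    n_tab = count_tables_with_margins(arr.sum(axis=1), arr.sum(axis=0))
    if n_tab <= max_tables:
        return FisherResult(_fisher_enumerate(arr), "enumeration",
                            n_tables=n_tab)
    p, se = _fisher_monte_carlo(arr, n_sim=n_sim, seed=seed)
    return FisherResult(p, "monte_carlo", se=se, n_tables=n_tab)


def _fisher_2x2(arr: np.ndarray) -> float:
    r1, r2 = arr.sum(axis=1)
    c1 = arr[:, 0].sum()
    n = arr.sum()
    rv = sps.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(arr[0, 0])
    p = float(pmf[pmf <= p_obs * (1 + _REL_TOL)].sum())
    return min(1.0, p)


def _log_table_prob_const(row_sums, col_sums) -> float:
    n = int(row_sums.sum())
    return (sum(lgamma(r + 1) for r in row_sums)
            + sum(lgamma(c + 1) for c in col_sums)
            - lgamma(n + 1))


def _log_prob(arr: np.ndarray, const: float) -> float:
    return const - sum(lgamma(v + 1) for v in arr.ravel())


def count_tables_with_margins(row_sums, col_sums) -> int:
    """Number of non-negative integer tables with the given margins.

    Dynamic programme over rows: states are the residual column sums.
    Used to decide between exact enumeration and Monte Carlo.
    """
    row_sums = [int(r) for r in row_sums]
    col_sums = tuple(int(c) for c in col_sums)
    states = {col_sums: 1}
    for r in row_sums[:-1]:
        nxt: dict[tuple, int] = {}
        for residual, ways in states.items():
            for row in _compositions(r, residual):
                new = tuple(c - x for c, x in zip(residual, row))
                nxt[new] = nxt.get(new, 0) + ways
        states = nxt
    # last row forced by residuals
    return sum(w for residual, w in states.items()
               if sum(residual) == row_sums[-1])


def _compositions(total: int, caps: Sequence[int]):
    """All ways to write ``total`` as capped non-negative parts."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    for x in range(min(total, caps[0]) + 1):
        for rest in _compositions(total - x, caps[1:]):
            yield (x,) + rest


def _fisher_enumerate(arr: np.ndarray) -> float:
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    const = _log_table_prob_const(row_sums, col_sums)
    logp_obs = _log_prob(arr, const)
    cutoff = logp_obs + math.log1p(_REL_TOL)
    total = 0.0

    def recurse(i: int, residual: tuple[int, ...], logfac: float):
        nonlocal total
        if i == len(row_sums) - 1:
            if sum(residual) != row_sums[-1]:
                return
            lp = const - logfac - sum(lgamma(v + 1) for v in residual)
            if lp <= cutoff:
                total += math.exp(lp)
            return
        for row in _compositions(int(row_sums[i]), residual):
            recurse(i + 1,
                    tuple(c - x for c, x in zip(residual, row)),
                    logfac + sum(lgamma(x + 1) for x in row))

    recurse(0, tuple(int(c) for c in col_sums), 0.0)
    return min(1.0, total)


def _fisher_monte_carlo(arr: np.ndarray, n_sim: int, seed: int
                        ) -> tuple[float, float]:
    """Estimate the exact p by sampling tables with the observed margins.

    Tables are drawn by shuffling the column labels of the underlying
    observation list against fixed row labels (equivalent to the
    multivariate hypergeometric null).
    """
    rng = np.random.default_rng(seed)
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    const = _log_table_prob_const(row_sums, col_sums)
    cutoff = _log_prob(arr, const) + math.log1p(_REL_TOL)
    row_labels = np.repeat(np.arange(len(row_sums)), row_sums)
    col_labels = np.repeat(np.arange(len(col_sums)), col_sums)
    hits = 0
    lg = np.vectorize(lambda v: lgamma(v + 1))
    for _ in range(n_sim):
        perm = rng.permutation(col_labels)
        tab = np.zeros_like(arr)
        np.add.at(tab, (row_labels, perm), 1)
        if const - lg(tab).sum() <= cutoff:
            hits += 1
    p = (hits + 1) / (n_sim + 1)
    se = math.sqrt(p * (1 - p) / (n_sim + 1))
    return p, se


def bonferroni(p_values: Sequence[float], family_size: int | None = None
               ) -> list[float]:
    """Bonferroni adjustment: ``min(1, p * k)``.

    ``family_size`` defaults to the number of comparisons passed in
    (the single comparisons performed within one group test).
    """
    ps = [float(p) for p in p_values]
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value out of [0,1]: {p}")
    k = family_size if family_size is not None else len(ps)
    return [min(1.0, p * k) for p in ps]


# ---------------------------------------------------------------------------
# count outcomes

def permutation_two_group(x, y, n_perm: int = 10_000, seed: int = 0,
                          alpha: float = 0.05) -> TestResult:
    """Two-sided permutation test on the difference of group means."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = abs(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:  # identical values: no evidence either way
        return TestResult("permutation_mean_diff", 0.0, 1.0,
                          alpha=alpha, estimate=0.0)
    rng = np.random.default_rng(seed)
    n_x, n_tot = len(x), len(pooled)
    # vectorised label shuffling: argsort of random keys
    keys = rng.random((n_perm, n_tot))
    order = np.argsort(keys, axis=1)
    perm = pooled[order]
    diffs = np.abs(perm[:, :n_x].mean(axis=1) - perm[:, n_x:].mean(axis=1))
    p = (1 + int((diffs >= obs - 1e-12).sum())) / (n_perm + 1)
    return TestResult("permutation_mean_diff", float(obs), float(p),
                      alpha=alpha, estimate=float(x.mean() - y.mean()))


def compare_counts(groups: dict[str, Sequence[float]],
                   family: str = "auto", engine: str = "auto",
                   n_perm: int = 10_000, seed: int = 0,
                   alpha: float = 0.05) -> list[TestResult]:
    """All-pairs contrasts between labelled count groups.

    ``engine="permutation"`` (the reference route) shuffles pooled
    labels and adjusts familywise with the max-T statistic over all
    pairs. ``engine="tukey"`` uses the studentised-range test on a
    normal linear model; ``engine="glm"`` fits a Poisson generalised
    linear model with overdispersion-robust (quasi-Poisson) or
    negative-binomial variance and Bonferroni-adjusts pairwise Wald
    contrasts. ``engine="auto"`` picks Tukey when residual diagnostics
    (Shapiro-Wilk and Levene at 0.05) pass and ``family`` does not force
    a count family, else the permutation route.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in data.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs >=2 observations")
    if engine == "auto":
        if family in ("poisson", "quasipoisson", "negative_binomial"):
            engine = "glm"
        elif _normal_diagnostics_pass(data):
            engine = "tukey"
        else:
            engine = "permutation"
    if engine == "permutation":
        return _pairs_permutation(data, n_perm=n_perm, seed=seed, alpha=alpha)
    if engine == "tukey":
        return _pairs_tukey(data, alpha=alpha)
    if engine == "glm":
        return _pairs_glm(data, family=family, alpha=alpha)
    raise ValueError(f"unknown engine {engine!r}")


def _normal_diagnostics_pass(data: dict[str, np.ndarray],
                             alpha: float = 0.05) -> bool:
    vals = list(data.values())
    if any(np.ptp(v) == 0 for v in vals):
        return False
    if any(len(v) < 3 for v in vals):
        return False
    sw = [sps.shapiro(v).pvalue for v in vals]
    lev = sps.levene(*vals).pvalue
    return all(p > alpha for p in sw) and lev > alpha


def _pair_iter(names):
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            yield a, b


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    denom = math.sqrt(vx / len(x) + vy / len(y))
    if denom == 0:
        return 0.0
    return (x.mean() - y.mean()) / denom


def _pairs_permutation(data, n_perm, seed, alpha) -> list[TestResult]:
    names = list(data)
    pooled = np.concatenate([data[k] for k in names])
    sizes = [len(data[k]) for k in names]
    starts = np.cumsum([0] + sizes)
    obs_t = {pair: _welch_t(data[pair[0]], data[pair[1]])
             for pair in _pair_iter(names)}
    degenerate = np.ptp(pooled) == 0
    rng = np.random.default_rng(seed)
    max_null = np.zeros(n_perm)
    null_t = {pair: np.zeros(n_perm) for pair in obs_t}
    if not degenerate:
        for r in range(n_perm):
            perm = rng.permutation(pooled)
            parts = {k: perm[starts[i]:starts[i + 1]]
                     for i, k in enumerate(names)}
            ts = {pair: abs(_welch_t(parts[pair[0]], parts[pair[1]]))
                  for pair in obs_t}
            for pair, t in ts.items():
                null_t[pair][r] = t
            max_null[r] = max(ts.values())
    results = []
    for pair, t in obs_t.items():
        x, y = data[pair[0]], data[pair[1]]
        if np.ptp(np.concatenate([x, y])) == 0 and x.mean() == 0:
            results.append(TestResult(
                "permutation_maxT", math.nan, math.nan, math.nan,
                groups=pair, alpha=alpha,
                extra={"undefined": "zero-variance zero-mean contrast"}))
            continue
        if degenerate:
            results.append(TestResult("permutation_maxT", 0.0, 1.0, 1.0,
                                      groups=pair, alpha=alpha, estimate=0.0))
            continue
        p_raw = (1 + int((null_t[pair] >= abs(t) - 1e-12).sum())) / (n_perm + 1)
        p_adj = (1 + int((max_null >= abs(t) - 1e-12).sum())) / (n_perm + 1)
        results.append(TestResult(
            "permutation_maxT", float(t), float(p_raw),
            float(max(p_adj, p_raw)), groups=pair, alpha=alpha,
            estimate=float(x.mean() - y.mean())))
    return results


def _pairs_tukey(data, alpha) -> list[TestResult]:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    names = list(data)
    values = np.concatenate([data[k] for k in names])
    labels = np.concatenate([[k] * len(data[k]) for k in names])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    from itertools import combinations
    pairs = list(combinations([str(g) for g in res.groupsunique], 2))
    results = []
    for (a, b), p, diff in zip(pairs, res.pvalues, res.meandiffs):
        results.append(TestResult(
            "tukey_hsd", float(diff), float(p), float(p),
            groups=(a, b), alpha=alpha, estimate=float(diff)))
    return results


def _pairs_glm(data, family, alpha) -> list[TestResult]:
    import statsmodels.api as sm
    names = list(data)
    y = np.concatenate([data[k] for k in names])
    X = np.zeros((len(y), len(names)))
    pos = 0
    for i, k in enumerate(names):
        X[pos:pos + len(data[k]), i] = 1.0
        pos += len(data[k])
    if family == "negative_binomial":
        mu = y.mean()
        var = y.var(ddof=1)
        a = max((var - mu) / mu ** 2, 1e-6)  # moment estimate of alpha
        fam = sm.families.NegativeBinomial(alpha=a)
        scale = None
    else:  # poisson / quasipoisson-style variance
        fam = sm.families.Poisson()
        scale = "X2" if family in ("auto", "quasipoisson") else None
    model = sm.GLM(y, X, family=fam)
    fit = model.fit(scale=scale) if scale else model.fit()
    cov = fit.cov_params()
    raw, pairs, stats_ = [], [], []
    for i, j in ((names.index(a), names.index(b))
                 for a, b in _pair_iter(names)):
        diff = fit.params[i] - fit.params[j]
        se = math.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j])
        z = diff / se if se > 0 else 0.0
        raw.append(2 * sps.norm.sf(abs(z)))
        pairs.append((names[i], names[j]))
        stats_.append(z)
    adj = bonferroni(raw)
    return [TestResult("glm_wald", float(z), float(p), float(pa),
                       groups=pair, alpha=alpha)
            for z, p, pa, pair in zip(stats_, raw, adj, pairs)]


# ---------------------------------------------------------------------------
# sperm counts

def compare_sperm(group_a, group_b, alpha: float = 0.05,
                  normality_alpha: float = 0.05) -> TestResult:
    """Compare two samples of estimated sperm totals.

    Shapiro-Wilk normality per group at ``normality_alpha``; both normal
    -> Welch two-sample t-test, otherwise Wilcoxon rank-sum with
    continuity correction. Medians and quartiles are reported alongside.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least three values per group")
    summaries = {
        "median": (float(np.median(a)), float(np.median(b))),
        "q1": (float(np.percentile(a, 25)), float(np.percentile(b, 25))),
        "q3": (float(np.percentile(a, 75)), float(np.percentile(b, 75))),
        "n": (len(a), len(b)),
    }
    degenerate = np.ptp(a) == 0 or np.ptp(b) == 0
    normal = False
    if not degenerate:
        normal = (sps.shapiro(a).pvalue > normality_alpha
                  and sps.shapiro(b).pvalue > normality_alpha)
    if normal:
        res = sps.ttest_ind(a, b, equal_var=False)
        return TestResult("welch_t", float(res.statistic), float(res.pvalue),
                          alpha=alpha, extra=summaries)
    if np.ptp(np.concatenate([a, b])) == 0:
        return TestResult("wilcoxon_rank_sum", 0.0, 1.0, alpha=alpha,
                          extra=summaries | {"warning": "all values tied"})
    res = sps.mannwhitneyu(a, b, use_continuity=True,
                           alternative="two-sided", method="asymptotic")
    return TestResult("wilcoxon_rank_sum", float(res.statistic),
                      float(res.pvalue), alpha=alpha, extra=summaries)
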