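"""Two-sample hypothesis tests shared by the soccer and Stroop analyses.

The workhorse is the Mann-Whitney-Wilcoxon rank test, used throughout to
ask whether two samples stem from the same distribution.  For small
samples the two-sided p-value is computed *exactly* by enumerating the
permutation distribution of the rank sum over all C(n_x + n_y, n_x)
assignments of the pooled (mid)ranks to the first sample; the
enumeration is carried out with an integer dynamic program over doubled
midranks, which is exact also in the presence of ties.  Above the
enumeration limit a normal approximation with tie-corrected variance and
continuity correction is used; a seeded Monte-Carlo permutation method
is available in between.

The parametric counterparts (pooled two-sample t, paired t) delegate to
scipy and exist to corroborate the distribution-free results.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, sqrt

import numpy as np
from scipy import stats

from .errors import DegenerateVarianceError, InsufficientDataError

#: Enumerate the exact permutation distribution as long as the number of
#: assignments C(n_x + n_y, n_x) does not exceed this bound.
MAX_EXACT_COMBINATIONS = 1_000_000


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample test.

    ``method`` records how the p-value was obtained: ``rank_exact``
    (complete enumeration), ``rank_normal`` (tie-corrected normal
    approximation), ``rank_montecarlo`` (seeded permutation sampling),
    ``t_two_sample`` or ``t_paired``.
    """

    statistic: float
    p_value: float
    method: str
    n_x: int
    n_y: int


def _as_sample(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise InsufficientDataError(f"sample {name!r} is empty")
    if np.isnan(arr).any():
        raise ValueError(f"sample {name!r} contains NaN")
    return arr


def _rank_sum_distribution(doubled_ranks: np.ndarray, n_x: int) -> np.ndarray:
    """Count, for every possible doubled rank sum ``s``, the subsets of
    size ``n_x`` of the pooled doubled midranks summing to ``s``.

    Classic subset-sum dynamic program; ``counts[k, s]`` is the number of
    k-subsets with sum s.  Total over the returned row equals
    C(N, n_x), i.e. the row *is* the complete enumeration of rank-sum
    assignments.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros((n_x + 1, total + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        kmax = n_x
        # iterate k downward so each rank is used at most once
        for k in range(kmax, 0, -1):
            counts[k, r:] += counts[k - 1, : total + 1 - r]
    return counts[n_x]


def _exact_two_sided_p(doubled_ranks: np.ndarray, n_x: int, observed_sum2: int) -> float:
    dist = _rank_sum_distribution(doubled_ranks, n_x)
    n = doubled_ranks.size
    # mean doubled rank sum of the first sample: n_x * (N + 1) in doubled
    # units, since doubled midranks sum to N(N+1)
    mean2 = n_x * (n + 1)
    sums = np.arange(dist.size)
    extreme = np.abs(2 * sums - 2 * mean2) >= abs(2 * observed_sum2 - 2 * mean2)
    return float(dist[extreme].sum() / dist.sum())


def mann_whitney(
    x,
    y,
    *,
    method: str = "auto",
    max_exact_combinations: int = MAX_EXACT_COMBINATIONS,
    n_resamples: int = 20_000,
    random_state=None,
) -> TestResult:
    """Two-sided Mann-Whitney-Wilcoxon rank test.

    Parameters
    ----------
    x, y
        The two samples (1-d, nonempty).
    method
        ``"auto"`` enumerates the exact permutation distribution when
        C(n_x + n_y, n_x) <= ``max_exact_combinations`` and otherwise
        falls back to the tie-corrected normal approximation with
        continuity correction.  ``"exact"``, ``"normal"`` and
        ``"montecarlo"`` force the respective computation.
    n_resamples, random_state
        Only used by the Monte-Carlo method.

    Returns
    -------
    TestResult
        ``statistic`` is the U statistic of the first sample (midranks
        for ties); ``p_value`` lies in (0, 1].

    Notes
    -----
    The exact two-sided p-value is the proportion of rank assignments
    whose U deviates from its null mean n_x n_y / 2 by at least the
    observed deviation.  It is invariant under strictly monotone
    transformations of the pooled data and under swapping the samples.
    """
    xa = _as_sample(x, "x")
    ya = _as_sample(y, "y")
    n_x, n_y = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    ranks = stats.rankdata(pooled)  # midranks
    rank_sum_x = float(ranks[:n_x].sum())
    u_stat = rank_sum_x - n_x * (n_x + 1) / 2.0

    if method == "auto":
        method = (
            "exact"
            if comb(n_x + n_y, n_x) <= max_exact_combinations
            else "normal"
        )

    if method == "exact":
        doubled = np.rint(2.0 * ranks).astype(np.int64)
        p = _exact_two_sided_p(doubled, n_x, int(round(2.0 * rank_sum_x)))
        return TestResult(u_stat, max(p, np.finfo(float).tiny), "rank_exact", n_x, n_y)

    if method == "montecarlo":
        rng = np.random.default_rng(random_state)
        mean_u = n_x * n_y / 2.0
        obs_dev = abs(u_stat - mean_u)
        count = 0
        for _ in range(n_resamples):
            perm = rng.permutation(ranks)
            u = perm[:n_x].sum() - n_x * (n_x + 1) / 2.0
            count += abs(u - mean_u) >= obs_dev - 1e-9
        # add-one (permutation-test convention) keeps p in (0, 1]
        p = (count + 1) / (n_resamples + 1)
        return TestResult(u_stat, float(p), "rank_montecarlo", n_x, n_y)

    if method == "normal":
        n = n_x + n_y
        mean_u = n_x * n_y / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum())
        var_u = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var_u <= 0:  # all observations tied
            return TestResult(u_stat, 1.0, "rank_normal", n_x, n_y)
        z = (abs(u_stat - mean_u) - 0.5) / sqrt(var_u)
        p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
        return TestResult(u_stat, max(p, np.finfo(float).tiny), "rank_normal", n_x, n_y)

    raise ValueError(f"unknown method {method!r}")


def two_sample_t(x, y, *, equal_var: bool = True) -> TestResult:
    """Two-sided two-sample Student t-test (pooled variance by default)."""
    xa = _as_sample(x, "x")
    ya = _as_sample(y, "y")
    if xa.size < 2 or ya.size < 2:
        raise InsufficientDataError("two_sample_t needs at least 2 values per sample")
    if np.var(xa, ddof=1) == 0.0 and np.var(ya, ddof=1) == 0.0:
        raise DegenerateVarianceError("pooled variance is zero")
    res = stats.ttest_ind(xa, ya, equal_var=equal_var)
    return TestResult(
        float(res.statistic), float(res.pvalue), "t_two_sample", xa.size, ya.size
    )


def paired_t(x, y) -> TestResult:
    """Two-sided paired t-test on matched samples."""
    xa = _as_sample(x, "x")
    ya = _as_sample(y, "y")
    if xa.size != ya.size:
        raise ValueError("paired samples must have equal length")
    if xa.size < 2:
        raise InsufficientDataError("paired_t needs at least 2 pairs")
    diffs = xa - ya
    if np.var(diffs, ddof=1) == 0.0:
        raise DegenerateVarianceError(
            "all paired differences are equal; t statistic undefined"
        )
    res = stats.ttest_rel(xa, ya)
    return TestResult(
        float(res.statistic), float(res.pvalue), "t_paired", xa.size, ya.size
    )


def p_value_panel(results, labels=None, alphas=(0.05, 0.01), ax=None):
    """Tabulate (and optionally plot) p-values against reference levels.

    Returns a DataFrame with one row per result and boolean columns
    flagging significance at each reference level (5% and 1% by
    default, the levels marked in the figures this mirrors).  If ``ax``
    is given, the p-values are drawn on a logarithmic axis with
    horizontal reference lines.
    """
    import pandas as pd

    results = list(results)
    if not results:
        raise InsufficientDataError("no test results to tabulate")
    if labels is None:
        labels = [str(i) for i in range(len(results))]
    frame = pd.DataFrame(
        {
            "label": list(labels),
            "p_value": [r.p_value for r in results],
            "method": [r.method for r in results],
        }
    )
    for a in alphas:
        frame[f"significant_{a:g}"] = frame["p_value"] <= a
    if ax is not None:
        ax.plot(range(len(frame)), frame["p_value"], "o-")
        ax.set_yscale("log")
        for a in alphas:
            ax.axhline(a, color="black", lw=0.8)
        ax.set_xticks(range(len(frame)))
        ax.set_xticklabels(frame["label"], rotation=45, ha="right")
        ax.set_ylabel("p value")
    return frame
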