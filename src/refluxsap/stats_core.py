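"""Exact and rank-based hypothesis tests used throughout the pipeline.

All tests are implemented here directly (not delegated wholesale to a stats
library) so that each can be verified against a brute-force oracle in the
test suite.  Conventions:

* Fisher's exact two-sided p uses the point-probability rule: sum of the
  probabilities of all margin-fixed tables whose point probability is at
  most the observed one (relative tie tolerance 1e-7).
* Rank tests use average ranks for ties, no continuity correction, and an
  exact enumeration path when the combined sample size is <= 10.
* alpha = 0.05 throughout; a Holm step-down adjuster is provided for callers
  that opt into multiplicity adjustment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2, norm, rankdata
from scipy.stats import random_table as _random_table

__all__ = [
    "TestResult",
    "fisher_exact_2x2",
    "exact_rxc_test",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "holm_adjust",
]

ALPHA = 0.05
_TIE_RTOL = 1e-7

EXACT_N_MAX = 10  # combined-n threshold for exact rank-test enumeration


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    mc_se: float | None = None  # Monte Carlo standard error, when applicable

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _as_counts_2x2(table) -> tuple[int, int, int, int]:
    if hasattr(table, "as_array"):
        arr = np.asarray(table.as_array())
    else:
        arr = np.asarray(table)
    a, b, c, d = (int(x) for x in arr.reshape(-1))
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    return a, b, c, d


def fisher_exact_2x2(table, alternative: str = "two_sided") -> TestResult:
    """Fisher's exact test for a 2x2 table ``[[a, b], [c, d]]``.

    The support is every table with the observed margins; point probabilities
    are hypergeometric.  ``two_sided`` sums tables as extreme or less probable
    than the observed one; ``greater``/``less`` are one-sided in the ``a``
    cell.  A table with a zero row or column margin has p = 1.
    """
    a, b, c, d = _as_counts_2x2(table)
    N = a + b + c + d
    K = a + b          # first-row margin
    n1 = a + c         # first-column margin
    if N == 0 or K in (0, N) or n1 in (0, N):
        return TestResult(float(a), 1.0, "fisher_exact", (N,))

    lo = max(0, K + n1 - N)
    hi = min(K, n1)
    support = np.arange(lo, hi + 1)
    # hypergeometric log-pmf over the full support, computed in one pass
    logpmf = (
        gammaln(K + 1) - gammaln(support + 1) - gammaln(K - support + 1)
        + gammaln(N - K + 1) - gammaln(n1 - support + 1)
        - gammaln(N - K - n1 + support + 1)
        - (gammaln(N + 1) - gammaln(n1 + 1) - gammaln(N - n1 + 1))
    )
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()  # guard against accumulated rounding
    obs = a - lo
    if alternative == "two_sided":
        p = float(pmf[pmf <= pmf[obs] * (1.0 + _TIE_RTOL)].sum())
    elif alternative == "greater":
        p = float(pmf[obs:].sum())
    elif alternative == "less":
        p = float(pmf[: obs + 1].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(float(a), min(p, 1.0), "fisher_exact", (N,))


def _log_point_prob(tables: np.ndarray, row: np.ndarray, col: np.ndarray) -> np.ndarray:
    """Log point probability of r x c tables under fixed margins."""
    N = int(row.sum())
    const = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(N + 1)
    return const - gammaln(tables + 1).sum(axis=(-2, -1))


def exact_rxc_test(table, n_resamples: int = 10000, seed=None) -> TestResult:
    """Monte Carlo exact test of independence for an r x c table.

    Freeman-Halton style: the p-value is the proportion of margin-preserving
    tables (sampled by Patefield's algorithm) whose point probability is at
    most the observed table's, with a +1/(n+1) correction for validity.
    Degenerate margins give p = 1.  Reproducible given ``seed``.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    N = int(obs.sum())
    if np.count_nonzero(row) <= 1 or np.count_nonzero(col) <= 1 or N == 0:
        return TestResult(0.0, 1.0, "exact_rxc_mc", (N,), mc_se=0.0)

    rng = np.random.default_rng(seed)
    log_obs = float(_log_point_prob(obs[None, :, :], row, col)[0])
    samples = _random_table(row, col).rvs(n_resamples, random_state=rng)
    samples = np.asarray(samples).reshape(n_resamples, *obs.shape)
    log_p = _log_point_prob(samples, row, col)
    tol = _TIE_RTOL * abs(log_obs) + 1e-12
    hits = int(np.count_nonzero(log_p <= log_obs + tol))
    p = (hits + 1) / (n_resamples + 1)
    mc_se = float(np.sqrt(p * (1 - p) / n_resamples))
    return TestResult(-log_obs, min(p, 1.0), "exact_rxc_mc", (N,), mc_se=mc_se)


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def _two_sided_from_null(null: np.ndarray, observed: float) -> float:
    """Two-sided p: P(|T - E T| >= |observed - E T|) under the null sample."""
    mu = null.mean()
    dev = abs(observed - mu)
    return float(np.mean(np.abs(null - mu) >= dev - 1e-12))


def mann_whitney_u(x, y) -> TestResult:
    """Mann-Whitney U (rank-sum) test, two-sided.

    Exact enumeration over all splits when n_x + n_y <= 10; otherwise the
    tie-corrected normal approximation without continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 1 or ny < 1:
        raise ValueError("need at least one observation per group")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)

    if np.ptp(combined) == 0:
        warnings.warn("all observations tied; p = 1")
        return TestResult(u, 1.0, "mann_whitney_u", (nx, ny))

    n = nx + ny
    if n <= EXACT_N_MAX:
        null = []
        for idx in itertools.combinations(range(n), nx):
            sel = np.zeros(n, dtype=bool)
            sel[list(idx)] = True
            null.append(ranks[sel].sum() - nx * (nx + 1) / 2.0)
        p = _two_sided_from_null(np.array(null), u)
        return TestResult(u, p, "mann_whitney_u_exact", (nx, ny))

    mu = nx * ny / 2.0
    # tie correction
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (n * (n - 1)))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        warnings.warn("degenerate variance; p = 1")
        return TestResult(u, 1.0, "mann_whitney_u", (nx, ny))
    z = (u - mu) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return TestResult(u, p, "mann_whitney_u", (nx, ny))


def wilcoxon_signed_rank(pre, post) -> TestResult:
    """Wilcoxon signed-rank test on paired samples, two-sided.

    Zero differences are dropped; exact sign enumeration when the number of
    non-zero differences is <= 10.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired samples must have equal length")
    d = post - pre
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all differences zero; p = 1")
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank", (0,))
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_N_MAX:
        signs = np.array(list(itertools.product([0, 1], repeat=n)))
        null = signs @ ranks
        p = _two_sided_from_null(null, w_plus)
        return TestResult(w_plus, p, "wilcoxon_signed_rank_exact", (n,))

    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - ((counts ** 3 - counts).sum()) / 48.0
    if sigma2 <= 0:
        warnings.warn("degenerate variance; p = 1")
        return TestResult(w_plus, 1.0, "wilcoxon_signed_rank", (n,))
    z = (w_plus - mu) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return TestResult(w_plus, p, "wilcoxon_signed_rank", (n,))


def _kw_statistic(groups: list[np.ndarray]) -> float:
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        ni = len(g)
        ri = ranks[start:start + ni].sum()
        h += ri * ri / ni
        start += ni
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - ((counts ** 3 - counts).sum()) / (n ** 3 - n)
    if correction <= 0:
        return 0.0
    return h / correction


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis rank test across k >= 2 groups.

    Chi-squared approximation with tie correction; exact permutation
    enumeration when the pooled sample size is <= 10.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    sizes = tuple(len(g) for g in groups)
    pooled = np.concatenate(groups)
    n = len(pooled)
    if np.ptp(pooled) == 0:
        warnings.warn("all observations tied; p = 1")
        return TestResult(0.0, 1.0, "kruskal_wallis", sizes)
    h = _kw_statistic(groups)

    if n <= EXACT_N_MAX:
        null = []
        idx_all = range(n)
        # enumerate distinct assignments of pooled indices to groups
        def recurse(avail: tuple, gi: int, acc: list):
            if gi == len(sizes) - 1:
                groups_perm = acc + [pooled[list(avail)]]
                null.append(_kw_statistic(groups_perm))
                return
            for idx in itertools.combinations(avail, sizes[gi]):
                rest = tuple(i for i in avail if i not in set(idx))
                recurse(rest, gi + 1, acc + [pooled[list(idx)]])

        recurse(tuple(idx_all), 0, [])
        p = float(np.mean(np.array(null) >= h - 1e-12))
        return TestResult(h, p, "kruskal_wallis_exact", sizes)

    p = float(chi2.sf(h, df=len(groups) - 1))
    return TestResult(h, p, "kruskal_wallis", sizes)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adjusted[i] = min(1.0, running)
    return adjusted
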