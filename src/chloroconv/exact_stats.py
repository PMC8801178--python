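"""Exact 2x2 and rank statistics implemented from first principles.

Three tests drive the convergence analysis:

* Fisher's exact test — hypergeometric enumeration conditional on both
  margins; the two-sided p-value sums the probabilities of all tables
  no more probable than the observed one.
* Boschloo's exact unconditional test — the Fisher p-value is the
  ordering statistic; the p-value is the supremum over the nuisance
  success probability pi of the total binomial probability of all
  outcome tables at least as extreme as the observed one.  Boschloo's
  test is uniformly at least as powerful as Fisher's (p_Boschloo <=
  p_Fisher), which is asserted on every call.
* Exact Mann-Whitney U — the permutation distribution of the rank sum,
  with midrank tie handling, computed by a shift-algorithm dynamic
  program (exact for any sample sizes; ties condition on the observed
  tie pattern).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

ALTERNATIVES = ("two_sided", "less", "greater")

_TIE_TOL = 1e-12  # relative tolerance when comparing table probabilities


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows are groups, columns outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be nonnegative integers")

    @classmethod
    def from_rows(cls, rows) -> "ContingencyTable2x2":
        (a, b), (c, d) = rows
        return cls(int(a), int(b), int(c), int(d))

    @property
    def n1(self) -> int:
        return self.a + self.b

    @property
    def n2(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest collection target

    p_value: float
    statistic: float
    alternative: str
    method: str
    nuisance_grid_size: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _check_alternative(alternative: str) -> None:
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")


# ---------------------------------------------------------------------------
# Fisher's exact test


def _log_hypergeom_pmf(x: np.ndarray, total: int, successes: int, draws: int
                       ) -> np.ndarray:
    lg = math.lgamma

    def logc(n, k):
        return lg(n + 1) - lg(k + 1) - lg(n - k + 1)

    out = np.empty(len(x))
    for i, xi in enumerate(x):
        out[i] = logc(successes, xi) + logc(total - successes, draws - xi) - logc(total, draws)
    return out


def fisher_exact(table: ContingencyTable2x2, alternative: str = "two_sided"
                 ) -> TestResult:
    """Fisher's exact test on a 2x2 table.

    ``less``/``greater`` refer to the first row's success probability
    relative to the second row's.
    """
    _check_alternative(alternative)
    t = table
    if t.total == 0:
        return TestResult(1.0, math.nan, alternative, "fisher_exact")
    m = t.a + t.c  # first-column margin
    lo = max(0, m - t.n2)
    hi = min(m, t.n1)
    support = np.arange(lo, hi + 1)
    with np.errstate(over="ignore"):
        pmf = np.exp(_log_hypergeom_pmf(support, t.total, m, t.n1))
    pmf = pmf / pmf.sum()
    idx = t.a - lo
    p_obs = pmf[idx]
    if alternative == "less":
        p = float(pmf[: idx + 1].sum())
    elif alternative == "greater":
        p = float(pmf[idx:].sum())
    else:
        p = float(pmf[pmf <= p_obs * (1.0 + _TIE_TOL)].sum())
    return TestResult(min(p, 1.0), float(p_obs), alternative, "fisher_exact")


# ---------------------------------------------------------------------------
# Boschloo's exact unconditional test


def _fisher_p_grid(n1: int, n2: int, alternative: str) -> np.ndarray:
    """Fisher p-value for every outcome table (x1, x2), shape (n1+1, n2+1)."""
    grid = np.empty((n1 + 1, n2 + 1))
    for x1 in range(n1 + 1):
        for x2 in range(n2 + 1):
            grid[x1, x2] = fisher_exact(
                ContingencyTable2x2(x1, n1 - x1, x2, n2 - x2), alternative
            ).p_value
    return grid


def _log_binom_pmf(n: int, p: np.ndarray, x: np.ndarray) -> np.ndarray:
    """log Binom(x; n, p) for vector p (grid) x vector x -> (len(p), len(x))."""
    lg = math.lgamma
    logc = np.array([lg(n + 1) - lg(k + 1) - lg(n - k + 1) for k in x])
    logp = np.log(p)[:, None]
    log1mp = np.log1p(-p)[:, None]
    return logc[None, :] + x[None, :] * logp + (n - x)[None, :] * log1mp


def _rejection_mass(pi: np.ndarray, mask: np.ndarray, n1: int, n2: int
                    ) -> np.ndarray:
    """P_pi(outcome in rejection region) for each nuisance value pi."""
    x1 = np.arange(n1 + 1)
    x2 = np.arange(n2 + 1)
    pmf1 = np.exp(_log_binom_pmf(n1, pi, x1))  # (g, n1+1)
    pmf2 = np.exp(_log_binom_pmf(n2, pi, x2))  # (g, n2+1)
    # sum over masked tables: pmf1 @ mask @ pmf2, batched over the grid
    return np.einsum("gi,ij,gj->g", pmf1, mask.astype(float), pmf2)


def _golden_max(f, lo: float, hi: float, iters: int = 60) -> float:
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    f1, f2 = f(x1), f(x2)
    for _ in range(iters):
        if f1 < f2:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + invphi * (hi - lo)
            f2 = f(x2)
        else:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - invphi * (hi - lo)
            f1 = f(x1)
    return max(f1, f2)


def boschloo_test(table: ContingencyTable2x2, alternative: str = "two_sided",
                  grid_size: int = 1000) -> TestResult:
    """Boschloo's exact unconditional test with Fisher-p ordering statistic.

    The supremum over the nuisance parameter is taken on a uniform grid
    over (0, 1) and refined by golden-section search around every local
    maximum of the grid profile.  The interval endpoints contribute
    degenerate all-failure/all-success mass and can only matter when the
    observed Fisher p is 1, in which case the p-value is 1 anyway.
    """
    _check_alternative(alternative)
    if grid_size < 100:
        raise ValueError("grid_size must be at least 100")
    t = table
    if t.n1 == 0 or t.n2 == 0:
        raise ValueError("Boschloo's test requires both row totals positive")

    fisher = fisher_exact(t, alternative)
    fgrid = _fisher_p_grid(t.n1, t.n2, alternative)
    mask = fgrid <= fisher.p_value * (1.0 + _TIE_TOL)

    pi = np.linspace(0.0, 1.0, grid_size + 2)[1:-1]
    profile = _rejection_mass(pi, mask, t.n1, t.n2)

    best = float(profile.max())
    # refine every interior local maximum of the grid profile
    is_peak = np.r_[
        profile[0] >= profile[1],
        (profile[1:-1] >= profile[:-2]) & (profile[1:-1] >= profile[2:]),
        profile[-1] >= profile[-2],
    ]
    peak_idx = np.argsort(profile[is_peak])[::-1][:3]
    peaks = np.flatnonzero(is_peak)[peak_idx]

    def f(x: float) -> float:
        return float(_rejection_mass(np.array([x]), mask, t.n1, t.n2)[0])

    step = pi[1] - pi[0]
    for k in peaks:
        lo = max(pi[k] - step, 1e-12)
        hi = min(pi[k] + step, 1.0 - 1e-12)
        best = max(best, _golden_max(f, lo, hi))

    p = min(best, 1.0)
    assert p <= fisher.p_value * (1.0 + 1e-9), (
        "Boschloo p-value exceeded the Fisher p-value"
    )
    return TestResult(p, fisher.p_value, alternative, "boschloo", grid_size)


# ---------------------------------------------------------------------------
# Exact Mann-Whitney U


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _ranksum_distribution(double_ranks: np.ndarray, n: int) -> np.ndarray:
    """Counts of n-subsets of ``double_ranks`` by subset sum (shift algorithm).

    double_ranks are integers (twice the midranks).  Returns an array
    ``counts`` where counts[k, s] is the number of k-subsets with sum s.
    Floating point is adequate: counts stay far below 2**1023.
    """
    total = int(double_ranks.sum())
    counts = np.zeros((n + 1, total + 1))
    counts[0, 0] = 1.0
    for r in double_ranks:
        r = int(r)
        # iterate subset size downwards to avoid reuse
        for k in range(min(n, 1_000_000), 0, -1):
            counts[k, r:] += counts[k - 1, : total + 1 - r]
    return counts[n]


def category_contrast(summary, metric: str, cat_a: str, cat_b: str,
                      gene: str | None = None) -> ContingencyTable2x2:
    """Build the 2x2 table for a category-vs-category contrast.

    ``metric`` is ``con_vs_nc_sites``, ``con_vs_nc_events`` (optionally
    restricted to one gene), or one of the pair-level rows
    (``no_replacements``, ``no_con``, ``with_con``, ``with_nc``,
    ``con_gt_nc``, ``con_gt_1``), whose columns are (pairs satisfying
    the row condition, remaining pairs).
    """
    from .classify import PAIR_ROWS

    if gene is not None:
        summary = _gene_restricted(summary, gene)
    if metric == "con_vs_nc_sites":
        return ContingencyTable2x2(
            summary.n_con_sites(cat_a), summary.n_nc_sites(cat_a),
            summary.n_con_sites(cat_b), summary.n_nc_sites(cat_b),
        )
    if metric == "con_vs_nc_events":
        return ContingencyTable2x2(
            summary.n_con_events(cat_a), summary.n_nc_events(cat_a),
            summary.n_con_events(cat_b), summary.n_nc_events(cat_b),
        )
    if metric in PAIR_ROWS:
        ka = summary.pair_row_count(metric, cat_a)
        kb = summary.pair_row_count(metric, cat_b)
        return ContingencyTable2x2(
            ka, summary.n_pairs(cat_a) - ka,
            kb, summary.n_pairs(cat_b) - kb,
        )
    raise ValueError(f"unknown metric {metric!r}")


def _gene_restricted(summary, gene: str):
    from .classify import summarize
    from .reference_branches import BranchPair

    pair_objs = []
    seen = set()
    for p, cat in summary.pair_category.items():
        a, b = sorted(p)
        if p not in seen:
            seen.add(p)
            pair_objs.append(BranchPair(a, b, cat))
    events = [e for e in summary.events if e.gene_id == gene]
    return summarize(events, pair_objs)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (available behind a flag; raw p by default)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(list(p_values), method="fdr_bh")[1]


def mann_whitney_exact(x: Sequence[float], y: Sequence[float],
                       alternative: str = "two_sided") -> TestResult:
    """Exact Mann-Whitney U test via the permutation distribution.

    Midranks handle ties; the null distribution is conditional on the
    observed tie pattern.  Two-sided p = min(1, 2 * min(tail p)).
    """
    _check_alternative(alternative)
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    double = np.rint(2.0 * ranks).astype(int)
    r1 = int(np.rint(2.0 * ranks[:n].sum()))  # doubled rank sum of x

    dist = _ranksum_distribution(double, n)
    total = dist.sum()
    sums = np.arange(len(dist))
    p_less = float(dist[sums <= r1].sum() / total)
    p_greater = float(dist[sums >= r1].sum() / total)

    u = ranks[:n].sum() - n * (n + 1) / 2.0
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    return TestResult(p, float(u), alternative, "mann_whitney_exact")
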