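"""Small-sample statistical test battery for two-group comparisons.

Implements the tests used to compare a case group against a control group in
a two-modality microbiota survey: Pearson chi-square without continuity
correction, the two-tailed Fisher exact test (point-probability convention),
Barnard's unconditional exact test for very small samples, the pooled-variance
Student t-test (from raw vectors or printed summary statistics), an exact
Mann-Whitney test by permutation enumeration for small n, and the
normal-theory one-sample binomial proportion test.  No multiple-testing
correction is applied anywhere by design (exploratory comparisons); a
Benjamini-Hochberg helper is left to the caller.

Barnard's test treats the common success probability pi as a nuisance
parameter: with the pooled Wald two-proportion statistic

    T(x1, x2) = (p1 - p2) / sqrt(pp (1 - pp) (1/n1 + 1/n2)),  pp = (x1+x2)/(n1+n2)

the two-tailed p-value is  max over pi in (0, 1)  of
sum over all tables with |T| >= |T_obs| of Binom(x1; n1, pi) Binom(x2; n2, pi),
computed on a grid with local refinement.  Every table's "mirror"
(n1 - x1, n2 - x2) has exactly the same |T|, and such exact ties are kept in
the rejection region (a small relative tolerance guards the comparison
against floating-point noise).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Contingency2x2",
    "TestResult",
    "chi2_uncorrected",
    "fisher_exact_two_tailed",
    "barnard_exact_two_tailed",
    "pooled_t_two_tailed",
    "pooled_t_from_vectors",
    "mann_whitney_two_tailed",
    "one_sample_proportion_normal",
    "choose_two_proportion_test",
    "run_two_proportion_test",
]


class Contingency2x2(NamedTuple):
    """2x2 table with rows = groups (case, control), columns = (yes, no)."""

    a: int
    b: int
    c: int
    d: int

    @classmethod
    def from_proportions(cls, k1: int, n1: int, k2: int, n2: int) -> "Contingency2x2":
        """Build from per-group counts k/N (successes over totals)."""
        return cls(k1, n1 - k1, k2, n2 - k2)

    def swapped(self) -> "Contingency2x2":
        return Contingency2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    df: float | None = None
    exact: bool = False
    inputs: dict = field(default_factory=dict)
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _as_table(table) -> Contingency2x2:
    if isinstance(table, Contingency2x2):
        t = table
    else:
        arr = np.asarray(table, dtype=float).reshape(4)
        t = Contingency2x2(*(int(v) for v in arr))
        if any(float(v) != int(v) for v in arr):
            raise ValueError("table entries must be integers")
    if min(t) < 0:
        raise ValueError("table entries must be non-negative")
    return t


# ---------------------------------------------------------------------------
# Chi-square (uncorrected)
# ---------------------------------------------------------------------------

def chi2_uncorrected(table) -> TestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1.

    The statistic equals the squared pooled two-proportion z statistic.  A
    zero column margin makes the comparison degenerate: the result is
    statistic 0, p = 1, with a warning.
    """
    t = _as_table(table)
    n1, n2 = t.a + t.b, t.c + t.d
    if n1 == 0 or n2 == 0:
        raise ValueError("both row sums must be positive")
    col1, col2 = t.a + t.c, t.b + t.d
    inputs = {"table": tuple(t)}
    if col1 == 0 or col2 == 0:
        warnings.warn("degenerate 2x2 table (a zero column margin); p = 1", stacklevel=2)
        return TestResult("chi2_uncorrected", 0.0, 1.0, df=1, inputs=inputs,
                          note="zero column margin")
    n = n1 + n2
    obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    expected = np.outer([n1, n2], [col1, col2]) / n
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return TestResult("chi2_uncorrected", chi2, p, df=1, inputs=inputs)


# ---------------------------------------------------------------------------
# Fisher exact (two-tailed, point-probability convention)
# ---------------------------------------------------------------------------

def _hypergeom_support(t: Contingency2x2) -> tuple[np.ndarray, np.ndarray]:
    """Support and point probabilities of the a-cell under fixed margins."""
    n1, col1 = t.a + t.b, t.a + t.c
    n = t.a + t.b + t.c + t.d
    lo = max(0, col1 - (t.c + t.d))
    hi = min(n1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, n1)
    return support, pmf


def fisher_exact_two_tailed(table, *, method: str = "point_probability") -> TestResult:
    """Two-tailed Fisher exact test on a 2x2 table.

    ``method="point_probability"`` (the dominant convention) sums the
    hypergeometric point probabilities of all tables with the observed
    margins that are no more probable than the observed one.
    ``method="doubling"`` instead doubles the smaller one-tail probability
    (capped at 1), matching some legacy software.
    """
    t = _as_table(table)
    support, pmf = _hypergeom_support(t)
    p_obs = float(pmf[support == t.a][0])
    if method == "point_probability":
        # same relative guard as common implementations: tables whose
        # probability exceeds p_obs by < 1e-7 relative count as ties
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    elif method == "doubling":
        lower = float(pmf[support <= t.a].sum())
        upper = float(pmf[support >= t.a].sum())
        p = 2 * min(lower, upper)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = min(p, 1.0)
    return TestResult(
        "fisher_exact_two_tailed", p_obs, p, exact=True,
        inputs={"table": tuple(t), "method": method},
    )


# ---------------------------------------------------------------------------
# Barnard exact (unconditional, two-tailed)
# ---------------------------------------------------------------------------

def _wald_statistic_grid(n1: int, n2: int, pooled: bool = True) -> np.ndarray:
    """T(x1, x2) on the full (n1+1) x (n2+1) lattice; 0 where undefined."""
    x1 = np.arange(n1 + 1)[:, None]
    x2 = np.arange(n2 + 1)[None, :]
    p1 = x1 / n1
    p2 = x2 / n2
    if pooled:
        pp = (x1 + x2) / (n1 + n2)
        var = pp * (1 - pp) * (1 / n1 + 1 / n2)
    else:
        var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, (p1 - p2) / np.sqrt(var), 0.0)
    return t


def barnard_exact_two_tailed(
    table,
    n_grid: int = 2000,
    *,
    statistic: str = "wald_pooled",
    refine: bool = True,
) -> TestResult:
    """Barnard's unconditional exact two-tailed test for a 2x2 table.

    Maximizes the tail probability of the rejection region
    ``{|T| >= |T_obs|}`` over the nuisance success probability on an
    ``n_grid``-point grid in (0, 1), followed by bounded local refinement
    around the grid maximum (the tail probability is a polynomial in pi, so
    the refinement is a smooth 1-D maximization).

    ``statistic="wald_pooled"`` (default) uses the pooled-variance score/Wald
    two-proportion z; ``"wald_unpooled"`` uses the unpooled (Welch-style)
    variance, for sensitivity analysis.
    """
    if n_grid < 10:
        raise ValueError(f"n_grid must be >= 10, got {n_grid}")
    if statistic not in ("wald_pooled", "wald_unpooled"):
        raise ValueError(f"unknown statistic {statistic!r}")
    t = _as_table(table)
    n1, n2 = t.a + t.b, t.c + t.d
    if n1 == 0 or n2 == 0:
        raise ValueError("both row sums must be positive")
    tgrid = _wald_statistic_grid(n1, n2, pooled=statistic == "wald_pooled")
    t_obs = tgrid[t.a, t.c]
    # exact |T| ties (notably the mirror table (n1-x1, n2-x2)) belong to the
    # rejection region; the relative tolerance only absorbs rounding noise
    region = np.abs(tgrid) >= abs(t_obs) * (1 - 1e-12) - 1e-12

    x1 = np.arange(n1 + 1)
    x2 = np.arange(n2 + 1)

    def tail(pi: np.ndarray) -> np.ndarray:
        pi = np.atleast_1d(pi)
        pmf1 = stats.binom.pmf(x1[None, :], n1, pi[:, None])
        pmf2 = stats.binom.pmf(x2[None, :], n2, pi[:, None])
        return np.einsum("gi,ij,gj->g", pmf1, region.astype(float), pmf2)

    eps = 1e-9
    grid = np.linspace(eps, 1 - eps, n_grid)
    values = tail(grid)
    best = int(values.argmax())
    p = float(values[best])
    if refine:
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, n_grid - 1)]
        res = optimize.minimize_scalar(
            lambda pi: -tail(np.array([pi]))[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        p = max(p, float(-res.fun))
    p = min(p, 1.0)
    return TestResult(
        "barnard_exact_two_tailed",
        float(t_obs),
        p,
        exact=True,
        inputs={"table": tuple(t), "n_grid": n_grid, "statistic": statistic},
    )


# ---------------------------------------------------------------------------
# Student t (pooled variance) from summaries or vectors
# ---------------------------------------------------------------------------

def pooled_t_two_tailed(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Two-tailed unpaired Student t-test (pooled variance) from summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    inputs = {"mean1": mean1, "sd1": sd1, "n1": n1, "mean2": mean2, "sd2": sd2, "n2": n2}
    df = n1 + n2 - 2
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return TestResult("pooled_t_two_tailed", 0.0, 1.0, df=df, inputs=inputs)
        warnings.warn("zero variance in both groups with unequal means; p = 0",
                      stacklevel=2)
        return TestResult("pooled_t_two_tailed", math.inf, 0.0, df=df, inputs=inputs,
                          note="degenerate zero-variance comparison")
    stat, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return TestResult("pooled_t_two_tailed", float(stat), float(p), df=df, inputs=inputs)


def pooled_t_from_vectors(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Reduce raw vectors to summary statistics and apply the pooled t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return pooled_t_two_tailed(
        float(x.mean()), float(x.std(ddof=1)), x.size,
        float(y.mean()), float(y.std(ddof=1)), y.size,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney (exact by enumeration for small n)
# ---------------------------------------------------------------------------

EXACT_MW_LIMIT = 12


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def mann_whitney_two_tailed(
    x: Sequence[float], y: Sequence[float], *, method: str = "auto"
) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    With ``n1 + n2 <= 12`` (or ``method="exact"``) the permutation null is
    enumerated exactly over all assignments of the pooled mid-ranks, giving
    ``p = P(|U - n1 n2 / 2| >= |U_obs - n1 n2 / 2|)``; ties are handled by
    mid-ranks.  Larger samples use the normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both vectors must be non-empty")
    n1, n2 = x.size, y.size
    if method == "auto":
        method = "exact" if n1 + n2 <= EXACT_MW_LIMIT else "asymptotic"
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2
    inputs = {"n1": n1, "n2": n2}
    if method == "exact":
        from itertools import combinations

        dev_obs = abs(u_obs - mu)
        hits = total = 0
        base = n1 * (n1 + 1) / 2
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - base
            total += 1
            if abs(u - mu) >= dev_obs - 1e-9:
                hits += 1
        return TestResult(
            "mann_whitney_two_tailed", u_obs, hits / total, exact=True, inputs=inputs
        )
    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(
        "mann_whitney_two_tailed", float(res.statistic), float(res.pvalue),
        inputs=inputs,
    )


# ---------------------------------------------------------------------------
# One-sample binomial proportion (normal theory)
# ---------------------------------------------------------------------------

def one_sample_proportion_normal(k: int, n: int, p0: float) -> TestResult:
    """Normal-theory one-sample test of a binomial proportion against p0."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("need 0 < p0 < 1")
    z = (k / n - p0) / math.sqrt(p0 * (1 - p0) / n)
    p = float(2 * stats.norm.sf(abs(z)))
    return TestResult(
        "one_sample_proportion_normal", z, p, inputs={"k": k, "n": n, "p0": p0}
    )


# ---------------------------------------------------------------------------
# Test auto-selection for 2x2 comparisons
# ---------------------------------------------------------------------------

def choose_two_proportion_test(
    table,
    *,
    per_sample: bool = False,
    barnard_max_n: int = 10,
    min_expected_cell: float = 5.0,
) -> str:
    """Pick a 2x2 test name following the survey's mixed usage.

    Per-sample presence comparisons with both group sizes <= ``barnard_max_n``
    get Barnard's unconditional test; otherwise tables with a minimum expected
    cell below ``min_expected_cell`` get Fisher, and everything else the
    uncorrected chi-square.
    """
    t = _as_table(table)
    n1, n2 = t.a + t.b, t.c + t.d
    if per_sample and max(n1, n2) <= barnard_max_n:
        return "barnard"
    col1, col2 = t.a + t.c, t.b + t.d
    n = n1 + n2
    if n == 0 or col1 == 0 or col2 == 0:
        return "fisher"
    min_expected = min(r * c / n for r in (n1, n2) for c in (col1, col2))
    return "fisher" if min_expected < min_expected_cell else "chi2"


_TEST_DISPATCH = {
    "chi2": chi2_uncorrected,
    "fisher": fisher_exact_two_tailed,
    "barnard": barnard_exact_two_tailed,
}


def run_two_proportion_test(table, test: str = "auto", **kwargs) -> TestResult:
    """Run a named (or auto-selected) 2x2 test on a table."""
    if test == "auto":
        test = choose_two_proportion_test(table, **kwargs)
        kwargs = {}
    try:
        fn = _TEST_DISPATCH[test]
    except KeyError:
        raise ValueError(f"unknown test {test!r}; options: {sorted(_TEST_DISPATCH)}")
    return fn(table, **kwargs)
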