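"""Rank-based comparison of carbon estimation methods.

Three instruments, all operating on per-species (or per-group) carbon
estimates of two or more methods:

* signed relative errors of each method's total against the cross-method
  arithmetic mean, RE = (X − μ)/μ · 100%;
* pairwise two-sided Wilcoxon signed-rank tests — exact null distribution
  for n ≤ 25 effective pairs (zero differences dropped, ties mid-ranked),
  normal approximation with continuity correction beyond;
* pairwise Spearman rank correlations — exact permutation p-value for
  n ≤ 9, t-distribution approximation beyond.

The significance level (default 0.05) is a report annotation only; nothing
is filtered by it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class ComparisonError(ValueError):
    pass


def relative_errors(method_totals: Mapping[str, float]) -> dict[str, float]:
    """Signed percentage deviation of each total from the cross-method mean.

    RE_m = (X_m − μ)/μ × 100 with μ the arithmetic mean of all supplied
    totals.  Requires at least two methods and μ ≠ 0.
    """
    if len(method_totals) < 2:
        raise ComparisonError("need at least two method totals")
    mu = float(np.mean(list(method_totals.values())))
    if mu == 0:
        raise ComparisonError("mean of method totals is zero; relative error undefined")
    return {m: (x - mu) / mu * 100.0 for m, x in method_totals.items()}


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ (sum of positive ranks)
    p_value: float
    n_effective: int  # pairs remaining after dropping zero differences
    exact: bool
    all_zero: bool = False


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p for the signed-rank statistic with mid-ranks.

    Enumerates the null distribution of W+ by dynamic programming over the
    doubled ranks (doubling makes tied mid-ranks integral).  The null is
    symmetric, so p = min(1, 2·min(P(W+ ≤ w), P(W+ ≥ w))).
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts += shifted
    n = len(ranks)
    w2 = int(round(2 * w_plus))
    cdf = counts[: w2 + 1].sum() / 2**n
    sf = counts[w2:].sum() / 2**n
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 25
) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's original rule) and reported via
    ``n_effective``; tied absolute differences receive mid-ranks.  If every
    difference is zero the test is vacuous and p = 1 is returned flagged.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, exact=True, all_zero=True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return WilcoxonResult(w_plus, _exact_signed_rank_p(w_plus, ranks), n, exact=True)
    # normal approximation with continuity correction;
    # variance with tie correction: n(n+1)(2n+1)/24 − Σ(t³−t)/48 over tie groups
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    return WilcoxonResult(w_plus, float(2 * stats.norm.sf(abs(z))), n, exact=False)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    exact: bool
    undefined: bool = False  # constant column: rho has no meaning


def spearman(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 9
) -> SpearmanResult:
    """Spearman rank correlation with exact permutation p for small n.

    Mid-ranks are used for ties.  For n ≤ ``exact_max_n`` the p-value is the
    exact two-sided permutation probability P(|ρ*| ≥ |ρ|) over all n!
    orderings of one margin; beyond that, the usual t approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y):
        raise ComparisonError("paired samples must have equal length")
    if n < 3:
        raise ComparisonError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(math.nan, math.nan, exact=True, undefined=True)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n > exact_max_n:
        res = stats.spearmanr(x, y)
        return SpearmanResult(rho, float(res.pvalue), exact=False)
    xc = rx - rx.mean()
    yc = ry - ry.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    rho_all = (yc[perms] @ xc) / denom
    p = float((np.abs(rho_all) >= abs(rho) - 1e-12).mean())
    return SpearmanResult(rho, p, exact=True)


def _pairs(columns: Sequence[str]) -> list[tuple[str, str]]:
    return list(itertools.combinations(columns, 2))


def pairwise_wilcoxon(per_group_matrix: pd.DataFrame) -> dict[tuple[str, str], WilcoxonResult]:
    """Wilcoxon signed-rank test for every pair of method columns."""
    return {
        (a, b): wilcoxon_signed_rank(per_group_matrix[a], per_group_matrix[b])
        for a, b in _pairs(list(per_group_matrix.columns))
    }


def spearman_matrix(per_group_matrix: pd.DataFrame) -> dict[tuple[str, str], SpearmanResult]:
    """Spearman rank correlation for every pair of method columns."""
    return {
        (a, b): spearman(per_group_matrix[a], per_group_matrix[b])
        for a, b in _pairs(list(per_group_matrix.columns))
    }


@dataclass(frozen=True)
class ComparisonReport:
    """Method totals, relative errors and pairwise rank statistics."""

    method_totals: dict[str, float]
    mean_total: float
    relative_errors_pct: dict[str, float]
    per_group_matrix: pd.DataFrame
    wilcoxon: dict[tuple[str, str], WilcoxonResult]
    spearman: dict[tuple[str, str], SpearmanResult]
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "method_totals_tC": self.method_totals,
            "mean_total_tC": self.mean_total,
            "relative_errors_pct": self.relative_errors_pct,
            "alpha": self.alpha,
            "wilcoxon": {
                f"{a}|{b}": {
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "n_effective": r.n_effective,
                    "exact": r.exact,
                    "significant": bool(r.p_value < self.alpha),
                }
                for (a, b), r in self.wilcoxon.items()
            },
            "spearman": {
                f"{a}|{b}": {
                    "rho": r.rho,
                    "p_value": r.p_value,
                    "exact": r.exact,
                    "undefined": r.undefined,
                }
                for (a, b), r in self.spearman.items()
            },
        }


def compare_methods(per_group_matrix: pd.DataFrame, alpha: float = 0.05) -> ComparisonReport:
    """Full comparison of method columns of a group × method carbon matrix."""
    totals = {m: float(per_group_matrix[m].sum()) for m in per_group_matrix.columns}
    return ComparisonReport(
        method_totals=totals,
        mean_total=float(np.mean(list(totals.values()))),
        relative_errors_pct=relative_errors(totals),
        per_group_matrix=per_group_matrix,
        wilcoxon=pairwise_wilcoxon(per_group_matrix),
        spearman=spearman_matrix(per_group_matrix),
        alpha=alpha,
    )


def per_species_matrix(stocks: Mapping[str, "object"]) -> pd.DataFrame:
    """Species × method carbon matrix from a mapping of StockTables."""
    cols = {}
    for name, stock in stocks.items():
        cols[name] = stock.by("species")["carbon_tC"]
    return pd.DataFrame(cols).fillna(0.0)
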