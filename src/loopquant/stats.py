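"""Allele-independence statistics for close-allele distributions.

Cell-to-cell heterogeneity in loop formation is probed by comparing, per
condition, the observed distribution of cells with 0..n close alleles
against the binomial expectation under complete allele independence,

    f(c) = C(n, c) * p_c**c * (1 - p_c)**(n - c),

where n is the ploidy and p_c the population frequency of close alleles
estimated from the same data. A Pearson chi-square test quantifies the
departure from independence (coupled alleles pile up mass at 0 and n).
Pairwise comparisons of contact fractions between conditions use the
Marascuilo procedure for multiple proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class BinomialNull:
    """Expected fractions of cells with c = 0..n close alleles under
    allele independence."""

    p_c: float
    n: int
    expected_fractions: np.ndarray


@dataclass(frozen=True)
class CloseAlleleDistribution:
    """Observed counts of cells by number of close alleles, one condition."""

    condition: str
    counts: np.ndarray  # length n + 1, index = number of close alleles
    n: int              # ploidy
    pooled_p_c: float

    @property
    def total_cells(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float
    expected_counts: np.ndarray
    pooled_categories: bool
    valid: bool
    message: str = ""


@dataclass(frozen=True)
class ProportionSet:
    """k group proportions with sizes, for simultaneous comparison."""

    labels: Sequence[str]
    proportions: np.ndarray
    sizes: np.ndarray
    alpha: float = 0.05

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        n = np.asarray(self.sizes)
        object.__setattr__(self, "proportions", p)
        object.__setattr__(self, "sizes", n)
        if len(self.labels) != len(p) or len(p) != len(n):
            raise ValueError("labels, proportions and sizes must align")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("proportions must lie in [0, 1]")
        if np.any(n < 1):
            raise ValueError("every group size must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def binomial_expected(p_c: float, n: int) -> BinomialNull:
    """Expected close-allele fractions under complete allele independence."""
    if not (0.0 <= p_c <= 1.0):
        raise ValueError(f"p_c must lie in [0, 1], got {p_c}")
    if n < 1:
        raise ValueError("ploidy n must be >= 1")
    f = sps.binom.pmf(np.arange(n + 1), n, p_c)
    return BinomialNull(p_c=float(p_c), n=int(n), expected_fractions=f)


def observed_distribution(
    summaries: pd.DataFrame, n: int, condition: str | None = None
) -> CloseAlleleDistribution:
    """Count cells by their number of close alleles; pool p_c.

    Every cell must carry exactly ``n`` retained pairs (the ploidy filter
    guarantees this upstream); the pooled close-allele frequency
    p_c = (total contacts) / (N * n) parameterizes the independence null.
    """
    df = summaries
    if condition is not None:
        df = df[df["condition"] == condition]
    if len(df) == 0:
        raise ValueError(f"no cells for condition {condition!r}")
    if (df["n_pairs"] != n).any():
        bad = df.loc[df["n_pairs"] != n, "nucleus_id"].iloc[0]
        raise ValueError(
            f"cell {bad!r} has n_pairs != ploidy {n}; apply the ploidy "
            "filter (and full pair retention) before heterogeneity analysis"
        )
    contacts = df["n_contacts"].to_numpy(dtype=int)
    counts = np.bincount(contacts, minlength=n + 1)[: n + 1]
    p_c = contacts.sum() / (len(df) * n)
    label = condition if condition is not None else str(df["condition"].iloc[0])
    return CloseAlleleDistribution(
        condition=label, counts=counts, n=n, pooled_p_c=float(p_c)
    )


def _pool_low_expected(
    observed: np.ndarray, expected: np.ndarray, floor: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Merge categories with expected count below ``floor`` into a neighbor."""
    obs = list(observed.astype(float))
    exp = list(expected.astype(float))
    pooled = False
    while len(exp) > 2 and min(exp) < floor:
        i = int(np.argmin(exp))
        j = i - 1 if i == len(exp) - 1 else (
            i + 1 if i == 0 else (i - 1 if exp[i - 1] < exp[i + 1] else i + 1)
        )
        lo, hi = sorted((i, j))
        obs[lo] += obs.pop(hi)
        exp[lo] += exp.pop(hi)
        pooled = True
    return np.array(obs), np.array(exp), pooled


def independence_test(
    dist: CloseAlleleDistribution,
    expected_floor: float = 1.0,
    fitted_params: int = 0,
) -> ChiSquareResult:
    """Pearson chi-square of observed vs binomial-expected close-allele counts.

    Expected counts come from ``binomial_expected(pooled_p_c, n)`` scaled by
    the number of cells. Categories with expected count below
    ``expected_floor`` are pooled with their smaller neighbor. Degrees of
    freedom default to categories - 1; pass ``fitted_params=1`` to account
    for p_c being estimated from the same data (categories - 2), which is
    the calibrated choice for type-I error control.
    """
    N = dist.total_cells
    if dist.pooled_p_c in (0.0, 1.0):
        return ChiSquareResult(
            statistic=float("nan"), df=0, pvalue=float("nan"),
            expected_counts=np.array([]), pooled_categories=False,
            valid=False,
            message="all alleles in one category: independence test undefined",
        )
    null = binomial_expected(dist.pooled_p_c, dist.n)
    expected = null.expected_fractions * N
    obs, exp, pooled = _pool_low_expected(
        dist.counts.astype(float), expected, expected_floor
    )
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(exp) - 1 - fitted_params
    if df < 1:
        return ChiSquareResult(
            statistic=chi2, df=df, pvalue=float("nan"),
            expected_counts=exp, pooled_categories=pooled, valid=False,
            message="no degrees of freedom left after pooling",
        )
    pvalue = float(sps.chi2.sf(chi2, df))
    return ChiSquareResult(
        statistic=chi2, df=df, pvalue=pvalue, expected_counts=exp,
        pooled_categories=pooled, valid=True,
    )


def marascuilo(groups: ProportionSet) -> pd.DataFrame:
    """Simultaneous pairwise comparison of k proportions.

    For each pair (i, j) the critical range is
    sqrt(chi2_{1-alpha, k-1}) * sqrt(p_i(1-p_i)/n_i + p_j(1-p_j)/n_j);
    the pair differs significantly when |p_i - p_j| exceeds it.
    """
    k = len(groups.labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    crit = np.sqrt(sps.chi2.ppf(1.0 - groups.alpha, k - 1))
    rows = []
    for i, j in combinations(range(k), 2):
        p_i, p_j = groups.proportions[i], groups.proportions[j]
        n_i, n_j = groups.sizes[i], groups.sizes[j]
        rng = crit * np.sqrt(p_i * (1 - p_i) / n_i + p_j * (1 - p_j) / n_j)
        diff = abs(p_i - p_j)
        rows.append({
            "group_i": groups.labels[i], "group_j": groups.labels[j],
            "diff": diff, "critical_range": float(rng),
            "significant": bool(diff > rng),
        })
    return pd.DataFrame(rows)


def significance_stars(pvalue: float) -> str:
    """Asterisk convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(pvalue):
        return "n.d."
    if pvalue < 0.001:
        return "***"
    if pvalue < 0.01:
        return "**"
    if pvalue < 0.05:
        return "*"
    return "n.s."
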