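"""Rating-study statistics: Fleiss' multirater kappa, chi-square tests,
and the Mann-Whitney U test.

These serve preference studies in which a panel of raters assigns each
item (an image pair) to a category (auto-capture better / manual better /
equal quality): kappa for the panel's chance-corrected agreement, the
chi-square test for vote-share independence or goodness of fit, and the
Mann-Whitney U test for comparing quality-score samples whose integer,
heavily tied values rule out normal-theory tests.

Implementations follow the classic definitions exactly -- equal raters per
item for Fleiss' kappa, U reported as min(U_a, U_b) with mid-rank tie
handling, exact enumeration for small samples -- with p-values from
scipy's distributions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Per-group sample size at or below which the Mann-Whitney p-value is
#: computed by exact enumeration rather than the normal approximation.
MWU_EXACT_MAX_N = 8


# --------------------------------------------------------------------------
# Fleiss' multirater kappa
# --------------------------------------------------------------------------


def votes_to_counts(votes: pd.DataFrame,
                    categories: Optional[Sequence] = None) -> np.ndarray:
    """Aggregate an items x raters vote table to an items x categories
    count matrix (column order = sorted categories unless given)."""
    values = votes.to_numpy()
    cats = list(categories) if categories is not None else sorted(
        pd.unique(values.ravel()))
    counts = np.zeros((values.shape[0], len(cats)), dtype=int)
    for j, c in enumerate(cats):
        counts[:, j] = (values == c).sum(axis=1)
    return counts


def fleiss_kappa(table) -> float:
    """Fleiss' kappa for an items x categories count matrix.

    kappa = (P_bar - P_e) / (1 - P_e) where P_bar is the mean within-item
    pairwise agreement and P_e the sum of squared category marginals.
    Requires the same number of ratings n >= 2 on every item.  Returns NaN
    when P_e = 1 (all ratings in one category across the whole table),
    where chance-corrected agreement is undefined.
    """

    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 1 or counts.shape[1] < 2:
        raise ValueError("need an items x categories matrix with >= 2 "
                         "categories")
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    row_sums = counts.sum(axis=1)
    n = row_sums[0]
    if n < 2:
        raise ValueError("each item needs at least 2 ratings")
    if not np.all(row_sums == n):
        raise ValueError("Fleiss' kappa requires an equal number of "
                         "ratings per item")
    n_items = counts.shape[0]
    p_j = counts.sum(axis=0) / (n_items * n)
    p_i = (np.sum(counts * (counts - 1.0), axis=1)) / (n * (n - 1.0))
    p_bar = float(np.mean(p_i))
    p_e = float(np.sum(p_j ** 2))
    if math.isclose(p_e, 1.0):
        return math.nan
    return (p_bar - p_e) / (1.0 - p_e)


# --------------------------------------------------------------------------
# Chi-square tests
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi_square(
    observed,
    mode: str = "independence",
    expected_probs: Optional[Sequence[float]] = None,
    yates: bool = False,
) -> ChiSquareResult:
    """Pearson chi-square test.

    mode="independence": ``observed`` is an r x c contingency table;
    expected counts come from the product of the margins and
    df = (r-1)(c-1).  mode="goodness-of-fit": ``observed`` is a count
    vector compared against ``expected_probs`` (uniform by default),
    df = k - 1.  No continuity correction unless ``yates`` is set (2 x 2
    independence only).
    """

    obs = np.asarray(observed, dtype=float)
    if np.any(obs < 0):
        raise ValueError("observed counts must be non-negative")

    if mode in ("independence", "ind"):
        if obs.ndim != 2 or min(obs.shape) < 2:
            raise ValueError("independence mode needs an r x c table, "
                             "r, c >= 2")
        total = obs.sum()
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
        df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    elif mode in ("goodness-of-fit", "gof"):
        obs = obs.ravel()
        k = obs.size
        if k < 2:
            raise ValueError("goodness of fit needs >= 2 categories")
        probs = (np.full(k, 1.0 / k) if expected_probs is None
                 else np.asarray(expected_probs, dtype=float))
        if probs.size != k or np.any(probs <= 0) or \
                not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("expected_probs must be positive and sum to 1")
        expected = probs * obs.sum()
        df = k - 1
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if np.any(expected <= 0):
        raise ValueError("all expected counts must be positive")

    diff = np.abs(obs - expected)
    if yates:
        if mode not in ("independence", "ind") or obs.shape != (2, 2):
            raise ValueError("Yates correction applies to 2 x 2 "
                             "independence tables only")
        diff = np.maximum(diff - 0.5, 0.0)
    x2 = float(np.sum(diff ** 2 / expected))
    p = float(sps.chi2.sf(x2, df))
    return ChiSquareResult(statistic=x2, df=int(df), p_value=p)


# --------------------------------------------------------------------------
# Mann-Whitney U
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # min(U_a, U_b)
    u_a: float
    p_value: float
    method: str  # "exact" | "normal" | "degenerate"


def _u_from_ranks(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   exact_max_n: int = MWU_EXACT_MAX_N) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with mid-rank tie handling.

    U statistics are computed from mid-ranks; the reported ``u`` is
    min(U_a, U_b).  The two-sided p-value is the exact permutation
    probability P(|U - n_a n_b / 2| >= |u_obs - n_a n_b / 2|) when both
    groups have at most ``exact_max_n`` observations, and otherwise a
    normal approximation with tie-corrected variance and a 0.5 continuity
    correction.  When every value in both samples is identical the test is
    degenerate and p = 1 is returned.
    """

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # mid-ranks
    u_a = _u_from_ranks(ranks[:n_a], n_a)
    u_b = n_a * n_b - u_a
    u = min(u_a, u_b)

    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(u=u, u_a=u_a, p_value=1.0,
                                 method="degenerate")

    mu = n_a * n_b / 2.0
    if n_a <= exact_max_n and n_b <= exact_max_n:
        # enumerate all assignments of the pooled mid-ranks to group a
        dev_obs = abs(u_a - mu)
        total = 0
        hits = 0
        idx = range(n_a + n_b)
        for comb in itertools.combinations(idx, n_a):
            u_comb = _u_from_ranks(ranks[list(comb)], n_a)
            total += 1
            if abs(u_comb - mu) >= dev_obs - 1e-12:
                hits += 1
        return MannWhitneyResult(u=u, u_a=u_a, p_value=hits / total,
                                 method="exact")

    # tie-corrected normal approximation
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1.0))
    var = n_a * n_b / 12.0 * ((n + 1.0) - tie_term)
    z = (abs(u_a - mu) - 0.5) / math.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
    return MannWhitneyResult(u=u, u_a=u_a, p_value=p, method="normal")
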