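"""Group statistics: Friedman tests and binomial confidence intervals.

Two animal groups of unequal size are compared over the 12-trial schedule by
a Friedman test on a trials x groups block matrix: each of the 12 blocks
holds the two per-group means of the per-animal measure for that trial, so
k = 2 columns and df = 1.  The statistic uses within-block mid-ranks with
the standard tie correction, and its p-value is the chi-square upper tail.

The ensemble-level verdict is backed by a binomial view of its members: each
strong classifier independently re-runs the group comparison on its own
classification, producing a 1 (significant) or 0; the Clopper-Pearson 95%
interval of that success proportion must lie clearly above 0.5 for the
conclusion to be confirmed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class FriedmanResult:
    Q: float
    df: int
    p: float
    k: int
    n_blocks: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass(frozen=True)
class BinomialCI:
    successes: int
    n: int
    mean: float
    low: float
    high: float
    confirmed: bool   # True when the interval lies clearly above 0.5


def chi2_upper_tail(Q: float, df: int) -> float:
    """Survival function of the chi-square distribution at ``Q``."""
    if Q < 0:
        raise ValueError("Q must be non-negative")
    if df < 1:
        raise ValueError("df must be at least 1")
    return float(sps.chi2.sf(Q, df))


def friedman_test(block_matrix: np.ndarray) -> FriedmanResult:
    """Friedman rank test over an ``n_blocks x k`` matrix.

    Ranks are taken within blocks with mid-ranks for ties; the statistic
    carries the usual tie correction and is referred to chi-square with
    ``k - 1`` degrees of freedom.
    """
    M = np.asarray(block_matrix, dtype=float)
    if M.ndim != 2:
        raise ValueError("block matrix must be 2-D")
    n, k = M.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 columns")
    if np.any(np.all(np.isnan(M), axis=1)):
        raise ValueError("a block is entirely missing")

    ranks = np.apply_along_axis(sps.rankdata, 1, M)
    col_sums = ranks.sum(axis=0)
    ssbn = float(np.sum(col_sums ** 2))

    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    ties = 0.0
    for row in M:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts ** 3 - counts))
    denom_corr = 1.0 - ties / (n * k * (k * k - 1))
    if denom_corr <= 0:
        # every block fully tied: no evidence either way
        return FriedmanResult(Q=0.0, df=k - 1, p=1.0, k=k, n_blocks=n)
    Q = (12.0 / (n * k * (k + 1)) * ssbn - 3.0 * n * (k + 1)) / denom_corr
    Q = max(Q, 0.0)
    return FriedmanResult(Q=float(Q), df=k - 1,
                          p=chi2_upper_tail(float(Q), k - 1),
                          k=k, n_blocks=n)


def vote_significance_ci(per_classifier_outcomes) -> BinomialCI:
    """Clopper-Pearson 95% CI over binary per-classifier verdicts."""
    outcomes = np.asarray(list(per_classifier_outcomes), dtype=int)
    if outcomes.size < 1:
        raise ValueError("need at least one outcome")
    if not np.all((outcomes == 0) | (outcomes == 1)):
        raise ValueError("outcomes must be binary")
    n = int(outcomes.size)
    s = int(outcomes.sum())
    low, high = proportion_confint(s, n, alpha=0.05, method="beta")
    return BinomialCI(successes=s, n=n, mean=s / n,
                      low=float(low), high=float(high),
                      confirmed=bool(low > 0.5))


def group_compare(measures: pd.DataFrame, measure: str,
                  trials: "list[int] | None" = None) -> FriedmanResult:
    """Friedman comparison of two groups across the trial schedule.

    ``measures`` is tidy with columns ``group``, ``animal_id``, ``trial`` and
    the named measure; each trial becomes a block whose two entries are the
    per-group means of the per-animal values.
    """
    if measure not in measures.columns:
        raise ValueError(f"measure {measure!r} not in the table")
    groups = sorted(measures["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    if trials is None:
        trials = sorted(measures["trial"].unique())
    cell = (measures.groupby(["trial", "group"])[measure]
            .mean().unstack("group"))
    missing = [t for t in trials if t not in cell.index
               or cell.loc[t].isna().any()]
    if missing:
        raise ValueError(f"a group is absent in trial(s) {missing}")
    block = cell.loc[trials, groups].to_numpy(float)
    return friedman_test(block)
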