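"""Shared exact tests, multiple-testing correction, correlation statistics,
a label-permutation engine, and the power-simulation acceptance rule.

These primitives back every analysis stage: gene-set enrichment is a Fisher
exact test on a 2x2 contingency table, q-values come from Benjamini-Hochberg,
clinical correlations of tied methylation ratios use Kendall's tau-b, and
concordance statistics are calibrated against exhaustive or sampled
label permutations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "PermutationResult",
    "fisher_exact_2x2",
    "bh_adjust",
    "kendall_tau",
    "permutation_pvalue",
    "power_simulation",
]

Alternative = Literal["two_sided", "greater", "less"]
Tail = Literal["two_sided", "greater", "less"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 contingency table of non-negative counts.

    Layout: ``a`` = in-set & positive, ``b`` = in-set & negative,
    ``c`` = out-set & positive, ``d`` = out-set & negative.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"count {name}={v!r} must be a non-negative integer")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("at least one margin of the table must be > 0")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class EnrichmentResult:
    """Odds ratio and Fisher p-value for one 2x2 enrichment test."""

    odds_ratio: float
    p_value: float
    table: ContingencyTable2x2
    q_value: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.odds_ratio < 0:
            raise ValueError("odds_ratio must be >= 0")


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic, its permutation null, and the permutation p-value."""

    observed_statistic: float
    null_statistics: np.ndarray
    p_value: float
    exhaustive: bool
    n_permutations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"permutation p-value {self.p_value} outside (0, 1]")


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact_2x2(
    table: ContingencyTable2x2, alternative: Alternative = "two_sided"
) -> EnrichmentResult:
    """Fisher's exact test on a 2x2 table.

    The odds ratio is the sample odds ratio ``ad / bc`` (+inf when ``bc`` is
    zero).  The p-value is computed by hypergeometric enumeration conditional
    on the margins; the two-sided p follows the minimum-likelihood convention
    (sum of probabilities of all tables no more likely than the observed one).
    Probabilities are compared in exact integer arithmetic, so ties at the
    observed likelihood are resolved deterministically with plain <= and no
    floating-point epsilon.
    """
    if isinstance(table, (tuple, list)):
        table = ContingencyTable2x2(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        # degenerate margins (0/0) carry no association evidence -> neutral OR
        odds_ratio = 1.0 if a * d == 0 else math.inf
    else:
        odds_ratio = (a * d) / (b * c)

    n = table.total
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    # integer pmf numerators over the common denominator comb(n, row1)
    numerators = [math.comb(col1, i) * math.comb(n - col1, row1 - i) for i in range(lo, hi + 1)]
    denom = math.comb(n, row1)
    num_obs = numerators[a - lo]

    if alternative == "greater":
        total = sum(numerators[a - lo :])
    elif alternative == "less":
        total = sum(numerators[: a - lo + 1])
    elif alternative == "two_sided":
        total = sum(num for num in numerators if num <= num_obs)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = float(Fraction(total, denom))
    return EnrichmentResult(odds_ratio=odds_ratio, p_value=min(p, 1.0), table=table)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Returns the adjusted values in the input order; an empty input returns an
    empty array.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return np.empty(0, dtype=float)
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Kendall tau
# ---------------------------------------------------------------------------


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Kendall rank correlation (tau-b) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant vector")
    res = stats.kendalltau(x, y, variant="b")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Permutation engine
# ---------------------------------------------------------------------------


def _group_masks_exhaustive(labels: np.ndarray) -> np.ndarray:
    """All distinct reassignments of a two-group labeling, as boolean masks
    marking membership of the first group."""
    n = labels.size
    uniq = np.unique(labels)
    n1 = int(np.sum(labels == uniq[0]))
    masks = np.zeros((math.comb(n, n1), n), dtype=bool)
    for i, idx in enumerate(itertools.combinations(range(n), n1)):
        masks[i, list(idx)] = True
    return masks


def n_arrangements(labels: Sequence) -> int:
    """Number of distinct two-group label arrangements."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size != 2:
        raise ValueError("permutation engine requires exactly two groups")
    return math.comb(int(counts.sum()), int(counts[0]))


def permutation_pvalue(
    values: np.ndarray,
    labels: Sequence,
    statistic: Callable[[np.ndarray, np.ndarray], float],
    max_exhaustive: int = 20_000,
    n_random: int = 5_000,
    seed: int | None = None,
    tail: Tail = "greater",
) -> PermutationResult:
    """Label-permutation p-value for an arbitrary two-group statistic.

    If the number of distinct label arrangements is at most ``max_exhaustive``
    all arrangements are enumerated and the p-value is the plain proportion of
    null statistics at least as extreme as the observed one (the observed
    arrangement is part of the enumeration, so p > 0).  Otherwise ``n_random``
    random arrangements are drawn and the +1-smoothed estimator
    ``(1 + #extreme) / (1 + n_random)`` is used.

    ``statistic`` must be a pure function of ``(values, labels)``.
    """
    values = np.asarray(values)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size != 2 or np.any(counts == 0):
        raise ValueError("need exactly two non-empty groups")
    if np.any(counts < 2):
        raise ValueError("need at least 2 samples per group")

    observed = float(statistic(values, labels))
    total = n_arrangements(labels)
    exhaustive = total <= max_exhaustive

    def _extreme(null: np.ndarray) -> np.ndarray:
        if tail == "greater":
            return null >= observed
        if tail == "less":
            return null <= observed
        if tail == "two_sided":
            return np.abs(null) >= abs(observed)
        raise ValueError(f"unknown tail {tail!r}")

    if exhaustive:
        masks = _group_masks_exhaustive(labels)
        null = np.empty(masks.shape[0], dtype=float)
        for i, mask in enumerate(masks):
            perm = np.where(mask, uniq[0], uniq[1])
            null[i] = statistic(values, perm)
        p = float(np.mean(_extreme(null)))
        n_perm = total
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_random, dtype=float)
        for i in range(n_random):
            null[i] = statistic(values, rng.permutation(labels))
        p = float((1 + np.sum(_extreme(null))) / (1 + n_random))
        n_perm = n_random

    return PermutationResult(
        observed_statistic=observed,
        null_statistics=null,
        p_value=p,
        exhaustive=exhaustive,
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Power simulation (pilot-study acceptance rule)
# ---------------------------------------------------------------------------


def power_simulation(
    group_sizes: tuple[int, int],
    effect: float | Callable[[np.random.Generator, tuple[int, int]], tuple[np.ndarray, np.ndarray]],
    n_repeats: int = 100,
    test: Literal["paired_t", "mann_whitney"] = "mann_whitney",
    alpha: float = 0.05,
    accept_threshold: float = 0.25,
    seed: int | None = None,
    sd: float = 1.0,
) -> tuple[float, bool]:
    """Simulate repeated small studies and report the fraction reaching p < alpha.

    ``effect`` is either a mean shift between the two groups (data then drawn
    Gaussian with standard deviation ``sd``) or a callable drawing the two
    group samples itself.  The simulated significance level is *accepted* when
    the success fraction strictly exceeds ``accept_threshold`` (default 25%).
    """
    n1, n2 = group_sizes
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if test == "paired_t" and n1 != n2:
        raise ValueError("paired t-test requires equal group sizes")

    rng = np.random.default_rng(seed)
    successes = 0
    for _ in range(n_repeats):
        if callable(effect):
            x, y = effect(rng, group_sizes)
        else:
            x = rng.normal(0.0, sd, size=n1)
            y = rng.normal(float(effect), sd, size=n2)
        if test == "paired_t":
            p = stats.ttest_rel(x, y).pvalue
        elif test == "mann_whitney":
            p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
        if p < alpha:
            successes += 1
    fraction = successes / n_repeats
    return fraction, fraction > accept_threshold
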