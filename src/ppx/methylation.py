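"""Targeted bisulfite methylation ratios, group comparisons, differential-
methylation classification, and clinical correlation.

The methylation level of a CpG in a sample is the number of methylated reads
divided by the total reads; duplicate sequencing runs are summed per sample
before a minimum-coverage filter (default 4 reads) is applied.  Group
comparisons fit a Poisson GLM of methylated counts on group with a log total-
reads offset (the coefficient is a log rate ratio of methylation), falling
back to a two-sample t-test on ratios when every sample of one group has zero
methylated counts (where the Poisson MLE diverges).  Clinical-group
comparisons with group sizes of at least four use the Wilcoxon rank-sum test.
Differential methylation is mild / moderate / strong at p < 0.05 with a
methylation-ratio difference of at least 0.125 / 0.25 / 0.5.

Coordinates are 1-based throughout; the BED export converts to 0-based
half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .stats_core import kendall_tau

logger = logging.getLogger(__name__)

__all__ = [
    "DMResult",
    "filter_and_ratio",
    "compare_groups",
    "compare_groups_clinical",
    "classify_dm",
    "methylation_clinical_correlation",
    "to_bed",
]

COUNT_COLUMNS = ("chrom", "pos", "sample", "group", "methylated", "total")
DMClass = Literal["none", "mild", "moderate", "strong"]

# classification tiers: (|delta| threshold, class), strongest first
_TIERS = ((0.5, "strong"), (0.25, "moderate"), (0.125, "mild"))


@dataclass(frozen=True)
class DMResult:
    """Group comparison at one CpG."""

    chrom: str
    pos: int
    ratio_a: float
    ratio_b: float
    delta: float
    test: Literal["poisson_glm", "t_test", "wilcoxon"]
    p_value: float
    dm_class: DMClass
    rate_ratio: float | None = None


def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"count table lacks columns {missing}")
    if (counts["methylated"] > counts["total"]).any() or (counts["methylated"] < 0).any():
        raise ValueError("need 0 <= methylated <= total")
    return counts


def filter_and_ratio(counts: pd.DataFrame, min_coverage: int = 4) -> pd.DataFrame:
    """Per-sample methylation ratios after run-summing and coverage filtering.

    Multiple sequencing runs of one sample at one CpG are summed (methylated
    and total) before rows with total < ``min_coverage`` are dropped.  Returns
    columns chrom, pos, sample, group, methylated, total, ratio.
    """
    df = _validate_counts(counts)
    summed = (
        df.groupby(["chrom", "pos", "sample", "group"], as_index=False, sort=True)[
            ["methylated", "total"]
        ].sum()
    )
    kept = summed[summed["total"] >= min_coverage].copy()
    n_dropped = len(summed) - len(kept)
    if n_dropped:
        logger.info("coverage filter dropped %d of %d CpG-sample rows", n_dropped, len(summed))
    kept["ratio"] = kept["methylated"] / kept["total"]
    return kept.reset_index(drop=True)


def _poisson_rate_ratio(
    meth: np.ndarray, total: np.ndarray, is_case: np.ndarray, offset: bool = True
):
    """Poisson GLM of methylated counts on group, by default with a log(total)
    offset so the coefficient is a log rate ratio per sequenced read."""
    X = sm.add_constant(is_case.astype(float))
    model = sm.GLM(
        meth,
        X,
        family=sm.families.Poisson(),
        offset=np.log(total.astype(float)) if offset else None,
    )
    fit = model.fit()
    coef = fit.params[1]
    return float(np.exp(coef)), float(fit.pvalues[1])


def compare_groups(
    cpg_rows: pd.DataFrame,
    min_group_n: int = 2,
    min_coverage: int = 4,
    offset: bool = True,
) -> DMResult | None:
    """Case/control comparison at a single CpG.

    ``cpg_rows`` holds the (already run-summed or raw) rows of one CpG.
    Returns None with a logged reason when either group has fewer than
    ``min_group_n`` samples after coverage filtering.  Delta is the
    difference of group mean ratios (first group minus second, groups sorted;
    with case/control labels this is case minus control after sorting puts
    case first).
    """
    rows = filter_and_ratio(cpg_rows, min_coverage=min_coverage)
    if rows.empty:
        return None
    chrom = rows["chrom"].iloc[0]
    pos = int(rows["pos"].iloc[0])
    groups = sorted(rows["group"].unique())
    if len(groups) != 2:
        logger.info("CpG %s:%d skipped: need exactly 2 groups", chrom, pos)
        return None
    ga = rows[rows["group"] == groups[0]]
    gb = rows[rows["group"] == groups[1]]
    if len(ga) < min_group_n or len(gb) < min_group_n:
        logger.info("CpG %s:%d skipped: group below n=%d", chrom, pos, min_group_n)
        return None
    ratio_a = float(ga["ratio"].mean())
    ratio_b = float(gb["ratio"].mean())
    delta = ratio_a - ratio_b

    all_zero = (ga["methylated"].sum() == 0) or (gb["methylated"].sum() == 0)
    if all_zero:
        # Poisson MLE diverges when one group is all-zero: fall back to t-test
        t_res = stats.ttest_ind(ga["ratio"], gb["ratio"])
        p = float(t_res.pvalue)
        if np.isnan(p):  # both groups constant, e.g. all zero everywhere
            p = 1.0
        test = "t_test"
        rate_ratio = None
    else:
        is_case = np.concatenate([np.ones(len(ga)), np.zeros(len(gb))])
        meth = np.concatenate([ga["methylated"], gb["methylated"]])
        total = np.concatenate([ga["total"], gb["total"]])
        rate_ratio, p = _poisson_rate_ratio(meth, total, is_case, offset=offset)
        test = "poisson_glm"
    return DMResult(
        chrom=chrom,
        pos=pos,
        ratio_a=ratio_a,
        ratio_b=ratio_b,
        delta=delta,
        test=test,
        p_value=p,
        dm_class=classify_dm(p, delta),
        rate_ratio=rate_ratio,
    )


def compare_groups_clinical(
    ratios: pd.DataFrame, min_group_n: int = 4
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of per-sample ratios between two clinical
    groups, one row per CpG; CpGs with a group below ``min_group_n`` are
    skipped and logged.

    ``ratios`` needs columns chrom, pos, group, ratio (the output of
    :func:`filter_and_ratio`).
    """
    rows = []
    for (chrom, pos), sub in ratios.groupby(["chrom", "pos"], sort=True):
        groups = sorted(sub["group"].unique())
        if len(groups) != 2:
            logger.info("CpG %s:%d skipped: need exactly 2 groups", chrom, pos)
            continue
        a = sub.loc[sub["group"] == groups[0], "ratio"].to_numpy()
        b = sub.loc[sub["group"] == groups[1], "ratio"].to_numpy()
        if len(a) < min_group_n or len(b) < min_group_n:
            logger.info("CpG %s:%d skipped: group below n=%d", chrom, pos, min_group_n)
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            p = float(stats.ranksums(a, b).pvalue)
        delta = float(a.mean() - b.mean())
        rows.append(
            {
                "chrom": chrom,
                "pos": int(pos),
                "ratio_a": float(a.mean()),
                "ratio_b": float(b.mean()),
                "delta": delta,
                "test": "wilcoxon",
                "p": p,
                "dm_class": classify_dm(p, delta),
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ratio_a", "ratio_b", "delta", "test", "p", "dm_class"]
    )


def classify_dm(p: float, delta: float, alpha: float = 0.05) -> DMClass:
    """Mild / moderate / strong differential methylation.

    none when p >= alpha or |delta| < 0.125; otherwise the highest tier whose
    threshold |delta| meets (tiers are nested: strong implies moderate and
    mild).
    """
    if not (-1.0 <= delta <= 1.0):
        raise ValueError("delta must lie in [-1, 1]")
    if p >= alpha:
        return "none"
    for threshold, name in _TIERS:
        if abs(delta) >= threshold:
            return name
    return "none"


def methylation_clinical_correlation(
    ratios: pd.DataFrame, clinical: pd.Series, min_pairs: int = 5
) -> pd.DataFrame:
    """Kendall tau-b of per-sample CpG ratios against a clinical variable.

    ``ratios`` as from :func:`filter_and_ratio`; ``clinical`` maps sample id
    to the variable.  CpGs with constant ratios or fewer than ``min_pairs``
    paired observations are skipped.
    """
    rows = []
    for (chrom, pos), sub in ratios.groupby(["chrom", "pos"], sort=True):
        paired = sub[sub["sample"].isin(clinical.index)]
        if len(paired) < min_pairs:
            logger.info("CpG %s:%d skipped: fewer than %d pairs", chrom, pos, min_pairs)
            continue
        x = paired["ratio"].to_numpy(dtype=float)
        y = clinical.loc[paired["sample"]].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.info("CpG %s:%d skipped: constant values", chrom, pos)
            continue
        tau, p = kendall_tau(x, y)
        rows.append(
            {"chrom": chrom, "pos": int(pos), "tau": tau, "p": p, "significant": p < 0.05}
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "tau", "p", "significant"])


def to_bed(results: Sequence[DMResult] | pd.DataFrame) -> pd.DataFrame:
    """BED-style frame (0-based half-open) from 1-based CpG results."""
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        df = pd.DataFrame([r.__dict__ for r in results])
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"].astype(int) - 1,
            "end": df["pos"].astype(int),
        }
    )
    if "dm_class" in df.columns:
        out["name"] = df["dm_class"].astype(str)
    return out
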