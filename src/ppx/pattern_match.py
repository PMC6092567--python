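"""Discretized expression-pattern concordance: the match-score statistic and
its class-label permutation null.

Genes are discretized into three states per contrast — up-regulated (UP),
down-regulated (DN), or unchanged (NS).  For a pair of conditions, each gene
scores +1 for UP/UP or DN/DN, 0 for NS/NS, -1 for UP/DN or DN/UP, and -0.5
for any other pattern; the matching score is the sum over genes.  Its
significance comes from permuting the class labels of the in vitro
experiment, re-deriving differential expression and the discretized states
for every arrangement (exhaustive when feasible, otherwise a random sample of
5,000 arrangements).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEResult, squeeze_variances
from .stats_core import PermutationResult, bh_adjust, permutation_pvalue

__all__ = [
    "StatePattern",
    "MatchScoreResult",
    "discretize_states",
    "match_score",
    "match_permutation_test",
]

State = Literal["UP", "DN", "NS"]
_STATE_CODE = {"UP": 1, "DN": -1, "NS": 0}


@dataclass(frozen=True)
class StatePattern:
    """Gene -> {UP, DN, NS} state assignment for one contrast."""

    states: pd.Series

    def __post_init__(self) -> None:
        bad = set(self.states.unique()) - set(_STATE_CODE)
        if bad:
            raise ValueError(f"invalid states {bad}; expected UP/DN/NS")

    @property
    def genes(self) -> pd.Index:
        return self.states.index

    def codes(self) -> np.ndarray:
        return self.states.map(_STATE_CODE).to_numpy(dtype=int)

    def inverted(self) -> "StatePattern":
        flip = {"UP": "DN", "DN": "UP", "NS": "NS"}
        return StatePattern(self.states.map(flip))


@dataclass(frozen=True)
class MatchScoreResult:
    """Matching score with the per-gene score vector and (optionally) its
    permutation null."""

    score: float
    per_gene: pd.Series
    permutation: PermutationResult | None = None


def discretize_states(
    de: DEResult, q_threshold: float = 0.05, fc_threshold: float = 1.5
) -> StatePattern:
    """UP if significant with positive fold-change, DN if negative, else NS."""
    table = de.table
    if table[["q", "log2fc"]].isna().any().any():
        raise ValueError("DE result contains missing q or fold-change values")
    sig = (table["q"] <= q_threshold) & (
        np.abs(table["log2fc"]) >= np.log2(fc_threshold)
    )
    states = np.where(~sig, "NS", np.where(table["log2fc"] > 0, "UP", "DN"))
    return StatePattern(pd.Series(states, index=table.index, name="state"))


def _score_codes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    prod = a * b
    out = np.full(a.shape, -0.5)
    out[prod == 1] = 1.0  # UP/UP or DN/DN
    out[prod == -1] = -1.0  # UP/DN or DN/UP
    out[(a == 0) & (b == 0)] = 0.0  # NS/NS
    return out


def match_score(a: StatePattern, b: StatePattern) -> MatchScoreResult:
    """Sum of per-gene scores over the shared gene universe."""
    if set(a.genes) != set(b.genes):
        only_a = sorted(set(a.genes) - set(b.genes))
        only_b = sorted(set(b.genes) - set(a.genes))
        raise ValueError(
            f"gene universes differ; only in A: {only_a[:5]}, only in B: {only_b[:5]}"
        )
    b_aligned = StatePattern(b.states.loc[a.genes])
    per_gene = pd.Series(
        _score_codes(a.codes(), b_aligned.codes()), index=a.genes, name="score"
    )
    return MatchScoreResult(score=float(per_gene.sum()), per_gene=per_gene)


# ---------------------------------------------------------------------------
# Permutation test with the DE -> discretize chain recomputed per arrangement
# ---------------------------------------------------------------------------


def _two_group_states(
    x: np.ndarray,
    case_mask: np.ndarray,
    q_threshold: float,
    fc_threshold: float,
    eb_shrink: bool = True,
) -> np.ndarray:
    """Vectorized two-group moderated-t DE call, returned as state codes."""
    n1 = int(case_mask.sum())
    n2 = x.shape[1] - n1
    g1 = x[:, case_mask]
    g2 = x[:, ~case_mask]
    m1 = g1.mean(axis=1)
    m2 = g2.mean(axis=1)
    log2fc = m1 - m2
    df = n1 + n2 - 2
    ss = ((g1 - m1[:, None]) ** 2).sum(axis=1) + ((g2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    if eb_shrink:
        s2_post, d0, _ = squeeze_variances(s2, df)
        df_t = df + d0
    else:
        s2_post, df_t = s2, df
    se = np.sqrt(np.maximum(s2_post, 1e-300) * (1.0 / n1 + 1.0 / n2))
    t = log2fc / se
    if np.isfinite(df_t):
        p = 2 * stats.t.sf(np.abs(t), df_t)
    else:
        p = 2 * stats.norm.sf(np.abs(t))
    q = bh_adjust(p)
    sig = (q <= q_threshold) & (np.abs(log2fc) >= np.log2(fc_threshold))
    return np.where(~sig, 0, np.sign(log2fc)).astype(int)


def match_permutation_test(
    in_vitro: pd.DataFrame,
    labels: Sequence,
    in_vivo: StatePattern,
    case_level: str | None = None,
    q_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    max_exhaustive: int = 20_000,
    n_random: int = 5_000,
    seed: int | None = None,
    tail: Literal["greater", "two_sided"] = "greater",
) -> MatchScoreResult:
    """Permutation test of in vitro / in vivo pattern concordance.

    ``in_vitro`` is a log2 genes x samples matrix over the in vivo pattern's
    gene universe, ``labels`` its two-class sample labels.  The full
    DE-and-discretize chain is recomputed for every permuted labeling, since
    the class labels feed the differential-expression computation.  The
    p-value is one-sided for high concordance by default.
    """
    labels = np.asarray([str(l) for l in labels])
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size != 2:
        raise ValueError("in vitro design must have exactly two classes")
    if np.any(counts < 2):
        raise ValueError("need >= 2 samples per in vitro class")
    genes = list(in_vivo.genes)
    missing = [g for g in genes if g not in in_vitro.index]
    if missing:
        raise ValueError(f"in vitro matrix lacks genes {missing[:5]}...")
    x = in_vitro.loc[genes].to_numpy(dtype=float)
    if case_level is None:
        case_level = "case" if "case" in uniq else sorted(uniq)[1]
    vivo_codes = in_vivo.codes()

    def statistic(values: np.ndarray, lab: np.ndarray) -> float:
        mask = np.asarray(lab) == case_level
        codes = _two_group_states(values, mask, q_threshold, fc_threshold)
        return float(_score_codes(codes, vivo_codes).sum())

    perm = permutation_pvalue(
        x,
        labels,
        statistic,
        max_exhaustive=max_exhaustive,
        n_random=n_random,
        seed=seed,
        tail=tail,
    )
    observed_codes = _two_group_states(
        x, labels == case_level, q_threshold, fc_threshold
    )
    per_gene = pd.Series(_score_codes(observed_codes, vivo_codes), index=genes, name="score")
    return MatchScoreResult(score=perm.observed_statistic, per_gene=per_gene, permutation=perm)
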