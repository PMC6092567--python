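"""Expression preprocessing, moderated differential-expression calling, and
qPCR -dCt processing with group models.

The pipeline ingests probe-summarized expression matrices (background
correction of raw scanner files is out of scope).  Preprocessing follows the
standard microarray recipe: log2 transform, quantile normalization, and an
intensity filter keeping genes above log2(50) in at least two samples.
Differential expression uses per-gene linear models with batch adjustment and
empirical-Bayes moderated t-statistics; genes are called DE at q <= 0.2 and a
linear fold-change >= 1.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .stats_core import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionStudy",
    "DEResult",
    "collapse_probesets",
    "quantile_normalize",
    "preprocess_filter",
    "de_linear_model",
    "qpcr_delta_ct",
    "qpcr_group_model",
    "qpcr_cluster",
]

DEFAULT_INTENSITY_FLOOR = float(np.log2(50))
DEFAULT_Q_THRESHOLD = 0.2
DEFAULT_FC_THRESHOLD = 1.5


@dataclass
class ExpressionStudy:
    """A log2 gene x sample expression matrix with sample and gene annotations.

    ``samples`` is indexed by sample id and may carry group, batch, maturity,
    MAP (mmHg), BW / BW_percentile, and GA_weeks columns; ``genes`` is indexed
    by gene id and may carry chromosome, ``is_tf`` (transcription-regulator
    flag) and ``is_placenta_predominant`` columns plus any ground-truth
    annotations attached by the synthetic-data generators.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.matrix.columns) != list(self.samples.index):
            raise ValueError("matrix columns must equal the sample table index")
        if list(self.matrix.index) != list(self.genes.index):
            raise ValueError("matrix rows must equal the gene table index")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionStudy":
        gene_ids = list(gene_ids)
        return ExpressionStudy(
            matrix=self.matrix.loc[gene_ids],
            samples=self.samples,
            genes=self.genes.loc[gene_ids],
        )


@dataclass
class DEResult:
    """Per-gene differential-expression calls.

    ``table`` columns: log2fc, t, p, q, call (bool), direction (up/down/none).
    """

    table: pd.DataFrame
    q_threshold: float
    fc_threshold: float
    prior_df: float | None = None
    prior_var: float | None = None

    @property
    def de_genes(self) -> pd.Index:
        return self.table.index[self.table["call"]]


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def collapse_probesets(matrix: pd.DataFrame, probeset_map: dict[str, str]) -> pd.DataFrame:
    """Collapse a probeset x sample matrix to genes, keeping the probeset with
    the highest mean intensity per gene; unmapped probesets are dropped with a
    warning."""
    mapped = matrix.index.map(probeset_map.get)
    unmapped = mapped.isna()
    if unmapped.any():
        warnings.warn(f"dropping {int(unmapped.sum())} unmapped probesets")
        matrix = matrix.loc[~unmapped]
        mapped = mapped[~unmapped]
    means = matrix.mean(axis=1)
    keep = (
        pd.DataFrame({"gene": mapped, "mean": means, "probeset": matrix.index})
        .sort_values(["gene", "mean", "probeset"], ascending=[True, False, True])
        .drop_duplicates("gene")
    )
    out = matrix.loc[keep["probeset"]]
    out.index = keep["gene"].to_list()
    return out


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample shares the same distribution.

    Each column's sorted values are replaced by the mean of the sorted values
    across columns; ties within a column receive the mean of their target
    quantiles.  Within-column ranks are preserved exactly.
    """
    x = matrix.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=0)
    mean_quantiles = sorted_x.mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        # average target quantiles over tied input values
        col = x[:, j]
        ranks = stats.rankdata(col, method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        frac = ranks - lo
        out[:, j] = mean_quantiles[lo] * (1 - frac) + mean_quantiles[hi] * frac
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def preprocess_filter(
    raw: pd.DataFrame,
    intensity_floor: float = DEFAULT_INTENSITY_FLOOR,
    min_samples: int = 2,
    already_log2: bool = False,
    samples: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
    normalize: bool = True,
) -> ExpressionStudy:
    """log2-transform, quantile-normalize, and intensity-filter a raw matrix.

    Genes are retained when their normalized log2 intensity exceeds
    ``intensity_floor`` (default log2(50)) in at least ``min_samples`` samples.
    """
    if raw.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = raw.astype(float)
    if not already_log2:
        if (mat.to_numpy() < 0).any():
            raise ValueError("linear-scale input must be non-negative")
        mat = np.log2(mat + 1.0)
    if normalize:
        mat = quantile_normalize(mat)
    keep = (mat > intensity_floor).sum(axis=1) >= min_samples
    retained = mat.loc[keep]
    logger.info(
        "intensity filter retained %d of %d genes (floor %.3f in >= %d samples)",
        keep.sum(), len(keep), intensity_floor, min_samples,
    )
    if samples is None:
        samples = pd.DataFrame(index=raw.columns)
    if genes is None:
        genes = pd.DataFrame(index=raw.index)
    return ExpressionStudy(
        matrix=retained, samples=samples.loc[raw.columns], genes=genes.loc[retained.index]
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    # initial value: trigamma(x) ~ 1/x for large x, ~ 1/x^2 for small x
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x - dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-gene residual variances.

    Fits a scaled inverse chi-square prior to the observed variances by
    matching the moments of log(s2); returns the posterior variances together
    with the estimated prior degrees of freedom and prior variance.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if not np.any(pos):
        raise ValueError("all residual variances are zero")
    z = np.log(np.where(pos, s2, np.nan))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = np.nanmean(e)
    n_ok = np.sum(~np.isnan(e))
    if n_ok < 2:
        return s2.copy(), np.inf, float(np.exp(e_mean))
    e_var = float(np.nanvar(e, ddof=1))
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
        post = np.full_like(s2, s0_sq)
    return post, float(d0), s0_sq


def _build_design(samples: pd.DataFrame, terms: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept from sample-table columns.

    Categorical (object/category/bool) columns are dummy-coded dropping the
    first level; numeric columns enter as-is.
    """
    cols: list[np.ndarray] = [np.ones(len(samples))]
    names = ["intercept"]
    for term in terms:
        if term not in samples.columns:
            raise ValueError(f"design term {term!r} missing from sample table")
        col = samples[term]
        if col.isna().any():
            raise ValueError(f"design term {term!r} has missing values")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
            levels = sorted(pd.unique(col.astype(str)))
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(float))
                names.append(f"{term}[{lev}]")
        else:
            cols.append(col.to_numpy(float))
            names.append(term)
    X = np.column_stack(cols)
    return X, names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        bad = [
            names[j]
            for j in range(1, X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_gene_lm(
    matrix: pd.DataFrame,
    design: np.ndarray,
    coef_names: list[str],
    eb_shrink: bool = True,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-gene least squares with (optionally) moderated t-statistics.

    Returns a frame with columns ``coef_<name>``, ``t_<name>``, ``p_<name>``
    for every non-intercept coefficient, and the moderation hyperparameters.
    """
    Y = matrix.to_numpy(dtype=float)
    n, p = design.shape
    if n <= p:
        raise ValueError("more coefficients than samples")
    _check_full_rank(design, coef_names)
    xtx_inv = np.linalg.inv(design.T @ design)
    pin = xtx_inv @ design.T
    beta = Y @ pin.T  # genes x p
    resid = Y - beta @ design.T
    df_resid = n - p
    s2 = (resid**2).sum(axis=1) / df_resid

    if eb_shrink:
        s2_post, d0, s0_sq = squeeze_variances(s2, df_resid)
        df_total = df_resid + (d0 if np.isfinite(d0) else 0)
        df_t = df_resid + d0
    else:
        s2_post, d0, s0_sq = s2, 0.0, float("nan")
        df_t = df_resid

    out = {}
    for j, name in enumerate(coef_names):
        if name == "intercept":
            continue
        se = np.sqrt(np.maximum(s2_post, 1e-300) * xtx_inv[j, j])
        t = beta[:, j] / se
        if np.isfinite(df_t):
            pvals = 2 * stats.t.sf(np.abs(t), df_t)
        else:
            pvals = 2 * stats.norm.sf(np.abs(t))
        out[f"coef_{name}"] = beta[:, j]
        out[f"t_{name}"] = t
        out[f"p_{name}"] = pvals
    frame = pd.DataFrame(out, index=matrix.index)
    return frame, {"prior_df": float(d0), "prior_var": s0_sq, "df_resid": float(df_resid)}


def de_linear_model(
    study: ExpressionStudy,
    design: Sequence[str] = ("group", "batch"),
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    case_level: str | None = None,
    eb_shrink: bool = True,
) -> DEResult:
    """Moderated-t differential expression with batch adjustment.

    The first design term is the group factor whose coefficient is the log2
    fold-change (``case_level`` selects which level counts as case; default is
    the lexicographically later level, so ``case`` vs ``control`` works out of
    the box).  Genes are called DE when q <= ``q_threshold`` and the linear
    fold-change magnitude is at least ``fc_threshold``.
    """
    samples = study.samples.copy()
    group_term = design[0]
    levels = sorted(pd.unique(samples[group_term].astype(str)))
    if len(levels) != 2:
        raise ValueError(f"group factor {group_term!r} must have exactly 2 levels")
    if case_level is None:
        case_level = "case" if "case" in levels else levels[1]
    # re-code so the dummy column is the case indicator
    samples[group_term] = np.where(
        samples[group_term].astype(str) == case_level, f"z_{case_level}", "a_ref"
    )
    X, names = _build_design(samples, design)
    frame, hyper = fit_gene_lm(study.matrix, X, names, eb_shrink=eb_shrink)
    coef_col = f"coef_{group_term}[z_{case_level}]"
    t_col = f"t_{group_term}[z_{case_level}]"
    p_col = f"p_{group_term}[z_{case_level}]"
    log2fc = frame[coef_col]
    pvals = frame[p_col]
    qvals = bh_adjust(pvals.to_numpy())
    call = (qvals <= q_threshold) & (np.abs(log2fc) >= np.log2(fc_threshold))
    direction = np.where(~call, "none", np.where(log2fc > 0, "up", "down"))
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": frame[t_col],
            "p": pvals,
            "q": qvals,
            "call": call,
            "direction": direction,
        },
        index=study.matrix.index,
    )
    return DEResult(
        table=table,
        q_threshold=q_threshold,
        fc_threshold=fc_threshold,
        prior_df=hyper["prior_df"],
        prior_var=hyper["prior_var"],
    )


# ---------------------------------------------------------------------------
# qPCR -dCt processing
# ---------------------------------------------------------------------------


def qpcr_delta_ct(
    ct_table: pd.DataFrame,
    reference_gene: str = "RPLP0",
    batches: pd.Series | None = None,
    calibrators: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Reference-normalized log2 relative expression: -dCt = Ct(ref) - Ct(gene).

    ``ct_table`` is genes x samples of raw Ct values and must contain the
    reference gene.  Samples with a missing reference Ct are dropped with a
    warning.  When ``batches`` (sample -> batch) and ``calibrators`` (sample
    ids measured in every batch) are given, a per-batch, per-gene additive
    offset is removed so calibrator samples share the same -dCt across
    batches.
    """
    if reference_gene not in ct_table.index:
        raise ValueError(f"reference gene {reference_gene!r} not in Ct table")
    ref = ct_table.loc[reference_gene]
    missing = ref.index[ref.isna()]
    if len(missing) > 0:
        warnings.warn(f"dropping samples with missing reference Ct: {list(missing)}")
        ct_table = ct_table.drop(columns=missing)
        ref = ref.drop(index=missing)
    neg_dct = ref - ct_table.drop(index=reference_gene)

    if batches is not None and calibrators is not None:
        cal = [s for s in calibrators if s in neg_dct.columns]
        if not cal:
            raise ValueError("no calibrator samples present in the Ct table")
        batches = batches.loc[neg_dct.columns]
        cal_mean = neg_dct[cal].mean(axis=1)  # per-gene grand calibrator mean
        for batch in pd.unique(batches):
            in_batch = batches.index[batches == batch]
            cal_b = [s for s in cal if s in set(in_batch)]
            if not cal_b:
                warnings.warn(f"batch {batch!r} has no calibrator; left unadjusted")
                continue
            offset = neg_dct[cal_b].mean(axis=1) - cal_mean
            neg_dct.loc[:, in_batch] = neg_dct.loc[:, in_batch].sub(offset, axis=0)
    return neg_dct


def qpcr_group_model(
    neg_dct: pd.DataFrame, group: pd.Series, maturity: pd.Series
) -> pd.DataFrame:
    """Per-gene linear model ``-dCt ~ group * maturity``.

    Returns per-gene group effects within each maturity stratum and the
    group-by-maturity interaction with their p-values.  Group and maturity are
    coded so the later-sorted level is the indicator (``case`` / ``preterm``
    conventions sort conveniently to 1 with ``case`` > ``control`` reversed,
    so the coding is reported in the column names).
    """
    samples = neg_dct.columns
    g = group.loc[samples].astype(str)
    m = maturity.loc[samples].astype(str)
    g_levels = sorted(g.unique())
    m_levels = sorted(m.unique())
    if len(g_levels) != 2 or len(m_levels) != 2:
        raise ValueError("group and maturity must each have exactly 2 levels")
    g1, m1 = g_levels[1], m_levels[1]
    for lev, ser, nm in ((g_levels[0], g, "group"), (g_levels[1], g, "group"),
                         (m_levels[0], m, "maturity"), (m_levels[1], m, "maturity")):
        if (ser == lev).sum() == 0:
            raise ValueError(f"empty {nm} stratum {lev!r}")
    gi = (g == g1).to_numpy(float)
    mi = (m == m1).to_numpy(float)
    for stratum, mask in ((m_levels[0], mi == 0), (m_levels[1], mi == 1)):
        if len(np.unique(gi[mask])) < 2:
            raise ValueError(f"maturity stratum {stratum!r} lacks both groups")
    X = np.column_stack([np.ones(len(samples)), gi, mi, gi * mi])
    names = ["intercept", "group", "maturity", "interaction"]
    _check_full_rank(X, names)
    Y = neg_dct.to_numpy(dtype=float)
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ (xtx_inv @ X.T).T
    resid = Y - beta @ X.T
    df = n - p
    s2 = (resid**2).sum(axis=1) / df

    def _tp(contrast: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        est = beta @ contrast
        se = np.sqrt(s2 * (contrast @ xtx_inv @ contrast))
        t = est / se
        return est, t, 2 * stats.t.sf(np.abs(t), df)

    eff0, t0, p0 = _tp(np.array([0.0, 1.0, 0.0, 0.0]))  # group effect, reference stratum
    eff1, t1, p1 = _tp(np.array([0.0, 1.0, 0.0, 1.0]))  # group effect, indicator stratum
    effi, ti, pi = _tp(np.array([0.0, 0.0, 0.0, 1.0]))  # interaction
    return pd.DataFrame(
        {
            f"group_effect[{m_levels[0]}]": eff0,
            f"group_p[{m_levels[0]}]": p0,
            f"group_effect[{m1}]": eff1,
            f"group_p[{m1}]": p1,
            "interaction_effect": effi,
            "interaction_p": pi,
        },
        index=neg_dct.index,
    )


def qpcr_cluster(neg_dct: pd.DataFrame) -> np.ndarray:
    """Average-linkage hierarchical clustering of samples on 1 - Pearson distance."""
    corr = np.corrcoef(neg_dct.to_numpy(dtype=float).T)
    dist = squareform(1.0 - corr, checks=False)
    return linkage(dist, method="average")
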