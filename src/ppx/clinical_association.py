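"""Gene-clinical-trait association models and the placental histology score.

Per-gene multiple regressions link expression to continuous maternal (mean
arterial pressure, mmHg) and fetal (birthweight) traits with batch
adjustment, moderated t-statistics, and BH q-values per trait (significance
at q <= 0.2).  The maternal vascular malperfusion score is the plain count of
histologic lesions in that category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression_modules import ModuleAssignment, module_enrichment
from .diffexpr import ExpressionStudy, _build_design, fit_gene_lm
from .stats_core import EnrichmentResult, bh_adjust

__all__ = [
    "TraitAssociation",
    "malperfusion_score",
    "gene_trait_model",
    "module_trait_enrichment",
    "gene_histology_assoc",
]

DEFAULT_Q_THRESHOLD = 0.2


@dataclass
class TraitAssociation:
    """Per-gene, per-trait coefficients with moderated t, p, q and call flag.

    ``table`` has a row per gene and, per trait, columns ``coef_<trait>``,
    ``t_<trait>``, ``p_<trait>``, ``q_<trait>``, ``sig_<trait>``.
    """

    table: pd.DataFrame
    traits: tuple[str, ...]
    q_threshold: float

    def significant(self, trait: str) -> pd.Index:
        return self.table.index[self.table[f"sig_{trait}"]]


def malperfusion_score(lesion_flags: Sequence[int]) -> int:
    """Maternal vascular malperfusion score: the number of lesions present."""
    flags = np.asarray(lesion_flags)
    if flags.size == 0:
        return 0
    if not np.isin(flags, (0, 1)).all():
        raise ValueError("lesion flags must be binary 0/1")
    return int(flags.sum())


def gene_trait_model(
    study: ExpressionStudy,
    traits: Sequence[str] = ("MAP", "BW_percentile"),
    adjust: Sequence[str] = ("batch",),
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    eb_shrink: bool = True,
) -> TraitAssociation:
    """Per-gene linear model ``y ~ trait_1 + ... + adjust terms``.

    All traits enter one joint regression (e.g. y ~ MAP + BW + Batch); each
    trait coefficient gets a moderated t, a p-value and a BH q across genes.
    """
    for trait in traits:
        col = study.samples[trait]
        if col.nunique() < 2:
            raise ValueError(f"trait {trait!r} is constant")
    X, names = _build_design(study.samples, list(traits) + list(adjust))
    frame, _ = fit_gene_lm(study.matrix, X, names, eb_shrink=eb_shrink)
    out = {}
    for trait in traits:
        pvals = frame[f"p_{trait}"].to_numpy()
        qvals = bh_adjust(pvals)
        out[f"coef_{trait}"] = frame[f"coef_{trait}"]
        out[f"t_{trait}"] = frame[f"t_{trait}"]
        out[f"p_{trait}"] = pvals
        out[f"q_{trait}"] = qvals
        out[f"sig_{trait}"] = qvals <= q_threshold
    return TraitAssociation(
        table=pd.DataFrame(out, index=study.matrix.index),
        traits=tuple(traits),
        q_threshold=q_threshold,
    )


def module_trait_enrichment(
    modules: ModuleAssignment, associations: TraitAssociation, trait: str
) -> dict[str, EnrichmentResult]:
    """Fisher enrichment of trait-significant genes within each module."""
    sig = associations.table[f"sig_{trait}"]
    if not sig.any():
        warnings.warn(f"no genes significant for {trait!r}; odds ratios undefined")
    return module_enrichment(modules, sig)


def gene_histology_assoc(
    neg_dct: pd.DataFrame, scores: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Simple per-gene regression of qPCR expression on the malperfusion score.

    Returns slope, r-squared, p, and a p < alpha flag per gene.
    """
    samples = neg_dct.columns
    s = scores.loc[samples].to_numpy(dtype=float)
    if np.ptp(s) == 0:
        raise ValueError("malperfusion score is constant across samples")
    rows = {}
    for gene, y in neg_dct.iterrows():
        res = stats.linregress(s, y.to_numpy(dtype=float))
        rows[gene] = {
            "slope": res.slope,
            "r_squared": res.rvalue**2,
            "p": res.pvalue,
            "significant": res.pvalue < alpha,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
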