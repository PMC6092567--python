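"""Predominantly tissue-specific gene calling and the liquid-biopsy
enrichment score.

A gene is called predominantly expressed in the target tissue (here: the
placenta, against 78 other tissues, cells, and cell lines) when its target
expression (1) reaches an absolute fluorescence floor, (2) is at least
``fold_median`` times the median of the other tissues, and (3) is at least
``fold_second`` times the highest other tissue.  The enrichment score divides
target expression by the mean of all non-target tissues.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TissueAtlas",
    "SpecificityCall",
    "call_predominant",
    "collapse_to_genes",
    "enrichment_score",
]


@dataclass
class TissueAtlas:
    """Linear-scale gene (or probeset) x tissue expression matrix.

    ``target_tissue`` must be one of the matrix columns.  ``probeset_map``
    optionally maps probeset ids (matrix rows) to gene symbols.
    """

    matrix: pd.DataFrame
    target_tissue: str
    probeset_map: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.target_tissue not in self.matrix.columns:
            raise ValueError(f"target tissue {self.target_tissue!r} not in atlas")
        if (self.matrix.to_numpy() < 0).any():
            raise ValueError("atlas values must be non-negative (linear scale)")
        if self.matrix.shape[1] < 2:
            raise ValueError("atlas needs at least 2 tissues")

    @property
    def other_tissues(self) -> list[str]:
        return [t for t in self.matrix.columns if t != self.target_tissue]


@dataclass(frozen=True)
class SpecificityCall:
    """Three-rule predominance diagnostics for one gene."""

    gene: str
    passes: bool
    level: float
    fold_over_median: float
    fold_over_second: float


def call_predominant(
    atlas: TissueAtlas,
    min_level: float = 1000.0,
    fold_median: float = 6.0,
    fold_second: float = 2.0,
) -> list[SpecificityCall]:
    """Apply the three predominance rules to every gene in the atlas.

    A gene passes iff target >= min_level AND target >= fold_median x
    median(other tissues) AND target >= fold_second x max(other tissues);
    ties at a threshold pass (>= semantics).
    """
    target = atlas.matrix[atlas.target_tissue].to_numpy(dtype=float)
    others = atlas.matrix[atlas.other_tissues].to_numpy(dtype=float)
    med = np.median(others, axis=1)
    second = others.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold_med = np.where(med > 0, target / med, np.inf)
        fold_sec = np.where(second > 0, target / second, np.inf)
    passes = (target >= min_level) & (fold_med >= fold_median) & (fold_sec >= fold_second)
    return [
        SpecificityCall(
            gene=g,
            passes=bool(passes[i]),
            level=float(target[i]),
            fold_over_median=float(fold_med[i]),
            fold_over_second=float(fold_sec[i]),
        )
        for i, g in enumerate(atlas.matrix.index)
    ]


def collapse_to_genes(
    calls: Sequence[SpecificityCall], probeset_map: Mapping[str, str]
) -> list[SpecificityCall]:
    """Collapse probeset-level calls to genes: a gene passes iff any of its
    probesets passes.  Unmapped probesets are excluded with a warning.

    The diagnostics of the best-passing probeset (highest level among passing
    ones, else highest level overall) represent the gene.
    """
    by_gene: dict[str, list[SpecificityCall]] = {}
    unmapped = []
    for call in calls:
        gene = probeset_map.get(call.gene)
        if gene is None:
            unmapped.append(call.gene)
            continue
        by_gene.setdefault(gene, []).append(call)
    if unmapped:
        warnings.warn(f"excluding {len(unmapped)} unmapped probesets: {unmapped[:5]}...")
        logger.warning("excluded %d unmapped probesets", len(unmapped))
    out = []
    for gene, gene_calls in by_gene.items():
        passing = [c for c in gene_calls if c.passes]
        best = max(passing or gene_calls, key=lambda c: c.level)
        out.append(
            SpecificityCall(
                gene=gene,
                passes=bool(passing),
                level=best.level,
                fold_over_median=best.fold_over_median,
                fold_over_second=best.fold_over_second,
            )
        )
    return out


def enrichment_score(atlas: TissueAtlas, gene: str) -> float:
    """Target-tissue expression divided by the mean over all other tissues."""
    if gene not in atlas.matrix.index:
        raise KeyError(f"gene {gene!r} not in atlas")
    row = atlas.matrix.loc[gene]
    target = float(row[atlas.target_tissue])
    mean_others = float(row[atlas.other_tissues].mean())
    if mean_others == 0:
        warnings.warn(f"gene {gene!r}: all non-target tissues are zero; score is +inf")
        return math.inf
    return target / mean_others
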