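"""Weighted co-expression network construction, module detection, hub
selection, and module enrichment.

Network construction follows the weighted-network recipe: the similarity
``s_ij = |Pearson(i, j)|`` is soft-thresholded to an adjacency
``a_ij = s_ij ** beta`` (beta = 10 by default, chosen on the scale-free
topology criterion), from which the topological overlap matrix

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

is derived (TOM diagonal set to 1 by convention).  Modules are branches of
the average-linkage dendrogram on 1 - TOM found with a re-implemented hybrid
dynamic tree cut: branches are cut adaptively from the dendrogram, branches
smaller than ``min_module_size`` stay unassigned, candidate branches must be
tighter (on the beta-independent |r| scale) than their surroundings, and a
final medoid-style (PAM-like) pass assigns left-over genes to the nearest
module when they fall within its topological-overlap radius.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .diffexpr import ExpressionStudy
from .stats_core import ContingencyTable2x2, EnrichmentResult, bh_adjust, fisher_exact_2x2

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkMatrices",
    "ModuleAssignment",
    "HubReport",
    "build_network",
    "detect_modules",
    "hub_candidates",
    "module_enrichment",
    "scale_free_fit",
]

UNASSIGNED = "unassigned"

# deep_split (0..3) -> fraction of the dendrogram height range used as the
# static cut; deeper splits cut lower and accept looser branches
_CUT_FRACTION = {0: 0.99, 1: 0.97, 2: 0.95, 3: 0.92}


@dataclass
class NetworkMatrices:
    """Similarity, soft-thresholded adjacency, connectivity, and TOM."""

    similarity: pd.DataFrame  # |Pearson|
    adjacency: pd.DataFrame  # similarity ** beta, zero diagonal
    connectivity: pd.Series  # k_i = sum_j a_ij
    tom: pd.DataFrame  # topological overlap, unit diagonal
    beta: float

    @property
    def genes(self) -> pd.Index:
        return self.similarity.index


@dataclass
class ModuleAssignment:
    """Gene -> module labels plus the dendrogram they were cut from."""

    labels: pd.Series  # gene id -> module label ("M1", ..., "unassigned")
    dendrogram: np.ndarray  # scipy linkage matrix
    min_module_size: int
    deep_split: int

    @property
    def module_names(self) -> list[str]:
        names = [m for m in pd.unique(self.labels) if m != UNASSIGNED]
        return sorted(names, key=lambda m: (-int((self.labels == m).sum()), m))

    def members(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]


@dataclass
class HubReport:
    """Ranked hub-candidate table.

    Columns: gene, module, mean_intensity, partner_count, partner_strength,
    is_tf, rank (1 = best within module).
    """

    table: pd.DataFrame
    intensity_min: float
    cor_min: float


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------


def tom_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap from a symmetric adjacency with zero diagonal."""
    a = np.asarray(adjacency, dtype=float)
    k = a.sum(axis=1)
    shared = a @ a  # zero diagonal removes the u = i, u = j terms
    min_k = np.minimum.outer(k, k)
    tom = (shared + a) / (min_k + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


def build_network(study: ExpressionStudy | pd.DataFrame, beta: float = 10.0) -> NetworkMatrices:
    """Similarity, soft-thresholded adjacency, connectivity, and TOM for the
    genes of ``study`` (typically restricted to the DE genes)."""
    matrix = study.matrix if isinstance(study, ExpressionStudy) else study
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant genes; their correlations are set to 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr[np.isnan(corr)] = 0.0
    s = np.abs(corr)
    np.fill_diagonal(s, 1.0)
    a = s**beta
    np.fill_diagonal(a, 0.0)
    tom = tom_from_adjacency(a)
    genes = matrix.index
    return NetworkMatrices(
        similarity=pd.DataFrame(s, index=genes, columns=genes),
        adjacency=pd.DataFrame(a, index=genes, columns=genes),
        connectivity=pd.Series(a.sum(axis=1), index=genes, name="k"),
        tom=pd.DataFrame(tom, index=genes, columns=genes),
        beta=beta,
    )


def scale_free_fit(connectivity: np.ndarray | pd.Series, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index, the criterion used to choose the
    soft power.

    The connectivities are binned (equal width), and log10 frequency is
    regressed on log10 mean connectivity per bin.  The index is
    ``-sign(slope) * R^2``: a network is scale-free-like only when the degree
    distribution both fits a power law and *decreases* with connectivity, so
    an increasing distribution scores negatively.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        raise ValueError("too few positive connectivities")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] += 1e-9
    centers, freqs = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (k >= lo) & (k < hi)
        if mask.sum() == 0:
            continue
        centers.append(k[mask].mean())
        freqs.append(mask.mean())
    logk = np.log10(np.asarray(centers))
    logp = np.log10(np.asarray(freqs))
    slope = np.polyfit(logk, logp, 1)[0]
    r = np.corrcoef(logk, logp)[0, 1]
    return float(-np.sign(slope) * r**2)


# ---------------------------------------------------------------------------
# Module detection (hybrid dynamic tree cut, re-implemented)
# ---------------------------------------------------------------------------


def _validate_clusters(
    labels: np.ndarray,
    similarity: np.ndarray,
    min_separation: float,
    min_within: float,
    min_reference: int,
) -> set[int]:
    """Keep clusters whose mean within-similarity clearly exceeds the mean
    similarity to their surroundings.

    The reference is the cluster's complement when that complement is large
    enough to be representative (at least ``min_reference`` genes); for a
    near-complete cluster the network-wide background substitutes, so a
    cluster of noise genes cannot validate itself against a few stray leaves.
    A cluster covering the whole network must clear the absolute
    ``min_within`` floor.  Validation runs on the |r| similarity scale so it
    is independent of the soft power.
    """
    valid: set[int] = set()
    n = labels.size
    off_diag = ~np.eye(n, dtype=bool)
    overall = similarity[off_diag].mean()
    for lab in np.unique(labels):
        idx = labels == lab
        size = int(idx.sum())
        if size < 2:
            continue
        block = similarity[np.ix_(idx, idx)]
        within = block[off_diag[np.ix_(idx, idx)]].mean()
        if size == n:
            if within >= min_within:
                valid.add(int(lab))
            continue
        between = similarity[np.ix_(idx, ~idx)].mean()
        background = between if (n - size) >= min_reference else max(between, overall)
        if within - background >= min_separation:
            valid.add(int(lab))
    return valid


def detect_modules(
    network: NetworkMatrices,
    min_module_size: int = 30,
    deep_split: int = 2,
    pam: bool = True,
    min_separation: float = 0.1,
    min_within: float = 0.3,
) -> ModuleAssignment:
    """Cut the average-linkage dendrogram on 1 - TOM into modules.

    Branches are formed by a static cut at a ``deep_split``-dependent fraction
    of the dendrogram height range; branches below ``min_module_size`` or
    failing the tightness validation stay unassigned.  With ``pam`` enabled,
    unassigned genes are subsequently attached to the module with the highest
    mean topological overlap, provided they fall within that module's TOM
    radius (the lower decile of the members' own mean intra-module overlap).

    Module labels are "M1", "M2", ... in order of decreasing size; genes in no
    module carry the label "unassigned".
    """
    if deep_split not in _CUT_FRACTION:
        raise ValueError("deep_split must be one of 0, 1, 2, 3")
    genes = network.genes
    tom = network.tom.to_numpy(dtype=float)
    sim = network.similarity.to_numpy(dtype=float)
    dist = 1.0 - tom
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    heights = Z[:, 2]

    if np.ptp(condensed) < 1e-12:
        warnings.warn("all pairwise distances equal; returning a single module")
        labels = pd.Series(["M1"] * len(genes), index=genes, name="module")
        return ModuleAssignment(labels, Z, min_module_size, deep_split)

    h_min, h_max = float(heights.min()), float(heights.max())
    cut = h_min + _CUT_FRACTION[deep_split] * (h_max - h_min)
    raw = fcluster(Z, t=cut, criterion="distance")

    # size filter, then tightness validation on the |r| scale
    sizes = pd.Series(raw).value_counts()
    big = {int(lab) for lab, n in sizes.items() if n >= min_module_size}
    candidate = np.where(np.isin(raw, list(big)), raw, 0)
    valid = _validate_clusters(raw, sim, min_separation, min_within, min_module_size) & big
    labels_num = np.where(np.isin(raw, list(valid)), raw, 0)

    if pam and valid:
        assigned = labels_num != 0
        radii: dict[int, float] = {}
        for lab in valid:
            idx = labels_num == lab
            block = tom[np.ix_(idx, idx)]
            member_means = (block.sum(axis=1) - 1.0) / (idx.sum() - 1)
            radii[lab] = float(np.quantile(member_means, 0.1))
        for i in np.flatnonzero(~assigned):
            best_lab, best_mean = 0, -np.inf
            for lab in valid:
                idx = labels_num == lab
                mean_tom = tom[i, idx].mean()
                if mean_tom > best_mean:
                    best_lab, best_mean = lab, mean_tom
            if best_lab and best_mean >= radii[best_lab]:
                labels_num[i] = best_lab

    # rename by decreasing size, deterministic tie-break on first gene index
    final = np.full(len(genes), UNASSIGNED, dtype=object)
    kept = [int(lab) for lab in np.unique(labels_num) if lab != 0]
    kept.sort(key=lambda lab: (-(labels_num == lab).sum(), int(np.argmax(labels_num == lab))))
    for rank, lab in enumerate(kept, start=1):
        final[labels_num == lab] = f"M{rank}"
    n_unassigned = int((final == UNASSIGNED).sum())
    logger.info(
        "detected %d modules; %d of %d genes unassigned", len(kept), n_unassigned, len(genes)
    )
    labels = pd.Series(final, index=genes, name="module")
    return ModuleAssignment(labels, Z, min_module_size, deep_split)


# ---------------------------------------------------------------------------
# Hub candidates
# ---------------------------------------------------------------------------


def hub_candidates(
    study: ExpressionStudy,
    modules: ModuleAssignment,
    intensity_min: float = 9.0,
    cor_min: float = 0.7,
    restrict_to: Sequence[str] | None = None,
    partner_set: Sequence[str] | None = None,
) -> HubReport:
    """Rank hub transcription-regulator candidates within each module.

    Candidates must carry the transcription-regulator flag (or belong to
    ``restrict_to``), have mean log2 intensity above ``intensity_min``, and
    are ranked within their module by the number of ``partner_set`` genes
    (default: all genes in the study) with which they are co-expressed at
    |Pearson| > ``cor_min``; ties break on summed |r| over qualifying
    partners, then on gene id.
    """
    if restrict_to is None:
        if "is_tf" not in study.genes.columns:
            raise ValueError("no transcription-regulator flag and no restrict_to set")
        restrict_to = list(study.genes.index[study.genes["is_tf"].astype(bool)])
    restrict_to = [g for g in restrict_to if g in study.matrix.index]
    if partner_set is None:
        partner_set = list(study.matrix.index)
    partner_set = [g for g in partner_set if g in study.matrix.index]
    if not partner_set:
        raise ValueError("empty partner set")

    mean_intensity = study.matrix.mean(axis=1)
    x = study.matrix.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(study.matrix.index)}
    partner_idx = np.array([gene_pos[g] for g in partner_set])
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x)
    corr[np.isnan(corr)] = 0.0

    rows = []
    for gene in restrict_to:
        if mean_intensity[gene] <= intensity_min:
            continue
        i = gene_pos[gene]
        r = np.abs(corr[i, partner_idx])
        qualifying = (r > cor_min) & (partner_idx != i)
        rows.append(
            {
                "gene": gene,
                "module": modules.labels.get(gene, UNASSIGNED),
                "mean_intensity": float(mean_intensity[gene]),
                "partner_count": int(qualifying.sum()),
                "partner_strength": float(r[qualifying].sum()),
                "is_tf": True,
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene", "module", "mean_intensity", "partner_count",
                       "partner_strength", "is_tf"],
    )
    if len(table):
        table = table.sort_values(
            ["module", "partner_count", "partner_strength", "gene"],
            ascending=[True, False, False, True],
        ).reset_index(drop=True)
        table["rank"] = table.groupby("module").cumcount() + 1
    else:
        table["rank"] = pd.Series(dtype=int)
    return HubReport(table=table, intensity_min=intensity_min, cor_min=cor_min)


# ---------------------------------------------------------------------------
# Module enrichment
# ---------------------------------------------------------------------------


def module_enrichment(
    modules: ModuleAssignment,
    gene_property: pd.Series,
    background: Sequence[str] | None = None,
) -> dict[str, EnrichmentResult]:
    """Fisher 2x2 enrichment of a binary gene property in each module.

    ``background`` defaults to all genes carrying a module assignment record
    (assigned or not).  When more than one module is tested, BH q-values are
    attached across modules.
    """
    if background is None:
        background = list(modules.labels.index)
    background = [g for g in background if g in gene_property.index]
    prop = gene_property.loc[background].astype(bool)
    results: dict[str, EnrichmentResult] = {}
    for module in modules.module_names:
        members = set(modules.members(module)) & set(background)
        if not members:
            warnings.warn(f"module {module} empty within background; skipped")
            continue
        in_mod = prop.index.isin(members)
        a = int((prop & in_mod).sum())
        b = int((~prop & in_mod).sum())
        c = int((prop & ~in_mod).sum())
        d = int((~prop & ~in_mod).sum())
        results[module] = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
    if len(results) > 1:
        names = list(results)
        qvals = bh_adjust([results[m].p_value for m in names])
        for name, q in zip(names, qvals):
            r = results[name]
            results[name] = EnrichmentResult(
                odds_ratio=r.odds_ratio, p_value=r.p_value, table=r.table, q_value=float(q)
            )
    return results
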