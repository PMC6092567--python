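"""Seeded generators for every input the pipeline consumes, with planted
ground truth for parameter-recovery testing.

The generators emulate the statistical structure of a two-condition placental
expression study (about a dozen preterm preeclampsia cases against five
gestational-age-matched controls), a 79-tissue expression atlas with a known
number of placenta-predominant genes, a literature-style percent-of-control
biomarker database linear in gestational age, and targeted bisulfite CpG
count tables with planted group methylation differences.

Module co-expression signal model: each planted module has a single latent
eigen-signal across samples; member genes load on it with uniform(0.5, 1)
loadings and per-gene noise calibrated so the expected pairwise within-module
correlation equals ``within_correlation``.  Batch effects are additive,
gene-independent per-batch offsets, matching the linear-model batch
adjustment downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import ExpressionStudy
from .tissue_specificity import TissueAtlas, call_predominant

__all__ = [
    "ModuleSpec",
    "StudySpec",
    "AtlasSpec",
    "make_study",
    "make_atlas",
    "make_biomarker_db",
    "MethylationTruth",
    "make_methylation_counts",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    ``group_shift`` moves the module eigen-signal between cases and controls
    (in raw eigen units, before standardization) so module genes are also
    differentially expressed, as the discovery modules were.
    """

    size: int
    within_correlation: float = 0.8
    trait_link: Literal["MAP", "BW", "none"] = "none"
    direction: Literal["up", "down"] = "up"
    group_shift: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.within_correlation < 1.0):
            raise ValueError("within_correlation must lie in (0, 1)")
        if self.size < 2:
            raise ValueError("module size must be >= 2")


@dataclass(frozen=True)
class StudySpec:
    """Study design for the synthetic two-condition expression experiment.

    Defaults mirror the discovery design: 12 cases vs 5 controls, two planted
    modules whose eigen-signals track mean arterial pressure and birthweight.
    """

    n_cases: int = 12
    n_controls: int = 5
    n_genes: int = 500
    module_specs: tuple[ModuleSpec, ...] = (
        ModuleSpec(size=50, within_correlation=0.8, trait_link="MAP", direction="up"),
        ModuleSpec(size=50, within_correlation=0.8, trait_link="BW", direction="down"),
    )
    batch_levels: int = 2
    noise_sd: float = 0.2  # log2 units, background measurement noise
    seed: int = 0
    n_de_genes: int = 0  # extra genes with a planted case/control shift
    de_log2fc: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    batch_sd: float = 0.3
    signal_scale: float = 1.0  # log2 units per eigen-signal standard deviation
    trait_correlation: float = 0.8
    tf_fraction: float = 0.1

    def __post_init__(self) -> None:
        if sum(m.size for m in self.module_specs) + self.n_de_genes > self.n_genes:
            raise ValueError("module sizes plus planted DE genes exceed n_genes")
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 samples per group")
        if self.batch_levels < 1:
            raise ValueError("batch_levels must be >= 1")


@dataclass(frozen=True)
class AtlasSpec:
    """Design of the synthetic tissue atlas (linear fluorescence units)."""

    n_genes: int = 200
    n_tissues: int = 79
    n_target_specific: int = 20
    specific_level: float = 3000.0
    background_level: float = 100.0
    seed: int = 0
    target_tissue: str = "placenta"

    def __post_init__(self) -> None:
        if self.n_target_specific > self.n_genes:
            raise ValueError("n_target_specific exceeds n_genes")
        if self.n_tissues < 2:
            raise ValueError("need at least 2 tissues")
        if self.specific_level < 1000.0:
            raise ValueError(
                "specific_level below the 1,000-unit rule: constructed positives "
                "would violate the absolute-level rule"
            )
        if self.background_level <= 0:
            raise ValueError("background_level must be positive")


def make_study(spec: StudySpec) -> ExpressionStudy:
    """Generate a log2 expression study with planted modules, batch effects,
    optional planted DE genes, and trait covariates.

    Ground truth is attached to the gene table (``true_module``, ``true_de``)
    and the trait construction guarantees that trait-linked module
    eigen-signals correlate with the trait at ``spec.trait_correlation`` in
    expectation.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_cases + spec.n_controls
    sample_ids = [f"S{i+1:02d}" for i in range(n_samples)]
    gene_ids = [f"G{i+1:04d}" for i in range(spec.n_genes)]
    group = np.array(["case"] * spec.n_cases + ["control"] * spec.n_controls)
    batch = np.array([f"b{(i % spec.batch_levels) + 1}" for i in range(n_samples)])
    ga_weeks = np.clip(rng.normal(32.0, 2.5, size=n_samples), 26.0, 37.0)

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    matrix = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samples))

    true_module = np.full(spec.n_genes, UNASSIGNED, dtype=object)
    true_de = np.zeros(spec.n_genes, dtype=bool)

    # planted modules
    eigen_signals: dict[int, np.ndarray] = {}
    cursor = 0
    case_indicator = (group == "case").astype(float)
    for m_idx, mod in enumerate(spec.module_specs):
        e = rng.standard_normal(n_samples)
        e = e + mod.group_shift * (case_indicator - case_indicator.mean())
        e = (e - e.mean()) / e.std()
        eigen_signals[m_idx] = e
        sign = 1.0 if mod.direction == "up" else -1.0
        idx = np.arange(cursor, cursor + mod.size)
        cursor += mod.size
        loadings = rng.uniform(0.5, 1.0, size=mod.size) * spec.signal_scale
        resid_sd = loadings * np.sqrt((1.0 - mod.within_correlation) / mod.within_correlation)
        signal = sign * loadings[:, None] * e[None, :]
        noise = rng.standard_normal((mod.size, n_samples)) * resid_sd[:, None]
        matrix[idx] = baseline[idx, None] + signal + noise
        true_module[idx] = f"M{m_idx + 1}"

    # planted case/control DE genes outside the modules
    de_idx = np.arange(cursor, cursor + spec.n_de_genes)
    cursor += spec.n_de_genes
    if spec.n_de_genes:
        matrix[de_idx] += spec.de_log2fc * (group == "case")[None, :]
        true_de[de_idx] = True

    # additive gene-independent batch offsets
    offsets = rng.normal(0.0, spec.batch_sd, size=spec.batch_levels)
    for k in range(spec.batch_levels):
        matrix[:, batch == f"b{k+1}"] += offsets[k]

    # traits: linked to module eigen-signals where requested
    r = spec.trait_correlation
    map_latent = rng.standard_normal(n_samples)
    bw_latent = rng.standard_normal(n_samples)
    for m_idx, mod in enumerate(spec.module_specs):
        e = eigen_signals[m_idx]
        mix = r * e + np.sqrt(1 - r**2) * rng.standard_normal(n_samples)
        if mod.trait_link == "MAP":
            map_latent = mix
        elif mod.trait_link == "BW":
            bw_latent = mix
    map_mmhg = 100.0 + 15.0 * map_latent
    bw_percentile = 100.0 * stats.norm.cdf(bw_latent)

    samples = pd.DataFrame(
        {
            "group": group,
            "batch": batch,
            "maturity": np.where(ga_weeks < 37.0, "preterm", "term"),
            "MAP": map_mmhg,
            "BW_percentile": bw_percentile,
            "GA_weeks": ga_weeks,
        },
        index=sample_ids,
    )
    is_tf = rng.random(spec.n_genes) < spec.tf_fraction
    genes = pd.DataFrame(
        {
            "chromosome": rng.choice([f"chr{i}" for i in range(1, 23)], size=spec.n_genes),
            "is_tf": is_tf,
            "is_placenta_predominant": rng.random(spec.n_genes) < 0.02,
            "true_module": true_module,
            "true_de": true_de,
        },
        index=gene_ids,
    )
    mat = pd.DataFrame(matrix, index=gene_ids, columns=sample_ids)
    return ExpressionStudy(matrix=mat, samples=samples, genes=genes)


def make_atlas(spec: AtlasSpec) -> TissueAtlas:
    """Generate a tissue atlas in which exactly ``n_target_specific`` genes
    satisfy all three predominance rules by construction."""
    rng = np.random.default_rng(spec.seed)
    tissues = [spec.target_tissue] + [f"tissue_{i:02d}" for i in range(1, spec.n_tissues)]
    gene_ids = [f"AG{i+1:04d}" for i in range(spec.n_genes)]
    log_bg = np.log(spec.background_level)
    values = rng.lognormal(mean=log_bg, sigma=0.5, size=(spec.n_genes, spec.n_tissues))

    specific = np.zeros(spec.n_genes, dtype=bool)
    specific[: spec.n_target_specific] = True

    for i in range(spec.n_genes):
        others = values[i, 1:]
        if specific[i]:
            target = spec.specific_level * rng.uniform(1.0, 3.0)
            # enforce the fold rules constructively
            cap = target / 2.0
            others = np.minimum(others, cap)
            med = np.median(others)
            if target < 6.0 * med:
                others *= target / (6.0 * med)
            values[i, 0] = target
            values[i, 1:] = others
        else:
            # make sure the gene fails the absolute-level rule outright
            if values[i, 0] >= 1000.0:
                values[i, 0] = np.median(others)

    matrix = pd.DataFrame(values, index=gene_ids, columns=tissues)
    atlas = TissueAtlas(matrix=matrix, target_tissue=spec.target_tissue)
    called = {c.gene for c in call_predominant(atlas) if c.passes}
    expected = set(np.array(gene_ids)[specific])
    if called != expected:  # pragma: no cover - construction guarantee
        raise RuntimeError("atlas construction failed to plant the requested positives")
    return atlas


def make_biomarker_db(
    markers: Sequence[str],
    slope_per_week: float | Mapping[str, float] = 0.0,
    intercept_percent: float | Mapping[str, float] = 100.0,
    n_studies: int = 20,
    weeks_range: tuple[float, float] = (8.0, 36.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Literature-style biomarker table: percent-of-control linear in
    gestational week plus Gaussian noise.

    Columns: study, marker, week, percent_of_control, n.
    """
    if not weeks_range or weeks_range[0] >= weeks_range[1]:
        raise ValueError("weeks_range must be a non-empty (low, high) interval")
    rng = np.random.default_rng(seed)
    rows = []
    for marker in markers:
        slope = slope_per_week[marker] if isinstance(slope_per_week, Mapping) else slope_per_week
        intercept = (
            intercept_percent[marker]
            if isinstance(intercept_percent, Mapping)
            else intercept_percent
        )
        weeks = rng.uniform(weeks_range[0], weeks_range[1], size=n_studies)
        percent = intercept + slope * weeks + rng.normal(0.0, noise_sd, size=n_studies)
        percent = np.maximum(percent, 1.0)  # percent-of-control must stay positive
        for j in range(n_studies):
            rows.append(
                {
                    "study": f"study_{j+1:03d}",
                    "marker": marker,
                    "week": float(weeks[j]),
                    "percent_of_control": float(percent[j]),
                    "n": int(rng.integers(20, 200)),
                }
            )
    return pd.DataFrame(rows)


class MethylationTruth(NamedTuple):
    """CpG count table plus the planted ground truth per CpG position."""

    counts: pd.DataFrame
    planted: pd.DataFrame  # index (chrom, pos): planted flag and true delta


def make_methylation_counts(
    n_cpgs: int = 20,
    samples_per_group: tuple[int, int] = (5, 5),
    depth_distribution: tuple[float, float] = (50.0, 5.0),  # NB mean, dispersion size
    baseline_ratio: float = 0.4,
    planted_delta: float = 0.3,
    n_planted: int = 0,
    seed: int = 0,
) -> MethylationTruth:
    """Targeted bisulfite CpG counts with planted group differences.

    Totals are negative-binomial with floor 1; methylated counts are binomial
    given the totals.  The first ``n_planted`` CpGs have their case-group
    methylation probability shifted by ``planted_delta``.
    """
    if not (0.0 <= baseline_ratio <= 1.0):
        raise ValueError("baseline_ratio must lie in [0, 1]")
    if not (0.0 <= baseline_ratio + planted_delta <= 1.0):
        raise ValueError("baseline_ratio + planted_delta outside [0, 1]")
    if n_planted > n_cpgs:
        raise ValueError("n_planted exceeds n_cpgs")
    rng = np.random.default_rng(seed)
    mean_depth, size = depth_distribution
    p_nb = size / (size + mean_depth)
    n_case, n_ctrl = samples_per_group
    sample_ids = [f"case_{i+1:02d}" for i in range(n_case)] + [
        f"ctrl_{i+1:02d}" for i in range(n_ctrl)
    ]
    groups = ["case"] * n_case + ["control"] * n_ctrl
    positions = 1_000_001 + 50 * np.arange(n_cpgs)  # 1-based coordinates
    rows = []
    truth_rows = []
    for i in range(n_cpgs):
        planted = i < n_planted
        truth_rows.append(
            {
                "chrom": "chr3",
                "pos": int(positions[i]),
                "planted": planted,
                "true_delta": planted_delta if planted else 0.0,
            }
        )
        for sample, grp in zip(sample_ids, groups):
            total = max(1, int(rng.negative_binomial(size, p_nb)))
            p = baseline_ratio + (planted_delta if (planted and grp == "case") else 0.0)
            meth = int(rng.binomial(total, p))
            rows.append(
                {
                    "chrom": "chr3",
                    "pos": int(positions[i]),
                    "sample": sample,
                    "group": grp,
                    "methylated": meth,
                    "total": total,
                }
            )
    counts = pd.DataFrame(rows)
    planted_df = pd.DataFrame(truth_rows).set_index(["chrom", "pos"])
    return MethylationTruth(counts=counts, planted=planted_df)
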