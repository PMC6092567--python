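"""Readers and writers for the plain-text schemas the pipeline exchanges.

Formats: expression TSV (genes x samples, log2 unless flagged), sample sheet
CSV, gene annotation TSV, tissue atlas TSV (first column gene/probeset id,
header row of tissue names), biomarker measurement CSV
(study,marker,week,percent_of_control[,n]), CpG count TSV
(chrom,pos,sample,group,methylated,total), and the per-stage result TSVs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .diffexpr import ExpressionStudy
from .tissue_specificity import TissueAtlas

__all__ = [
    "read_expression",
    "write_expression",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_annotations",
    "write_gene_annotations",
    "read_study",
    "write_study",
    "read_atlas",
    "write_atlas",
    "read_biomarkers",
    "write_biomarkers",
    "read_cpg_counts",
    "write_cpg_counts",
    "write_table",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).rename_axis(None)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0).rename_axis(None)


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, index_label="sample")


def read_gene_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).rename_axis(None)


def write_gene_annotations(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index_label="gene")


def write_study(study: ExpressionStudy, directory: str | Path, prefix: str = "study") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_expression(study.matrix, directory / f"{prefix}_expression.tsv")
    write_sample_sheet(study.samples, directory / f"{prefix}_samples.csv")
    write_gene_annotations(study.genes, directory / f"{prefix}_genes.tsv")


def read_study(directory: str | Path, prefix: str = "study") -> ExpressionStudy:
    directory = Path(directory)
    return ExpressionStudy(
        matrix=read_expression(directory / f"{prefix}_expression.tsv"),
        samples=read_sample_sheet(directory / f"{prefix}_samples.csv"),
        genes=read_gene_annotations(directory / f"{prefix}_genes.tsv"),
    )


def read_atlas(path: str | Path, target_tissue: str) -> TissueAtlas:
    matrix = pd.read_csv(path, sep="\t", index_col=0).rename_axis(None)
    return TissueAtlas(matrix=matrix, target_tissue=target_tissue)


def write_atlas(atlas: TissueAtlas, path: str | Path) -> None:
    atlas.matrix.to_csv(path, sep="\t", index_label="gene")


def read_biomarkers(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_biomarkers(measurements: pd.DataFrame, path: str | Path) -> None:
    measurements.to_csv(path, index=False)


def read_cpg_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cpg_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def write_table(frame: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Generic TSV writer for result tables."""
    frame.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)
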