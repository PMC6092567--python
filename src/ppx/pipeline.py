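"""Pipeline orchestration: stage execution in dependency order with a YAML
config, per-stage TSV/JSON outputs, logging, and a reproducible report.

Stage order: simulate -> de -> modules -> hubs -> enrich -> clinical ->
biopsy -> matchscore -> methylation.  Every stage can be toggled; all
parameters and the seed are recorded in the report together with a checksum
over the written outputs, so two runs with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as ppx_io
from .clinical_association import gene_trait_model, module_trait_enrichment
from .coexpression_modules import build_network, detect_modules, hub_candidates, module_enrichment
from .diffexpr import de_linear_model
from .liquid_biopsy import ga_trend, trimester_summary
from .methylation import compare_groups, filter_and_ratio
from .pattern_match import discretize_states, match_permutation_test
from .synthetic_data import (
    AtlasSpec,
    ModuleSpec,
    StudySpec,
    make_atlas,
    make_biomarker_db,
    make_methylation_counts,
    make_study,
)
from .tissue_specificity import call_predominant

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "DEFAULT_CONFIG"]

STAGES = (
    "simulate",
    "de",
    "modules",
    "hubs",
    "enrich",
    "clinical",
    "biopsy",
    "matchscore",
    "methylation",
)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "stages": list(STAGES),
    "simulate": {
        "n_cases": 12,
        "n_controls": 5,
        "n_genes": 300,
        "modules": [
            {"size": 50, "within_correlation": 0.8, "trait_link": "MAP",
             "direction": "up", "group_shift": 2.0},
            {"size": 50, "within_correlation": 0.8, "trait_link": "BW",
             "direction": "down", "group_shift": 2.0},
        ],
        "batch_levels": 2,
        "noise_sd": 0.2,
        "n_de_genes": 30,
        "de_log2fc": 1.0,
        "atlas": {"n_genes": 100, "n_tissues": 79, "n_target_specific": 20},
        "biomarkers": {
            "markers": ["hPL", "sFlt-1", "sEng", "leptin", "hCG"],
            "slope_per_week": 5.0,
            "intercept_percent": 40.0,
            "n_studies": 30,
            "noise_sd": 10.0,
        },
        "methylation": {
            "n_cpgs": 20,
            "samples_per_group": [5, 5],
            "baseline_ratio": 0.4,
            "planted_delta": 0.3,
            "n_planted": 5,
        },
    },
    "de": {"q_threshold": 0.2, "fc_threshold": 1.5},
    "modules": {"beta": 10.0, "min_module_size": 30, "deep_split": 2},
    "hubs": {"intensity_min": 9.0, "cor_min": 0.7},
    "enrich": {},
    "clinical": {"traits": ["MAP", "BW_percentile"], "q_threshold": 0.2},
    "biopsy": {"cutoff_week": 12.0},
    "matchscore": {"q_threshold": 0.05, "fc_threshold": 1.5, "n_random": 5000},
    "methylation": {"min_coverage": 4, "min_group_n": 2},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (stage toggles + stage parameters)."""

    settings: dict[str, Any]

    def __post_init__(self) -> None:
        unknown = set(self.settings) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        def _merge(defaults: Any, override: Any, path: str) -> Any:
            if isinstance(defaults, dict) and isinstance(override, dict):
                extra = set(override) - set(defaults)
                if extra:
                    raise ValueError(f"unknown keys in [{path}]: {sorted(extra)}")
                return {
                    k: _merge(defaults[k], override[k], f"{path}.{k}")
                    if k in override
                    else defaults[k]
                    for k in defaults
                }
            return override

        merged: dict[str, Any] = {}
        for section, defaults in DEFAULT_CONFIG.items():
            if section in self.settings:
                merged[section] = _merge(defaults, self.settings[section], section)
            else:
                merged[section] = defaults
        bad_stages = set(merged["stages"]) - set(STAGES)
        if bad_stages:
            raise ValueError(f"unknown stages: {sorted(bad_stages)}")
        self.settings = merged

    def __getitem__(self, key: str) -> Any:
        return self.settings[key]

    @property
    def stages(self) -> list[str]:
        return list(self.settings["stages"])

    @property
    def seed(self) -> int:
        return int(self.settings["seed"])


def load_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> PipelineConfig:
    settings: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            settings = yaml.safe_load(fh) or {}
    if overrides:
        settings.update(overrides)
    return PipelineConfig(settings)


def _study_spec(cfg: PipelineConfig) -> StudySpec:
    sim = cfg["simulate"]
    modules = tuple(
        ModuleSpec(
            size=m["size"],
            within_correlation=m.get("within_correlation", 0.8),
            trait_link=m.get("trait_link", "none"),
            direction=m.get("direction", "up"),
            group_shift=m.get("group_shift", 0.0),
        )
        for m in sim["modules"]
    )
    return StudySpec(
        n_cases=sim["n_cases"],
        n_controls=sim["n_controls"],
        n_genes=sim["n_genes"],
        module_specs=modules,
        batch_levels=sim["batch_levels"],
        noise_sd=sim["noise_sd"],
        n_de_genes=sim["n_de_genes"],
        de_log2fc=sim["de_log2fc"],
        seed=cfg.seed,
    )


def _checksum(out_dir: Path, files: list[Path]) -> str:
    h = hashlib.sha256()
    for path in sorted(files):
        h.update(path.name.encode())
        h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute the requested stages in dependency order and write a report.

    Returns the report dict (also written as ``report.json``): parameters,
    seed, per-stage summaries, and a checksum over all written outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = config.stages
    seed = config.seed
    written: list[Path] = []
    report: dict[str, Any] = {"seed": seed, "parameters": config.settings, "stages": {}}

    def _write(frame: pd.DataFrame, name: str, index_label: str | None = None) -> None:
        path = out_dir / name
        ppx_io.write_table(frame, path, index_label=index_label)
        written.append(path)

    study = None
    atlas = None
    biomarkers = None
    meth_truth = None
    if "simulate" in stages:
        study = make_study(_study_spec(config))
        ppx_io.write_study(study, out_dir)
        written.extend(
            out_dir / f"study_{part}" for part in ("expression.tsv", "samples.csv", "genes.tsv")
        )
        sim = config["simulate"]
        atlas_spec = AtlasSpec(seed=seed, **sim["atlas"])
        atlas = make_atlas(atlas_spec)
        ppx_io.write_atlas(atlas, out_dir / "atlas.tsv")
        written.append(out_dir / "atlas.tsv")
        bio = sim["biomarkers"]
        biomarkers = make_biomarker_db(
            markers=bio["markers"],
            slope_per_week=bio["slope_per_week"],
            intercept_percent=bio["intercept_percent"],
            n_studies=bio["n_studies"],
            noise_sd=bio["noise_sd"],
            seed=seed,
        )
        ppx_io.write_biomarkers(biomarkers, out_dir / "biomarkers.csv")
        written.append(out_dir / "biomarkers.csv")
        meth = sim["methylation"]
        meth_truth = make_methylation_counts(
            n_cpgs=meth["n_cpgs"],
            samples_per_group=tuple(meth["samples_per_group"]),
            baseline_ratio=meth["baseline_ratio"],
            planted_delta=meth["planted_delta"],
            n_planted=meth["n_planted"],
            seed=seed,
        )
        ppx_io.write_cpg_counts(meth_truth.counts, out_dir / "cpg_counts.tsv")
        written.append(out_dir / "cpg_counts.tsv")
        report["stages"]["simulate"] = {
            "n_genes": study.n_genes,
            "n_samples": study.n_samples,
            "n_atlas_genes": atlas.matrix.shape[0],
            "n_biomarker_rows": len(biomarkers),
            "n_cpgs": meth["n_cpgs"],
        }

    def _require(stage: str, obj, producer: str):
        if obj is None:
            raise RuntimeError(f"stage {stage!r} requires output of stage {producer!r}")
        return obj

    de_result = None
    if "de" in stages:
        study = _require("de", study, "simulate")
        de_cfg = config["de"]
        de_result = de_linear_model(
            study, q_threshold=de_cfg["q_threshold"], fc_threshold=de_cfg["fc_threshold"]
        )
        _write(de_result.table, "de_results.tsv", index_label="gene")
        report["stages"]["de"] = {
            "n_de": int(de_result.table["call"].sum()),
            "prior_df": de_result.prior_df,
        }

    modules = None
    network = None
    if "modules" in stages:
        study = _require("modules", study, "simulate")
        de_result = _require("modules", de_result, "de")
        mod_cfg = config["modules"]
        de_genes = list(de_result.de_genes)
        module_input = study.subset_genes(de_genes) if len(de_genes) >= 2 else study
        network = build_network(module_input, beta=mod_cfg["beta"])
        modules = detect_modules(
            network,
            min_module_size=mod_cfg["min_module_size"],
            deep_split=mod_cfg["deep_split"],
        )
        _write(modules.labels.to_frame(), "modules.tsv", index_label="gene")
        sizes = {m: int((modules.labels == m).sum()) for m in modules.module_names}
        report["stages"]["modules"] = {"module_sizes": sizes}

    if "hubs" in stages:
        study = _require("hubs", study, "simulate")
        modules = _require("hubs", modules, "modules")
        hub_cfg = config["hubs"]
        hubs = hub_candidates(
            study,
            modules,
            intensity_min=hub_cfg["intensity_min"],
            cor_min=hub_cfg["cor_min"],
        )
        _write(hubs.table, "hub_candidates.tsv")
        report["stages"]["hubs"] = {"n_candidates": len(hubs.table)}

    if "enrich" in stages:
        study = _require("enrich", study, "simulate")
        modules = _require("enrich", modules, "modules")
        atlas = _require("enrich", atlas, "simulate")
        calls = call_predominant(atlas)
        prop = study.genes["is_placenta_predominant"].astype(bool)
        enr = module_enrichment(modules, prop)
        frame = pd.DataFrame(
            {
                "module": list(enr),
                "odds_ratio": [enr[m].odds_ratio for m in enr],
                "p": [enr[m].p_value for m in enr],
                "q": [enr[m].q_value for m in enr],
            }
        )
        _write(frame, "module_enrichment.tsv")
        report["stages"]["enrich"] = {
            "n_predominant_atlas": int(sum(c.passes for c in calls)),
            "modules_tested": list(enr),
        }

    if "clinical" in stages:
        study = _require("clinical", study, "simulate")
        modules = _require("clinical", modules, "modules")
        cl_cfg = config["clinical"]
        assoc = gene_trait_model(
            study, traits=tuple(cl_cfg["traits"]), q_threshold=cl_cfg["q_threshold"]
        )
        _write(assoc.table, "trait_associations.tsv", index_label="gene")
        trait_enr = {}
        for trait in cl_cfg["traits"]:
            enr = module_trait_enrichment(modules, assoc, trait)
            trait_enr[trait] = {m: {"or": enr[m].odds_ratio, "p": enr[m].p_value} for m in enr}
        report["stages"]["clinical"] = {
            "n_sig": {t: int(assoc.table[f"sig_{t}"].sum()) for t in cl_cfg["traits"]},
            "module_trait_enrichment": trait_enr,
        }

    if "biopsy" in stages:
        biomarkers = _require("biopsy", biomarkers, "simulate")
        cutoff = config["biopsy"]["cutoff_week"]
        trends = []
        for marker in sorted(biomarkers["marker"].unique()):
            t = ga_trend(biomarkers, marker, cutoff_week=cutoff)
            trends.append(
                {
                    "marker": t.marker,
                    "pearson_r": t.pearson_r,
                    "p": t.p_value,
                    "n": t.n_points,
                }
            )
        _write(pd.DataFrame(trends), "biopsy_trends.tsv")
        summary = trimester_summary(biomarkers, cutoff_week=cutoff)
        _write(summary.reset_index(), "biopsy_trimesters.tsv")
        report["stages"]["biopsy"] = {"n_markers": len(trends)}

    if "matchscore" in stages:
        study = _require("matchscore", study, "simulate")
        de_result = _require("matchscore", de_result, "de")
        ms_cfg = config["matchscore"]
        pattern = discretize_states(
            de_result, q_threshold=ms_cfg["q_threshold"], fc_threshold=ms_cfg["fc_threshold"]
        )
        # in vitro stand-in: the study itself, so the observed score is the
        # self-match ceiling and the permutation null is well-exercised
        result = match_permutation_test(
            study.matrix,
            study.samples["group"],
            pattern,
            q_threshold=ms_cfg["q_threshold"],
            fc_threshold=ms_cfg["fc_threshold"],
            n_random=ms_cfg["n_random"],
            seed=seed,
        )
        payload = {
            "score": result.score,
            "p": result.permutation.p_value,
            "n_permutations": result.permutation.n_permutations,
            "exhaustive": result.permutation.exhaustive,
            "seed": seed,
        }
        path = out_dir / "matchscore.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        written.append(path)
        _write(pattern.states.to_frame(), "states.tsv", index_label="gene")
        report["stages"]["matchscore"] = payload

    if "methylation" in stages:
        meth_truth = _require("methylation", meth_truth, "simulate")
        me_cfg = config["methylation"]
        counts = meth_truth.counts
        results = []
        for (chrom, pos), sub in counts.groupby(["chrom", "pos"], sort=True):
            res = compare_groups(
                sub, min_group_n=me_cfg["min_group_n"], min_coverage=me_cfg["min_coverage"]
            )
            if res is not None:
                results.append(res.__dict__)
        frame = pd.DataFrame(results)
        _write(frame, "methylation_dm.tsv")
        report["stages"]["methylation"] = {
            "n_cpgs_tested": len(frame),
            "n_dm": int((frame["dm_class"] != "none").sum()) if len(frame) else 0,
        }

    report["output_checksum"] = _checksum(out_dir, written)
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    logger.info("pipeline finished; %d outputs in %s", len(written), out_dir)
    return report
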