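"""Discovery -> validation workflow orchestration.

``run_all`` drives the full analysis from one configuration: load (or
simulate) both cohorts, join sequence families and apply the min-count
filter, normalize to scaled relative-binding values, run the OLS contrasts
on the discovery cohort, freeze the descriptive panels, and validate each
panel on the independent validation cohort.  Every run directory carries a
manifest (config hash, seed, package version, stage counts) sufficient to
reproduce the outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import FilterConfig, filter_min_count, join_families
from .differential import default_contrasts, ols_contrast, summarize_contrasts, unique_descriptive
from .io import check_samples_match, read_counts, read_metadata, write_counts, write_panel_fasta
from .normalize import to_percent, to_scaled
from .simulate import PlantedEffect, SimulationConfig, generate_cohort
from .validation import validate_panel

__all__ = ["PipelineConfig", "run_discovery", "run_validation", "run_all"]

CONDITIONS = ("timepoint", "bmi_group", "parity")


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML."""

    discovery_counts: str | None = None
    discovery_metadata: str | None = None
    validation_counts: str | None = None
    validation_metadata: str | None = None
    simulate: dict | None = None  # SimulationConfig kwargs (+ planted dicts)
    d_max: int = 3
    c_min: int = 3
    presence_mode: str = "all_samples"
    time_threshold: float = 1.0
    group_threshold: float = 0.2
    fdr_q: float = 0.05
    timepoints: tuple = ("3d", "1m", "2m", "3m")
    motif_k: int = 7
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.timepoints = tuple(cfg.timepoints)
        return cfg

    def canonical_json(self) -> str:
        d = asdict(self)
        d["timepoints"] = list(self.timepoints)
        return json.dumps(d, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]

    def filter_config(self) -> FilterConfig:
        return FilterConfig(self.d_max, self.c_min, self.presence_mode)

    def contrasts(self):
        return default_contrasts(
            self.timepoints, self.time_threshold, self.group_threshold, self.fdr_q
        )


def _simulation_config(cfg: PipelineConfig, cohort: str, seed_offset: int) -> SimulationConfig:
    kwargs = dict(cfg.simulate or {})
    planted = [
        PlantedEffect(**p) if isinstance(p, dict) else p
        for p in kwargs.pop("planted", [])
    ]
    kwargs.setdefault("timepoints", cfg.timepoints)
    kwargs.pop("seed", None)
    kwargs.setdefault("library_seed", int(cfg.seed))
    return SimulationConfig(
        planted=tuple(planted),
        cohort=cohort,
        seed=int(cfg.seed) + seed_offset,
        **kwargs,
    )


def _load_cohort(cfg: PipelineConfig, cohort: str):
    if cfg.simulate is not None:
        offset = 0 if cohort == "discovery" else 1_000_003
        counts, meta, truth = generate_cohort(_simulation_config(cfg, cohort, offset))
        return counts, meta, truth
    counts_path = getattr(cfg, f"{cohort}_counts")
    meta_path = getattr(cfg, f"{cohort}_metadata")
    if counts_path is None or meta_path is None:
        raise ValueError(f"no counts/metadata configured for the {cohort} cohort")
    counts = read_counts(counts_path)
    meta = read_metadata(meta_path)
    check_samples_match(counts, meta)
    return counts, meta, None


def _process_cohort(counts: pd.DataFrame, cfg: PipelineConfig):
    """Join, filter, normalize; returns dict of stage outputs and counts."""
    fc = cfg.filter_config()
    joined, families = join_families(counts, fc)
    filtered = filter_min_count(joined, fc)
    scaled = to_scaled(to_percent(filtered))
    return {
        "joined": joined,
        "families": families,
        "filtered": filtered,
        "scaled": scaled,
        "stage_counts": {
            "raw_sequences": int(counts.shape[0]),
            "total_reads": int(counts.to_numpy().sum()),
            "joined_sequences": int(joined.shape[0]),
            "retained_sequences": int(filtered.shape[0]),
        },
    }


def run_discovery(counts: pd.DataFrame, meta: pd.DataFrame, cfg: PipelineConfig) -> dict:
    """Discovery-cohort analysis: families, filter, scaling, OLS panels."""
    check_samples_match(counts, meta)
    stages = _process_cohort(counts, cfg)
    results = {}
    for spec in cfg.contrasts():
        results[spec.name] = ols_contrast(stages["scaled"], meta, spec)
    panels = {
        cond: unique_descriptive(results, cond) for cond in CONDITIONS
    }
    stages["results"] = results
    stages["summary"] = summarize_contrasts(results)
    stages["panels"] = panels
    stages["stage_counts"]["descriptive_per_contrast"] = {
        name: int(res["descriptive"].sum()) for name, res in results.items()
    }
    return stages


def run_validation(
    counts: pd.DataFrame, meta: pd.DataFrame, panels: dict, cfg: PipelineConfig
) -> dict:
    """Frozen-panel validation on the independent cohort."""
    check_samples_match(counts, meta)
    stages = _process_cohort(counts, cfg)
    validations = {}
    for cond, panel in panels.items():
        if not panel:
            continue
        validations[cond] = validate_panel(
            stages["scaled"], meta, panel, cond, cfg.timepoints
        )
    stages["validations"] = validations
    return stages


def run_all(cfg: PipelineConfig, outdir) -> dict:
    """Run discovery and validation, write outputs + manifest, return report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "INCOMPLETE").write_text("run in progress\n")

    d_counts, d_meta, d_truth = _load_cohort(cfg, "discovery")
    v_counts, v_meta, v_truth = _load_cohort(cfg, "validation")
    overlap = set(d_meta["sample_id"]) & set(v_meta["sample_id"])
    if overlap:
        raise ValueError(f"cohort sample sets overlap: {sorted(overlap)[:5]}")

    disc = run_discovery(d_counts, d_meta, cfg)
    any_panel = any(disc["panels"].values())
    if any_panel:
        vali = run_validation(v_counts, v_meta, disc["panels"], cfg)
    else:
        vali = {"validations": {}, "stage_counts": {"skipped": True}}

    write_counts(disc["filtered"], outdir / "discovery_filtered_counts.tsv")
    disc["scaled"].to_csv(outdir / "discovery_scaled.tsv", sep="\t")
    disc["summary"].to_csv(outdir / "contrast_summary.tsv", sep="\t", index=False)
    for name, res in disc["results"].items():
        res.to_csv(outdir / f"contrast_{name.replace(':', '_')}.tsv", sep="\t")
    for cond, panel in disc["panels"].items():
        if panel:
            write_panel_fasta(panel, outdir / f"panel_{cond}.fasta")

    report = {
        "config_hash": cfg.config_hash,
        "seed": int(cfg.seed),
        "version": __version__,
        "discovery": disc["stage_counts"],
        "validation": vali.get("stage_counts", {}),
        "panels": {c: len(p) for c, p in disc["panels"].items()},
        "validation_results": {},
    }
    if not any_panel:
        report["validation_note"] = "no descriptive sequences; validation skipped"
    for cond, pv in vali.get("validations", {}).items():
        report["validation_results"][cond] = {
            "panel_coverage": pv.panel_coverage,
            "explained_variance_pc1": float(pv.explained_variance_ratio[0]),
            "group_medians": {k: round(v, 10) for k, v in pv.group_medians.items()},
            "group_variances": {k: round(v, 10) for k, v in pv.group_variances.items()},
            "wilcoxon_p": {k: float(v) for k, v in pv.wilcoxon_p.items()},
        }

    manifest = {
        "config": json.loads(cfg.canonical_json()),
        "config_hash": cfg.config_hash,
        "seed": int(cfg.seed),
        "version": __version__,
        "stage_counts": {
            "discovery": disc["stage_counts"],
            "validation": vali.get("stage_counts", {}),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
    (outdir / "INCOMPLETE").unlink()
    return report
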