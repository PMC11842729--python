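"""End-to-end orchestration: simulate -> triage -> load -> origin ->
diversity -> biomarkers, with deterministic TSV/JSON outputs per stage.

Per-stage seeds are derived from the master seed by fixed offsets
(simulate +1, origin +4, diversity +5, biomarkers +6) and recorded in
each stage's JSON summary.  All outputs are written with fixed float
formatting and sorted JSON keys so that a rerun with the same seed is
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .containers import FeatureTable
from .simulate import SimulationConfig, config_from_dict, simulate_study
from .triage import AMPLICON, TriageConfig, TriageResult, triage_features
from .load import box_summary, compare_ratios, depth_abundance_correlation, load_profiles
from .origin import (
    category_abundance,
    collapse_to_rank,
    observed_set,
    partition_origin,
    venn_accounting,
)
from .diversity import RarefactionEnsemble, alpha_ensemble, beta_ensemble, index_tree
from .lefse import lefse_screen

log = logging.getLogger("microtriage")

FLOAT_FORMAT = "%.10g"

STAGE_SEED_OFFSETS = {
    "simulate": 1, "triage": 2, "load": 3, "origin": 4, "diversity": 5, "lefse": 6,
}


def stage_seed(master_seed: int, stage: str) -> int:
    return (int(master_seed) + STAGE_SEED_OFFSETS[stage]) % (2**31)


@dataclass
class PipelineConfig:
    """Analysis-scale knobs for a full run.

    The bundled defaults use a desk-scale ensemble (50 rarefactions, 999
    permutations); the underlying functions default to the full-scale
    500/10000 convention when called directly.
    """

    sim: dict = field(default_factory=dict)  # SimulationConfig overrides
    n_reps: int = 50
    n_permutations: int = 999
    rarefaction_depth: int | None = None
    rank: str = "genus"
    lda_threshold: float = 4.5
    kw_alpha: float = 0.05
    triage: dict = field(default_factory=dict)  # TriageConfig overrides

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def _log_stage(stage: str, seed, shapes: dict, outdir: Path) -> None:
    log.info("stage=%s seed=%s %s outdir=%s", stage, seed,
             " ".join(f"{k}={v}" for k, v in shapes.items()), outdir)


def _group_label(meta_row) -> str:
    if meta_row["source"] == "fecal":
        return f"fecal_{meta_row['treatment']}"
    if meta_row["source"] == "blank":
        return "blank"
    return f"{meta_row['implant_status']}_{meta_row['treatment']}"


def run_all(outdir, master_seed: int = 0, config: PipelineConfig | None = None) -> dict:
    """Run every stage on a fresh synthetic study; returns the combined
    run summary (also written to ``run_summary.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    summary: dict = {"master_seed": int(master_seed)}

    # ---- simulate ----
    seed = stage_seed(master_seed, "simulate")
    sim_config = config_from_dict({**config.sim, "seed": seed})
    table, metadata, annotations, tree, truth = simulate_study(sim_config)
    mio.write_feature_table(table, outdir / "table.tsv")
    mio.write_metadata(metadata, outdir / "metadata.tsv")
    mio.write_taxonomy(annotations, outdir / "taxonomy.tsv")
    mio.write_tree(tree, outdir / "tree.nwk")
    truth_df = pd.DataFrame({"role": truth.roles})
    truth_df.index.name = "feature_id"
    _write_tsv(truth_df, outdir / "truth_features.tsv")
    biomass_df = truth.biomass.to_frame()
    biomass_df.index.name = "sample_id"
    _write_tsv(biomass_df, outdir / "truth_biomass.tsv")
    _write_json({"seed": seed, **asdict(sim_config)}, outdir / "simulate_summary.json")
    _log_stage("simulate", seed, {"features": table.n_features, "samples": table.n_samples}, outdir)
    summary["simulate"] = {"n_features": table.n_features, "n_samples": table.n_samples}

    # ---- triage ----
    tri_config = TriageConfig(**config.triage)
    tri = triage_features(table, metadata, annotations, tri_config)
    tri_df = pd.DataFrame({
        "class": tri.classes,
        "prevalence_p": tri.prevalence_p,
        "frequency_p": tri.frequency_p,
    })
    tri_df.index.name = "feature_id"
    _write_tsv(tri_df, outdir / "triage.tsv")
    _write_json({"class_counts": tri.summary(),
                 "thresholds": asdict(tri_config),
                 "strata": [list(s) for s in tri.strata]}, outdir / "triage_summary.json")
    _log_stage("triage", None, tri.summary(), outdir)
    summary["triage"] = tri.summary()

    # ---- load ----
    profiles = load_profiles(table, tri)
    _write_tsv(profiles, outdir / "load_profiles.tsv")
    meta_nb = metadata[metadata["source"] != "blank"]
    groups = metadata.apply(_group_label, axis=1)
    comparison = compare_ratios(profiles.loc[meta_nb.index],
                                metadata.assign(group=groups), "group")
    _write_tsv(comparison.pairwise, outdir / "load_tests.tsv", index=False)
    diag = {}
    for source in ("brain", "fecal"):
        ids = list(meta_nb.index[meta_nb["source"] == source])
        sub = table.select_samples(ids)
        for target in ("AMPLICON", "CONTAMINANT"):
            res = depth_abundance_correlation(sub, tri, target)
            diag[f"{source}_{target.lower()}"] = {
                "rho": res.statistic, "p": res.p_value,
            }
    _write_json({
        "kruskal_statistic": comparison.statistic,
        "kruskal_p": comparison.p_value,
        "group_medians": comparison.extra["group_medians"],
        "group_boxes": {
            g: box_summary(profiles.loc[meta_nb.index[groups[meta_nb.index] == g], "ratio"])
            for g in sorted(groups[meta_nb.index].unique())
        },
        "depth_abundance": diag,
    }, outdir / "load_summary.json")
    _log_stage("load", None, {"samples": len(profiles)}, outdir)
    summary["load"] = {"group_medians": comparison.extra["group_medians"]}

    # ---- origin ----
    seed = stage_seed(master_seed, "origin")
    amplicon = table.select_features(tri.features_in_class(AMPLICON))
    genus = collapse_to_rank(amplicon, annotations, config.rank)
    is_brain = metadata["source"] == "brain"
    background = observed_set(genus, metadata, lambda m: (m["source"] == "brain") & (m["implant_status"] == "unimplanted"))
    acute = observed_set(genus, metadata, lambda m: m["implant_status"] == "acute")
    chronic = observed_set(genus, metadata, lambda m: m["implant_status"] == "chronic")
    fecal = observed_set(genus, metadata, lambda m: m["source"] == "fecal")
    venn = venn_accounting(background, acute, chronic, fecal)
    partition = partition_origin(acute | chronic, background, fecal)
    part_df = partition.to_frame()
    part_df.index.name = "taxon"
    _write_tsv(part_df, outdir / "origin_partition.tsv")
    _write_json(venn.to_dict(), outdir / "venn_accounting.json")
    implanted_ids = list(metadata.index[is_brain & metadata["implant_status"].isin(["acute", "chronic"])])
    implanted_genus = genus.select_samples(implanted_ids)
    ensemble = RarefactionEnsemble(implanted_genus, n_reps=config.n_reps,
                                   depth=config.rarefaction_depth, seed=seed)
    cat = category_abundance(ensemble.tables(), partition,
                             metadata.assign(group=groups), group_col="group")
    per_sample = cat["per_sample"].copy()
    per_sample.index.name = "sample_id"
    _write_tsv(per_sample, outdir / "category_abundance.tsv")
    mean_by_group = cat["per_sample"].groupby(groups.loc[cat["per_sample"].index]).mean()
    _write_json({"seed": seed, "n_reps": config.n_reps, "depth": ensemble.depth,
                 "mean_by_group": {str(g): row.to_dict()
                                   for g, row in mean_by_group.iterrows()}},
                outdir / "origin_summary.json")
    _log_stage("origin", seed, {"taxa": genus.n_features}, outdir)
    summary["origin"] = venn.to_dict()

    # ---- diversity ----
    seed = stage_seed(master_seed, "diversity")
    brain_ids = list(metadata.index[is_brain])
    brain_amplicon = amplicon.select_samples(brain_ids)
    alpha = alpha_ensemble(brain_amplicon, metadata, n_reps=config.n_reps,
                           depth=config.rarefaction_depth, seed=seed)
    per_sample = alpha["per_sample"].copy()
    per_sample.index.name = "sample_id"
    _write_tsv(per_sample, outdir / "alpha_metrics.tsv")
    alpha_tests = []
    for metric, tab in alpha["anova"].items():
        if tab is None:
            continue
        t = tab.reset_index().rename(columns={"index": "term"})
        t.insert(0, "metric", metric)
        alpha_tests.append(t)
    if alpha_tests:
        _write_tsv(pd.concat(alpha_tests, ignore_index=True), outdir / "alpha_tests.tsv", index=False)
    tindex = index_tree(tree)
    beta_summaries = {}
    pcoa_frames = []
    for treatment in ("control", "antibiotic"):
        cohort = list(metadata.index[is_brain & (metadata["treatment"] == treatment)])
        cohort_table = amplicon.select_samples(cohort)
        beta = beta_ensemble(cohort_table, tindex, metadata, n_reps=config.n_reps,
                             depth=config.rarefaction_depth, seed=seed + 7,
                             n_permutations=config.n_permutations)
        beta_summaries[treatment] = {
            "max_adjusted_p": beta["max_adjusted_p"],
            "min_raw_p": beta["min_raw_p"],
            "depth": beta["depth"],
            "n_reps": beta["n_reps"],
            "n_permutations": beta["n_permutations"],
        }
        coords = beta["first_replicate"]["pcoa"].coordinates.iloc[:, :2].copy()
        coords.insert(0, "treatment", treatment)
        coords.index.name = "sample_id"
        pcoa_frames.append(coords)
    _write_tsv(pd.concat(pcoa_frames), outdir / "pcoa_coords.tsv")
    _write_json({"seed": seed, "alpha_depth": alpha["depth"],
                 "alpha_warnings": alpha["warnings"],
                 "permanova": beta_summaries}, outdir / "permanova_summary.json")
    _log_stage("diversity", seed, {"brain_samples": len(brain_ids)}, outdir)
    summary["diversity"] = beta_summaries

    # ---- biomarkers ----
    seed = stage_seed(master_seed, "lefse")
    classes = metadata.loc[brain_ids, "implant_status"]
    hits = lefse_screen(brain_amplicon, annotations, classes,
                        alpha=config.kw_alpha, lda_threshold=config.lda_threshold,
                        seed=seed)
    _write_tsv(hits, outdir / "biomarkers.tsv", index=False)
    _write_json({"seed": seed, "n_hits": int(len(hits)),
                 "lda_threshold": config.lda_threshold}, outdir / "lefse_summary.json")
    _log_stage("lefse", seed, {"hits": len(hits)}, outdir)
    summary["lefse"] = {"n_hits": int(len(hits))}

    _write_json(summary, outdir / "run_summary.json")
    return summary


def load_config(path) -> PipelineConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.from_dict(raw)
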