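"""Pipeline driver chaining all stages with file artifacts.

Stages: simulate → screen → schedule → qc → curate → normalize → analyze.
Each stage writes its artifacts into the output directory and appends row
counts to a machine-readable run manifest.  All randomness flows from one
root seed through fixed per-stage offsets.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .analysis import differential, evaluate_classifiers, runs_to_frame
from .containers import PLATFORMS, FeatureTable
from .curation import coverage_filter, deduplicate, impute
from .normalization import (NormAEConfig, apply_normalization, assess,
                            fit_normae, normalize_median, normalize_tic,
                            qc_nist_cv)
from .qc import QCThresholds, qc_report
from .scheduling import interleave_qc, randomize_order
from .screening import disposition, roster_to_frame, screen_subject
from .simulate import SimulationConfig, simulate_feature_tables, simulate_roster

logger = logging.getLogger(__name__)

# per-stage seed offsets derived from the root seed
_STAGE_SEED = {"simulate": 0, "schedule": 11, "impute": 23, "normalize": 37,
               "analyze": 53}


def stage_seed(root: int, stage: str) -> int:
    return int((root * 1009 + _STAGE_SEED[stage]) % (2**31 - 1))


@dataclass
class PipelineConfig:
    """Root configuration: simulation block plus per-stage parameters."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    coverage_threshold: float = 0.5
    drop_low_coverage_annotated: bool = False
    lod_percentile: float = 1.0  # used when no explicit LOD is configured
    normae: NormAEConfig = field(default_factory=NormAEConfig)
    run_normae: bool = True
    contrast: tuple[str, str] = ("CRC", "HCtrl")
    algorithms: tuple[str, ...] = ("gradient_boosted_trees",)
    n_repeats: int = 3
    run_classifiers: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d:
            sim = dict(d["simulation"])
            if "gradient" in sim:
                sim["gradient"] = tuple(sim["gradient"])
            if "case_groups" in sim:
                sim["case_groups"] = tuple(sim["case_groups"])
            d["simulation"] = SimulationConfig(**sim)
        if "normae" in d:
            nae = dict(d["normae"])
            if "hidden" in nae:
                nae["hidden"] = tuple(nae["hidden"])
            d["normae"] = NormAEConfig(**nae)
        if "contrast" in d:
            d["contrast"] = tuple(d["contrast"])
        if "algorithms" in d:
            d["algorithms"] = tuple(d["algorithms"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["gradient"] = list(d["simulation"]["gradient"])
        d["simulation"]["case_groups"] = list(d["simulation"]["case_groups"])
        d["normae"]["hidden"] = list(d["normae"]["hidden"])
        d["contrast"] = list(d["contrast"])
        d["algorithms"] = list(d["algorithms"])
        return d

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        return cls.from_dict(io.read_yaml(path) or {})


def run_pipeline(config: PipelineConfig, outdir: Path) -> dict:
    """Execute every enabled stage; returns the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    sim = dataclasses.replace(config.simulation,
                              seed=stage_seed(config.seed, "simulate"))

    # -- simulate -----------------------------------------------------------
    roster = simulate_roster(sim)
    io.write_schedule(roster_to_frame(roster), outdir / "roster.tsv")
    manifest["stages"]["simulate"] = {"n_subjects": len(roster)}

    # -- screen -------------------------------------------------------------
    disp = disposition(roster)
    io.write_json(
        {"n_consenting": disp.n_consenting, "n_excluded": disp.n_excluded,
         "n_eligible": disp.n_eligible,
         "exclusion_counts": disp.exclusion_counts,
         "group_counts": disp.group_counts},
        outdir / "disposition.json")
    excluded = pd.DataFrame(
        [{"subject_id": sid, "reasons": ";".join(rs)}
         for sid, rs in disp.all_reasons.items()])
    excluded.to_csv(outdir / "excluded.tsv", sep="\t", index=False)
    manifest["stages"]["screen"] = {
        "n_excluded": disp.n_excluded, "n_eligible": disp.n_eligible}
    eligible = [r for r in roster if screen_subject(r)[0]]

    # -- schedule -----------------------------------------------------------
    samples = pd.DataFrame({
        "sample_id": [r.subject_id for r in eligible],
        "hospital": [r.hospital for r in eligible],
        "group": [r.group for r in eligible],
        "sex": [r.sex for r in eligible],
        "age": [r.age for r in eligible]})
    sched = randomize_order(samples, batch_size=sim.batch_size,
                            seed=stage_seed(config.seed, "schedule"),
                            n_batches=sim.n_batches)
    sched = interleave_qc(sched, qc_period=sim.qc_period, gradient=sim.gradient)
    io.write_schedule(sched.entries, outdir / "schedule.tsv")
    manifest["stages"]["schedule"] = {
        "n_injections": len(sched.entries), "n_batches": sched.n_batches}

    tables, truth = simulate_feature_tables(sim, sched, roster)
    io.write_sample_sheet(next(iter(tables.values())).sample_meta,
                          outdir / "samples.tsv")
    for p, t in tables.items():
        io.write_feature_table(t, outdir / f"table_{p}.tsv")
        io.write_standards(truth.standards[p], outdir / f"standards_{p}.tsv")
        truth.qc_observations[p].to_csv(
            outdir / f"qc_observations_{p}.tsv", sep="\t", index=False)

    # -- qc -----------------------------------------------------------------
    qc_all = {}
    for p in PLATFORMS:
        rep = qc_report(truth.qc_observations[p], truth.standards[p],
                        QCThresholds())
        io.write_json(rep.to_dict(), outdir / f"qc_report_{p}.json")
        qc_all[p] = rep.passed()
    manifest["stages"]["qc"] = {"passed": qc_all}

    # -- curate -------------------------------------------------------------
    curated: dict[str, FeatureTable] = {}
    cur_counts = {}
    for p, t in tables.items():
        filt = coverage_filter(t, config.coverage_threshold,
                               config.drop_low_coverage_annotated)
        lod = sim.lod_intensity.get(p)
        if lod is None:
            lod = float(np.nanpercentile(
                filt.matrix.to_numpy(), config.lod_percentile))
        n_missing = int(filt.matrix.isna().to_numpy().sum())
        imp = impute(filt, lod=lod, seed=stage_seed(config.seed, "impute"))
        curated[p] = imp
        io.write_feature_table(imp, outdir / f"curated_{p}.tsv")
        cur_counts[p] = {"n_features_in": t.n_features,
                         "n_features_kept": filt.n_features,
                         "n_imputed_cells": n_missing}
    manifest["stages"]["curate"] = cur_counts

    # -- normalize ----------------------------------------------------------
    norm_tables = curated
    if config.run_normae:
        norm_tables = {}
        norm_counts = {}
        for p, t in curated.items():
            model = fit_normae(t, config=config.normae,
                               seed=stage_seed(config.seed, "normalize"))
            corrected = apply_normalization(model, t)
            report = assess(t, corrected)
            io.write_feature_table(corrected, outdir / f"normalized_{p}.tsv")
            # TIC/median baselines on the metabolome-carrying injections
            sub = t.subset_columns(t.columns_of_type("bio", "QC_bio", "QC_NIST"))
            io.write_json(
                {"median_cv_before": float(report.cv_before.median()),
                 "median_cv_after": float(report.cv_after.median()),
                 "qc_dispersion_ratio": report.qc_dispersion_ratio,
                 "median_cv_tic": float(
                     qc_nist_cv(normalize_tic(sub)).median()),
                 "median_cv_median_scale": float(
                     qc_nist_cv(normalize_median(sub)).median())},
                outdir / f"assessment_{p}.json")
            norm_tables[p] = corrected
            norm_counts[p] = {"epochs_run": len(model.history)}
        manifest["stages"]["normalize"] = norm_counts

    # -- merge / deduplicate ------------------------------------------------
    result = deduplicate(norm_tables)
    io.write_feature_table(result.merged, outdir / "merged.tsv")
    result.kept.to_csv(outdir / "provenance.tsv", sep="\t", index=False)
    result.dropped.to_csv(outdir / "dropped_duplicates.tsv", sep="\t",
                          index=False)
    manifest["stages"]["merge"] = {
        "n_features": result.merged.n_features,
        "n_duplicates_dropped": len(result.dropped)}

    # -- analyze ------------------------------------------------------------
    contrast = differential(result.merged, config.contrast)
    contrast.table.to_csv(outdir / "contrast.tsv", sep="\t",
                          index_label="feature_id")
    manifest["stages"]["analyze"] = {
        "n_up": contrast.n_up, "n_down": contrast.n_down}
    if config.run_classifiers:
        meta = result.merged.sample_meta
        bio = result.merged.bio_columns
        labels = meta.loc[bio, "group"]
        labels = labels[labels.isin(config.contrast)]
        runs = evaluate_classifiers(
            result.merged, labels, algorithms=config.algorithms,
            n_repeats=config.n_repeats,
            seed=stage_seed(config.seed, "analyze"))
        frame = runs_to_frame(runs)
        frame.to_csv(outdir / "classifier_f1.tsv", sep="\t", index=False)
        io.write_json(
            {"mean_f1_macro": frame.groupby("algorithm")["f1_macro"]
             .mean().to_dict()},
            outdir / "classifier_report.json")
        manifest["stages"]["analyze"]["mean_f1_macro"] = (
            frame.groupby("algorithm")["f1_macro"].mean().to_dict())

    io.write_json(manifest, outdir / "manifest.json")
    return manifest
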