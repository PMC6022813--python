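"""End-to-end orchestration of the datalog mining study.

Runs, as toggled: simulate -> clean -> loans -> audiogram clustering ->
GP anomaly -> subgroup discovery -> style prediction, writing every stage's
artifact plus a machine-readable run manifest (package version, seeds, row
counts per stage).  The manifest contains no wall-clock information, so two
runs of the same configuration produce identical manifests; per-stage
timing goes to the log only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from .audiogram_clustering import cluster_audiograms, count_notch_centers, screen_low_pta
from .cleaning import (
    apply_predicate,
    apply_primary_rules,
    latest_snapshot_per_device,
    require_complete_audiogram,
)
from .datalog_model import ConfigError, Dataset, read_snapshots, write_snapshots
from .directionality_anomaly import fit_gp, mean_input_spl_frame, zscore_histogram, zscores
from .loan_detection import compare_style_rates, flag_loan_devices
from .style_prediction import crossval_forest, region_heatmap
from .subgroup_discovery import INPUT_SPL_MODALITY, STYLE_MODALITY, Modality, discover_subgroups
from .synthetic_data import SimulationConfig, simulate_dataset

logger = logging.getLogger("aidlog")

ALL_STAGES = ("simulate", "clean", "loans", "cluster", "gp_anomaly", "subgroups", "predict_style")

#: Fixed per-stage seed offsets from the top-level seed, so each stage is
#: independently reproducible.
SEED_OFFSETS = {
    "simulate": 0,
    "cluster": 1,
    "gp_anomaly": 2,
    "subgroups": 3,
    "predict_style": 4,
}


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of a full run; constructed from a nested mapping/YAML."""

    out_dir: str = "aidlog_run"
    seed: int = 20180531
    stages: tuple[str, ...] = ALL_STAGES
    input_path: str | None = None  # used instead of simulation when given
    simulate: dict = dataclasses.field(default_factory=dict)
    cluster: dict = dataclasses.field(default_factory=dict)  # k, n_starts, screen_pta
    loans: dict = dataclasses.field(default_factory=dict)  # improve_dB, min_freqs
    gp_anomaly: dict = dataclasses.field(default_factory=dict)  # m, style
    subgroups: dict = dataclasses.field(default_factory=dict)  # alpha, min_effect
    predict_style: dict = dataclasses.field(default_factory=dict)  # trees, folds, max_depth

    @classmethod
    def from_mapping(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in d.items() if k in known})
        cfg.stages = tuple(cfg.stages)
        bad = set(cfg.stages) - set(ALL_STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")
        if "simulate" not in cfg.stages and cfg.input_path is None:
            raise ConfigError("need either the simulate stage or an input_path")
        return cfg


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    return int(config.seed + SEED_OFFSETS.get(stage, 0)) % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run manifest.

    Artifacts are written under ``config.out_dir``; a stage failure aborts
    the run with a stage-attributed error, preserving artifacts written so
    far.  Identical configurations yield identical manifests.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "aidlog_version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "stage_seeds": {s: _stage_seed(config, s) for s in config.stages if s in SEED_OFFSETS},
        "rows": {},
        "outputs": {},
    }

    dataset: Dataset | None = None
    truth = None
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            t0 = time.perf_counter()
            dataset, truth = _run_stage(stage, config, dataset, truth, out, manifest)
            logger.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest


def _run_stage(stage, config, dataset, truth, out, manifest):
    if stage == "simulate":
        sim = SimulationConfig(**{"seed": _stage_seed(config, "simulate"), **config.simulate})
        dataset, truth = simulate_dataset(sim)
        write_snapshots(dataset, out / "data.csv")
        truth.devices.to_csv(out / "truth_devices.csv", index=False)
        truth.snapshots.to_csv(out / "truth_snapshots.csv", index=False)
        manifest["rows"]["simulate"] = len(dataset)
        manifest["outputs"]["data"] = "data.csv"
        return dataset, truth

    if dataset is None:
        dataset = read_snapshots(config.input_path)
        manifest["rows"]["input"] = len(dataset)

    if stage == "clean":
        cleaned, report = apply_primary_rules(dataset)
        write_snapshots(cleaned, out / "clean.csv")
        manifest["rows"]["clean"] = len(cleaned)
        manifest["outputs"]["clean"] = "clean.csv"
        manifest["cleaning_removed"] = report.removed
        return cleaned, truth

    if stage == "loans":
        complete, _ = require_complete_audiogram(dataset)
        result = flag_loan_devices(dataset=complete, **config.loans)
        result.devices.to_csv(out / "loan_flags.csv", index=False)
        result.by_style.to_csv(out / "loan_by_style.csv", index=False)
        pvals = compare_style_rates(result)
        pvals.to_csv(out / "loan_style_pvalues.csv")
        manifest["rows"]["loans"] = int(len(result.devices))
        manifest["loan_flagged_devices"] = int(result.devices["flagged"].sum())
        manifest["outputs"]["loans"] = "loan_flags.csv"
        return dataset, truth

    if stage == "cluster":
        opts = dict(config.cluster)
        screen_pta = opts.pop("screen_pta", 20.0)
        complete, _ = require_complete_audiogram(dataset)
        screened = screen_low_pta(complete, max_pta=screen_pta)
        model = cluster_audiograms(screened, seed=_stage_seed(config, "cluster"), **opts)
        np.savetxt(out / "cluster_centers.csv", model.centers, delimiter=",")
        manifest["rows"]["cluster"] = int(len(screened))
        manifest["cluster_notch_centers"] = count_notch_centers(model)
        manifest["outputs"]["cluster"] = "cluster_centers.csv"
        return dataset, truth

    if stage == "gp_anomaly":
        opts = dict(config.gp_anomaly)
        style = opts.pop("style", "BTEa")
        sub, _ = apply_predicate(dataset, lambda f: f["style"].eq(style).to_numpy(), "style")
        x = sub.frame["fraction_directional"].to_numpy(dtype=float)
        y = mean_input_spl_frame(sub.frame)
        model = fit_gp(x, y, seed=_stage_seed(config, "gp_anomaly"), **opts)
        result = zscores(model, x=x, value=y)
        np.savetxt(
            out / "zscores.csv",
            np.column_stack([x, y, result.mu, result.sd, result.z, result.flagged]),
            delimiter=",",
            header="fraction_directional,mean_input_spl,mu,sd,z,flagged",
            comments="",
        )
        counts, edges = zscore_histogram(result)
        np.savetxt(out / "zscore_histogram.csv", np.column_stack([edges[:-1], edges[1:], counts]), delimiter=",", header="lo,hi,count", comments="")
        manifest["rows"]["gp_anomaly"] = int(len(result))
        manifest["gp_flag_rate"] = round(result.flag_rate, 6)
        manifest["outputs"]["gp_anomaly"] = "zscores.csv"
        return dataset, truth

    if stage == "subgroups":
        opts = dict(config.subgroups)
        latest = latest_snapshot_per_device(dataset)
        keep = latest.frame["style"].notna().to_numpy()
        latest = latest.subset(keep)
        result = discover_subgroups(
            latest,
            STYLE_MODALITY,
            INPUT_SPL_MODALITY,
            seed=_stage_seed(config, "subgroups"),
            **opts,
        )
        result.to_frame().to_csv(out / "subgroups.csv", index=False)
        manifest["rows"]["subgroups"] = result.n
        manifest["subgroups_found"] = len(result.subgroups)
        manifest["outputs"]["subgroups"] = "subgroups.csv"
        return dataset, truth

    if stage == "predict_style":
        opts = dict(config.predict_style)
        heat_style = opts.pop("heatmap_style", "CIC")
        latest = latest_snapshot_per_device(dataset)
        latest = latest.subset(latest.frame["style"].notna().to_numpy())
        cm, models = crossval_forest(latest, seed=_stage_seed(config, "predict_style"), **opts)
        cm.counts.to_csv(out / "confusion.csv")
        heat = region_heatmap(models, target_style=heat_style)
        heat.to_frame().to_csv(out / "heatmap.csv")
        manifest["rows"]["predict_style"] = cm.n
        manifest["outputs"]["predict_style"] = "confusion.csv"
        return dataset, truth

    raise ConfigError(f"unknown stage {stage!r}")
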