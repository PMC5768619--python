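"""End-to-end pipeline: simulate → scan → correct → network → linkage → anova.

A single YAML/TOML-style mapping configures every stage; one master seed
fans out to per-stage child seeds by a documented derivation
(``SeedSequence([seed, stage_index])``) so stages can be rerun
independently.  Every run directory contains the input echo, per-stage
outputs, a JSON manifest sufficient to reproduce the run, and a log with
one line per stage.
"""

from __future__ import annotations

import json
import logging
import os
import platform
from dataclasses import asdict
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corrstats import anova_screen
from .datatypes import Group
from .dataset import LongitudinalDataset
from .interactome import (
    bonferroni_correct,
    build_network,
    export_network,
    hub_ranking,
    repeated_scan,
)
from .io import write_dataset, write_edges
from .linkage import (
    deltas_to_frame,
    differential_linkage,
    intra_parameter_scan,
    intra_to_frame,
    linkage_matrix,
)
from .simulate import SimConfig, config_to_dict, generate_cohort

STAGES = ("simulate", "scan", "correct", "network", "linkage", "intra", "anova")

_STAGE_KEYS: dict[str, set[str]] = {
    "simulate": {f for f in SimConfig.__dataclass_fields__} - {"seed"},
    "scan": {"alpha", "group", "normality_alpha", "require_sign_consistency",
             "fail_fast"},
    "correct": {"family_alpha", "method", "m"},
    "network": {"corrected_only"},
    "linkage": {"groups", "threshold", "mode", "variables", "include_baseline",
                "alpha", "collapse"},
    "intra": {"alpha", "group"},
    "anova": {"alpha", "variables"},
}
_TOP_KEYS = {"seed", "stages"} | set(STAGES)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_config(cfg: dict[str, Any]) -> dict[str, Any]:
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "seed" not in cfg:
        raise ValueError("config must set 'seed'")
    stages = cfg.get("stages", list(STAGES))
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stage(s): {bad}")
    for stage in STAGES:
        section = cfg.get(stage, {})
        if section is None:
            continue
        if not isinstance(section, dict):
            raise ValueError(f"config section {stage!r} must be a mapping")
        unknown = set(section) - _STAGE_KEYS[stage]
        if unknown:
            raise ValueError(
                f"unknown key(s) in section {stage!r}: {sorted(unknown)}"
            )
    return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([master_seed, idx]).generate_state(1)[0]
               % (2 ** 31))


def load_config(path: str | os.PathLike) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        return validate_config(yaml.safe_load(fh))


def run_pipeline(
    config: dict[str, Any] | str | os.PathLike,
    outdir: str | os.PathLike,
    dataset: LongitudinalDataset | None = None,
) -> dict[str, Any]:
    """Run the configured stages, writing all artifacts into ``outdir``.

    Returns the manifest.  An external ``dataset`` replaces the simulate
    stage (real data instead of a synthetic cohort).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = validate_config(config)
    os.makedirs(outdir, exist_ok=True)
    log_path = os.path.join(outdir, "pipeline.log")
    logger = logging.getLogger("rbclink.pipeline")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    seed = int(config["seed"])
    stages = list(config.get("stages", STAGES))
    manifest: dict[str, Any] = {
        "rbclink_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "seed_derivation": "SeedSequence([seed, stage_index]) % 2**31",
        "stages": stages,
        "parameters": {},
        "outputs": {},
    }
    with open(os.path.join(outdir, "config_echo.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    def out(name: str) -> str:
        return os.path.join(outdir, name)

    truth = None
    edges = None
    corrected = None
    net = None
    current = "?"
    try:
        if "simulate" in stages:
            current = "simulate"
            sim_kwargs = dict(config.get("simulate") or {})
            sim_cfg = SimConfig(seed=stage_seed(seed, "simulate"), **sim_kwargs)
            dataset, truth = generate_cohort(sim_cfg)
            write_dataset(dataset, out("dataset_long.csv"), format="long")
            truth.write(outdir)
            manifest["parameters"]["simulate"] = config_to_dict(sim_cfg)
            manifest["outputs"]["dataset"] = "dataset_long.csv"
            logger.info("simulate: %d variables x %d samples",
                        dataset.n_variables(), dataset.n_samples())
        if dataset is None:
            raise ValueError("no dataset: enable the simulate stage or pass one")

        if "scan" in stages:
            current = "scan"
            kw = dict(config.get("scan") or {})
            alpha = kw.pop("alpha", 0.01)
            edges = repeated_scan(dataset, alpha=alpha, **kw)
            n_pass = sum(e.passes_raw for e in edges)
            write_edges(edges, out("edges_raw.tsv"),
                        timepoints=dataset.storage_timepoints())
            manifest["parameters"]["scan"] = {"alpha": alpha, **{
                k: (v.value if isinstance(v, Group) else v) for k, v in kw.items()}}
            manifest["outputs"]["edges_raw"] = "edges_raw.tsv"
            logger.info("scan: %d candidate pairs, %d pass the repeated filter",
                        len(edges), n_pass)

        if "correct" in stages:
            current = "correct"
            if edges is None:
                raise ValueError("correct stage requires the scan stage")
            kw = dict(config.get("correct") or {})
            m = int(kw.pop("m", len(edges)))
            corrected = bonferroni_correct(edges, m=m, **kw)
            write_edges(corrected, out("edges_corrected.tsv"),
                        timepoints=dataset.storage_timepoints())
            n_corr = sum(e.passes_corrected for e in corrected)
            manifest["parameters"]["correct"] = {
                "m": m,
                "family_alpha": kw.get("family_alpha", 0.05),
                "method": kw.get("method", "max-p"),
            }
            manifest["outputs"]["edges_corrected"] = "edges_corrected.tsv"
            logger.info("correct: %d of %d raw edges survive (m=%d)",
                        n_corr, sum(e.passes_raw for e in corrected), m)

        if "network" in stages:
            current = "network"
            source = corrected if corrected is not None else edges
            if source is None:
                raise ValueError("network stage requires the scan stage")
            kw = dict(config.get("network") or {})
            net = build_network(source, variables=dataset.variables,
                                metadata={"seed": seed}, **kw)
            export_network(net, out("network.graphml"), format="graphml")
            export_network(net, out("network.sif"), format="sif")
            pd.DataFrame(hub_ranking(net), columns=["node", "degree"]).to_csv(
                out("hubs.tsv"), sep="\t", index=False)
            manifest["parameters"]["network"] = kw
            manifest["outputs"]["network"] = ["network.graphml", "network.sif",
                                              "hubs.tsv"]
            logger.info("network: %d nodes, %d edges", net.n_nodes, net.n_edges)

        if "linkage" in stages:
            current = "linkage"
            kw = dict(config.get("linkage") or {})
            groups = [Group(g) for g in kw.pop("groups",
                                               ["deficient", "sufficient"])]
            threshold = kw.pop("threshold", 0.30)
            mode = kw.pop("mode", "abs_magnitude")
            variables = kw.pop("variables", None)
            mats = [linkage_matrix(dataset, g, variables, **kw) for g in groups]
            for g, mat in zip(groups, mats):
                mat.r.to_csv(out(f"linkage_r_{g.value}.csv"))
            deltas = differential_linkage(mats[0], mats[1],
                                          threshold=threshold, mode=mode)
            deltas_to_frame(deltas).to_csv(out("linkage_deltas.tsv"),
                                           sep="\t", index=False)
            manifest["parameters"]["linkage"] = {
                "groups": [g.value for g in groups],
                "threshold": threshold, "mode": mode,
            }
            manifest["outputs"]["linkage"] = "linkage_deltas.tsv"
            logger.info("linkage: %d pairs, %d rewired at delta > %.2f",
                        len(deltas), sum(d.rewired for d in deltas), threshold)

        if "intra" in stages:
            current = "intra"
            kw = dict(config.get("intra") or {})
            intra = intra_parameter_scan(dataset, **kw)
            intra_to_frame(intra).to_csv(out("intra.tsv"), sep="\t", index=False)
            manifest["outputs"]["intra"] = "intra.tsv"
            logger.info("intra: %d variables scanned, %d donor-signatures",
                        len(intra),
                        sum(r.all_timepoints_significant for r in intra))

        if "anova" in stages:
            current = "anova"
            kw = dict(config.get("anova") or {})
            table = anova_screen(dataset, **kw)
            table.to_csv(out("anova.tsv"), sep="\t", index=False)
            manifest["outputs"]["anova"] = "anova.tsv"
            if "sig_group" in table.columns:
                logger.info("anova: %d variables, %d with group effect",
                            len(table), int(table["sig_group"].sum()))
    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        logger.error("stage %s failed: %s", current, exc)
        handler.close()
        logger.removeHandler(handler)
        raise PipelineStageError(current, exc) from exc

    with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("pipeline complete")
    handler.close()
    logger.removeHandler(handler)
    return manifest
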