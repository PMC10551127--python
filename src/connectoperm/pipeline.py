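"""End-to-end orchestration: simulate -> connectivity -> graph metrics ->
group permutation tests -> NBS -> network blocks -> clinical association.

A single :class:`RunConfig` (YAML-serializable) drives the run. One
master seed deterministically derives a seed per stage through a fixed
spawn-key scheme, so a rerun with the same config reproduces every
artifact byte-for-byte and partial reruns stay consistent.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blocks import block_group_test, block_table
from .clinical import assoc_scan
from .connectivity import build_fc_matrix
from .graph_metrics import (
    DEFAULT_N_NULL,
    DensityGrid,
    GLOBAL_METRIC_NAMES,
    NODAL_METRIC_NAMES,
    compute_cohort_metrics,
)
from .io_core import (
    Atlas,
    COVARIATE_COLUMNS,
    write_matrix,
    write_phenotypes,
    write_results,
    write_timeseries,
)
from .nbs import NBSConfig, nbs_test, network_pair_tally
from .perm_glm import family_test, make_design
from .synthetic import CohortSpec, demo_atlas, sample_cohort

log = logging.getLogger("connectoperm")

_STAGES = ("simulate", "connectivity", "graph", "gtest", "nbs", "blocks", "assoc")


@dataclasses.dataclass
class RunConfig:
    """Pipeline settings; defaults are the study's stated analysis choices."""

    out_dir: str = "run_out"
    seed: int = 0
    # cohort
    n_parcels: int = 400
    n_patients: int = 35
    n_controls: int = 40
    n_timepoints: int = 170
    effect_blocks: list = dataclasses.field(default_factory=list)
    effect_edges: list = dataclasses.field(default_factory=list)
    # connectivity
    method: str = "tikhonov_partial"
    lam: float = 1.0
    # graph
    density_percents: list = dataclasses.field(
        default_factory=lambda: list(range(10, 35))
    )
    n_null: int = DEFAULT_N_NULL
    # inference
    n_perm: int = 10_000
    nbs_primary_alpha: float = 0.001
    nbs_component_alpha: float = 0.025
    fdr_alpha: float = 0.05
    stages: list = dataclasses.field(default_factory=lambda: list(_STAGES))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from the master seed."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: RunConfig, atlas: Atlas | None = None) -> dict[str, Path]:
    """Execute the enabled stages in order; returns the written artifacts."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = atlas or demo_atlas(config.n_parcels)
    grid = DensityGrid(tuple(config.density_percents))
    enabled = [s for s in _STAGES if s in config.stages]
    timings: dict[str, float] = {}
    tables: dict[str, pd.DataFrame] = {}

    def _stage(name: str) -> bool:
        return name in enabled

    # --- simulate -----------------------------------------------------
    t0 = time.time()
    spec = CohortSpec(
        atlas=atlas,
        n_patients=config.n_patients,
        n_controls=config.n_controls,
        n_timepoints=config.n_timepoints,
        effect_edges=[tuple(e) for e in config.effect_edges],
        effect_blocks=[tuple(b) for b in config.effect_blocks],
        seed=stage_seed(config.seed, "simulate"),
    )
    series, pheno, truth = sample_cohort(spec)
    if _stage("simulate"):
        ts_dir = out / "timeseries"
        for ts in series:
            write_timeseries(ts, ts_dir, atlas)
        write_phenotypes(pheno, out / "phenotypes.tsv")
        atlas.table.to_csv(out / "atlas.tsv", sep="\t", index=False)
    timings["simulate"] = time.time() - t0
    log.info("simulate: %d subjects in %.1fs", len(series), timings["simulate"])

    design = make_design(pheno, [ts.subject_id for ts in series])

    # --- connectivity -------------------------------------------------
    t0 = time.time()
    fcs = [build_fc_matrix(ts, method=config.method, lam=config.lam) for ts in series]
    if _stage("connectivity"):
        fc_dir = out / "fc"
        fc_dir.mkdir(exist_ok=True)
        for fc in fcs:
            write_matrix(fc.z, fc_dir / f"{fc.subject_id}.tsv", atlas.parcel_ids)
    timings["connectivity"] = time.time() - t0
    log.info("connectivity: %s (lambda=%g) in %.1fs", config.method, config.lam,
             timings["connectivity"])

    # --- graph metrics + group tests ---------------------------------
    metrics = None
    if _stage("graph") or _stage("gtest") or _stage("assoc"):
        t0 = time.time()
        metrics = compute_cohort_metrics(
            fcs, grid, n_null=config.n_null, seed=stage_seed(config.seed, "graph"),
            include_nodal=True,
        )
        tables["metrics_global_auc"] = metrics.global_auc.reset_index(names="subject_id")
        timings["graph"] = time.time() - t0
        log.info("graph metrics: %d densities in %.1fs", len(grid), timings["graph"])

    if _stage("gtest") and metrics is not None:
        t0 = time.time()
        gseed = stage_seed(config.seed, "gtest")
        res_global = family_test(
            metrics.global_auc.to_numpy(),
            design,
            list(GLOBAL_METRIC_NAMES),
            n_perm=config.n_perm,
            seed=gseed,
        )
        tables["perm_global"] = res_global.table
        nodal_frames = []
        for mi, mname in enumerate(NODAL_METRIC_NAMES):
            df = metrics.nodal_auc[mname]
            res = family_test(
                df.to_numpy(),
                design,
                [str(c + 1) for c in range(df.shape[1])],
                n_perm=config.n_perm,
                seed=gseed + 1 + mi,
            )
            frame = res.table.rename(columns={"outcome": "parcel_id"})
            frame.insert(0, "metric", mname)
            nodal_frames.append(frame)
        tables["perm_nodal"] = pd.concat(nodal_frames, ignore_index=True)
        timings["gtest"] = time.time() - t0
        log.info("gtest: %d permutations in %.1fs", config.n_perm, timings["gtest"])

    # --- NBS ----------------------------------------------------------
    nbs_result = None
    if _stage("nbs"):
        t0 = time.time()
        nbs_result = nbs_test(
            fcs,
            design,
            NBSConfig(
                primary_alpha=config.nbs_primary_alpha,
                component_alpha=config.nbs_component_alpha,
                n_perm=config.n_perm,
                seed=stage_seed(config.seed, "nbs"),
            ),
        )
        tables["nbs_edges"] = nbs_result.edge_table(atlas)
        tables["nbs_network_tally"] = network_pair_tally(nbs_result, atlas)
        timings["nbs"] = time.time() - t0
        log.info("nbs: %d significant components in %.1fs",
                 len(nbs_result.significant()), timings["nbs"])

    # --- network blocks ----------------------------------------------
    block_res = None
    blocks_df = None
    if _stage("blocks"):
        t0 = time.time()
        blocks_df = block_table(fcs, atlas)
        block_res = block_group_test(
            blocks_df, design, n_perm=config.n_perm,
            seed=stage_seed(config.seed, "blocks"),
        )
        tables["blocks_fc"] = blocks_df.reset_index(names="subject_id")
        tables["perm_blocks"] = block_res.table
        timings["blocks"] = time.time() - t0
        log.info("blocks: 28 values in %.1fs", timings["blocks"])

    # --- clinical association ----------------------------------------
    if _stage("assoc") and metrics is not None:
        t0 = time.time()
        patient_mask = np.array(
            [g == "patient" for g in pheno.aligned_to(list(design.subject_ids)).table["group"]]
        )
        indices = metrics.global_auc.loc[patient_mask].copy()
        if block_res is not None and blocks_df is not None:
            sig = block_res.table.loc[
                block_res.table["q"] < config.fdr_alpha, "outcome"
            ]
            for name in sig:
                indices[f"block_{name}"] = blocks_df.loc[patient_mask, name].to_numpy()
        ptable = pheno.aligned_to(list(design.subject_ids)).table[patient_mask]
        scores = ptable[["sas", "sds", "wexner"]]
        covs = ptable[list(COVARIATE_COLUMNS)]
        tables["assoc"] = assoc_scan(indices, scores, covs)
        timings["assoc"] = time.time() - t0
        log.info("assoc: %d pairs in %.1fs", len(tables["assoc"]), timings["assoc"])

    metadata = {
        "software": f"connectoperm {__version__}",
        "config": config.to_dict(),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in enabled},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "n_subjects": len(series),
        "pd_repaired": truth.pd_repaired,
        "total_wall_s": round(time.time() - t_start, 3),
    }
    return write_results(tables, out, metadata)
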