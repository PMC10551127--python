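"""Simulation studies validating the pipeline's error control and power.

These run many seeded synthetic cohorts through the real pipeline and
measure:

* family-wise type-I error of the max-statistic global-metric test and
  of NBS on null cohorts (no injected group difference, covariates
  present);
* recovery of an injected within-network block decrease by the block-FC
  test and of an injected connected edge component by NBS;
* the false-positive rate of the covariate-controlled clinical scan when
  scores and network indices are uncoupled.

Cohort sizes default to a scaled-down study (40 parcels, 20+20 subjects,
1,000 permutations) so hundreds of replicates run on one CPU in minutes;
the group sizes for the recovery studies match the study design (35/40).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .blocks import block_group_test, block_table
from .clinical import assoc_scan
from .connectivity import build_fc_matrix
from .graph_metrics import DensityGrid, GLOBAL_METRIC_NAMES, compute_cohort_metrics
from .io_core import Atlas, COVARIATE_COLUMNS
from .nbs import NBSConfig, nbs_test
from .perm_glm import family_test, make_design
from .synthetic import CohortSpec, demo_atlas, sample_cohort


def _cohort_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


def _run_cohort(spec: CohortSpec, lam: float = 1.0):
    series, pheno, truth = sample_cohort(spec)
    fcs = [build_fc_matrix(ts, lam=lam) for ts in series]
    design = make_design(pheno, [ts.subject_id for ts in series])
    return fcs, pheno, design, truth


@dataclasses.dataclass(frozen=True)
class TypeIResult:
    global_false_positives: int
    nbs_false_positives: int
    n_cohorts: int

    @property
    def global_rate(self) -> float:
        return self.global_false_positives / self.n_cohorts

    @property
    def nbs_rate(self) -> float:
        return self.nbs_false_positives / self.n_cohorts


def type_one_error_study(
    n_cohorts: int = 200,
    seed: int = 0,
    n_parcels: int = 40,
    n_per_group: int = 20,
    n_timepoints: int = 170,
    n_perm: int = 1000,
    n_null: int = 3,
    alpha: float = 0.05,
    run_global: bool = True,
    run_nbs: bool = True,
) -> TypeIResult:
    """Family-wise false-positive counts over null cohorts.

    A cohort is a global false positive if any of the 8 AUC metrics has
    max-stat corrected p <= alpha, and an NBS false positive if any
    component in either direction reaches p < 0.025.
    """
    atlas = demo_atlas(n_parcels)
    grid = DensityGrid()
    seeds = _cohort_seeds(seed, 3 * n_cohorts).reshape(n_cohorts, 3)
    fp_global = 0
    fp_nbs = 0
    for k in range(n_cohorts):
        spec = CohortSpec(
            atlas=atlas,
            n_patients=n_per_group,
            n_controls=n_per_group,
            n_timepoints=n_timepoints,
            seed=int(seeds[k, 0]),
        )
        fcs, _, design, _ = _run_cohort(spec)
        if run_global:
            metrics = compute_cohort_metrics(
                fcs, grid, n_null=n_null, seed=int(seeds[k, 1]), include_nodal=False
            )
            res = family_test(
                metrics.global_auc.to_numpy(),
                design,
                list(GLOBAL_METRIC_NAMES),
                n_perm=n_perm,
                seed=int(seeds[k, 1]),
            )
            if (res.table["p_corr"].dropna() <= alpha).any():
                fp_global += 1
        if run_nbs:
            result = nbs_test(
                fcs, design, NBSConfig(n_perm=n_perm, seed=int(seeds[k, 2]))
            )
            if result.significant():
                fp_nbs += 1
    return TypeIResult(fp_global, fp_nbs, n_cohorts)


def block_recovery_study(
    n_runs: int = 100,
    delta_r: float = -0.2,
    network: str = "LN",
    seed: int = 0,
    n_parcels: int = 40,
    n_patients: int = 35,
    n_controls: int = 40,
    n_timepoints: int = 170,
    n_perm: int = 1000,
    alpha: float = 0.05,
) -> float:
    """Fraction of runs where the injected within-network block reaches
    FDR q < alpha in the 28-block test."""
    atlas = demo_atlas(n_parcels)
    seeds = _cohort_seeds(seed, 2 * n_runs).reshape(n_runs, 2)
    hits = 0
    target = f"{network}-{network}"
    for k in range(n_runs):
        spec = CohortSpec(
            atlas=atlas,
            n_patients=n_patients,
            n_controls=n_controls,
            n_timepoints=n_timepoints,
            effect_blocks=[(network, network, delta_r)],
            seed=int(seeds[k, 0]),
        )
        fcs, _, design, _ = _run_cohort(spec)
        res = block_group_test(
            block_table(fcs, atlas), design, n_perm=n_perm, seed=int(seeds[k, 1])
        )
        row = res.table.set_index("outcome").loc[target]
        if row["q"] < alpha:
            hits += 1
    return hits / n_runs


def planted_component(atlas: Atlas, n_edges: int = 20) -> list[tuple[int, int]]:
    """A deterministic connected set of edges spanning two networks.

    Nodes are taken from the LN and SMN systems; a spanning path makes
    the edge set connected and extra chords top it up to ``n_edges``.
    """
    nodes = list(atlas.network_indices("LN")) + list(atlas.network_indices("SMN"))
    edges: list[tuple[int, int]] = []
    for a, b in zip(nodes, nodes[1:]):  # spanning path: connectivity guarantee
        edges.append((min(a, b), max(a, b)))
        if len(edges) == n_edges:
            return edges
    for step in range(2, len(nodes)):
        for i in range(len(nodes) - step):
            a, b = nodes[i], nodes[i + step]
            edges.append((min(a, b), max(a, b)))
            if len(edges) == n_edges:
                return edges
    raise ValueError(f"not enough node pairs for {n_edges} edges")


def nbs_recovery_study(
    n_runs: int = 50,
    delta_z: float = 0.35,
    n_edges: int = 20,
    seed: int = 0,
    n_parcels: int = 40,
    n_patients: int = 35,
    n_controls: int = 40,
    n_timepoints: int = 170,
    n_perm: int = 1000,
    overlap_threshold: float = 0.8,
) -> float:
    """Fraction of runs where significant NBS components recover at least
    ``overlap_threshold`` of the injected edges.

    The injected effect raises each planted edge's correlation by
    tanh(arctanh(r) + delta_z) - r, i.e. a shift of ``delta_z`` on the
    Fisher-z scale of the generating correlation.
    """
    atlas = demo_atlas(n_parcels)
    edges = planted_component(atlas, n_edges)
    seeds = _cohort_seeds(seed, 2 * n_runs).reshape(n_runs, 2)
    hits = 0
    for k in range(n_runs):
        spec0 = CohortSpec(atlas=atlas, seed=0)
        base = np.where(
            atlas.network_labels[[e[0] for e in edges]]
            == atlas.network_labels[[e[1] for e in edges]],
            spec0.base_within_block_r,
            spec0.base_between_block_r,
        )
        deltas = np.tanh(np.arctanh(base) + delta_z) - base
        spec = CohortSpec(
            atlas=atlas,
            n_patients=n_patients,
            n_controls=n_controls,
            n_timepoints=n_timepoints,
            effect_edges=[(i, j, float(d)) for (i, j), d in zip(edges, deltas)],
            seed=int(seeds[k, 0]),
        )
        fcs, _, design, _ = _run_cohort(spec)
        result = nbs_test(
            fcs, design, NBSConfig(n_perm=n_perm, seed=int(seeds[k, 1]))
        )
        found = set()
        for comp in result.significant("hyper"):
            found.update(comp.edges)
        overlap = len(found & set(edges)) / len(edges)
        if overlap >= overlap_threshold:
            hits += 1
    return hits / n_runs


def clinical_null_study(
    n_runs: int = 100,
    seed: int = 0,
    n_parcels: int = 40,
    n_patients: int = 35,
    n_timepoints: int = 170,
    alpha: float = 0.05,
) -> float:
    """Fraction of runs with zero FDR-significant (index, score) pairs
    when network indices and clinical scores are generated uncoupled.

    Indices are the 28 block-FC values of the patient group (cheap to
    compute and exactly as many outcomes as the block family), scores
    are the three clinical scales; covariates are partialled out.
    """
    atlas = demo_atlas(n_parcels)
    seeds = _cohort_seeds(seed, n_runs)
    clean = 0
    for k in range(n_runs):
        spec = CohortSpec(
            atlas=atlas,
            n_patients=n_patients,
            n_controls=2,  # controls unused by the scan; keep the cohort tiny
            n_timepoints=n_timepoints,
            seed=int(seeds[k]),
        )
        series, pheno, _ = sample_cohort(spec)
        patients = pheno.table["group"] == "patient"
        fcs = [
            build_fc_matrix(ts)
            for ts, pat in zip(series, patients)
            if pat
        ]
        blocks = block_table(fcs, atlas)
        ptab = pheno.table[patients.to_numpy()]
        res = assoc_scan(
            blocks.reset_index(drop=True),
            ptab[["sas", "sds", "wexner"]].reset_index(drop=True),
            ptab[list(COVARIATE_COLUMNS)].reset_index(drop=True),
        )
        if not (res["q"] < alpha).any():
            clean += 1
    return clean / n_runs


def clinical_power_study(
    n_runs: int = 100,
    target_r: float = 0.6,
    seed: int = 0,
    n_patients: int = 35,
    alpha: float = 0.05,
) -> float:
    """Fraction of runs detecting (q < alpha) a planted index-score coupling.

    A single network index is generated and one score is built as
    index + noise with population correlation ``target_r``; two further
    uncoupled scores complete the scan family.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    lam = np.sqrt(target_r**2 / (1 - target_r**2))
    for _ in range(n_runs):
        index = rng.standard_normal(n_patients)
        scores = {
            "sas": lam * index + rng.standard_normal(n_patients),
            "sds": rng.standard_normal(n_patients),
            "wexner": rng.standard_normal(n_patients),
        }
        res = assoc_scan(
            pd.DataFrame({"index": index}),
            pd.DataFrame(scores),
            rng.standard_normal((n_patients, 4)),
        )
        if (res.loc[res["score"] == "sas", "q"] < alpha).any():
            hits += 1
    return hits / n_runs
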