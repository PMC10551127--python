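"""Seeded two-group synthetic cohorts with block-structured covariance.

The generator emulates the structure of a resting-state case/control study:
two groups (default 35 patients, 40 controls), ~170 retained volumes at
TR = 2 s, parcels labeled with the Yeo-7 systems, an inter-parcel
correlation matrix that is block-structured by network membership
(within-network coupling stronger than between-network), AR(1) temporal
autocorrelation standing in for band-passed BOLD, matched nuisance
covariates (age, sex, mean framewise displacement, cortex volume) and
clinical scores (SAS/SDS both groups, Wexner patients only).

Group differences are injected either on single edges (``effect_edges``)
or on whole network blocks (``effect_blocks``), applied to the patient
group's target correlation matrix; the truth record reports exactly what
was injected so downstream inference can be scored against ground truth.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import (
    Atlas,
    PhenotypeTable,
    TimeSeriesSet,
    ValidationError,
    YEO7_NETWORKS,
)

_PD_EIG_FLOOR = 1e-6


@dataclasses.dataclass(frozen=True)
class CovariateModel:
    """Distributions of the four nuisance covariates and clinical scores.

    Defaults reproduce the study cohort's demographics: ages ~47/45 y,
    mostly female, framewise displacement log-normal around 0.055 mm,
    total cortical gray volume ~5e5 mm^3, SAS/SDS elevated in patients,
    Wexner score recorded for patients only.
    """

    age_mean_patient: float = 47.2
    age_sd_patient: float = 12.8
    age_mean_control: float = 45.1
    age_sd_control: float = 13.1
    male_prop_patient: float = 6 / 35
    male_prop_control: float = 13 / 40
    fd_log_mean: float = -2.90  # log(0.055 mm)
    fd_log_sd: float = 0.44
    cortex_volume_mean: float = 5.0e5  # mm^3
    cortex_volume_sd: float = 5.0e4
    sas_mean_patient: float = 49.8
    sas_sd_patient: float = 7.2
    sas_mean_control: float = 35.1
    sas_sd_control: float = 9.0
    sds_mean_patient: float = 53.1
    sds_sd_patient: float = 9.0
    sds_mean_control: float = 36.9
    sds_sd_control: float = 12.1
    wexner_mean: float = 13.5
    wexner_sd: float = 4.3


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Everything needed to draw one synthetic cohort reproducibly."""

    atlas: Atlas
    n_patients: int = 35
    n_controls: int = 40
    n_timepoints: int = 170
    tr_seconds: float = 2.0
    base_within_block_r: float = 0.4
    base_between_block_r: float = 0.1
    effect_edges: Sequence[tuple[int, int, float]] = ()  # 0-based node pairs
    effect_blocks: Sequence[tuple[str, str, float]] = ()
    covariates: CovariateModel = CovariateModel()
    temporal_smoothing: float = 0.3  # AR(1) coefficient
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.base_within_block_r < 1:
            raise ValidationError("base_within_block_r must be in [0, 1)")
        if not -1 < self.base_between_block_r < 1:
            raise ValidationError("base_between_block_r must be in (-1, 1)")
        if not 0 <= self.temporal_smoothing < 1:
            raise ValidationError("temporal_smoothing (AR(1) coef) must be in [0, 1)")
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValidationError("both groups must be non-empty")
        if self.n_timepoints < 30:
            raise ValidationError("n_timepoints must be >= 30")
        for a, b, _ in self.effect_blocks:
            for net in (a, b):
                if net not in YEO7_NETWORKS:
                    raise ValidationError(f"unknown network {net!r} in effect_blocks")


@dataclasses.dataclass(frozen=True)
class CohortTruth:
    """Ground truth of one sampled cohort."""

    target_r_patient: np.ndarray
    target_r_control: np.ndarray
    effect_edges: tuple[tuple[int, int, float], ...]
    effect_blocks: tuple[tuple[str, str, float], ...]
    pd_repaired: dict[str, bool]
    seed: int


def _nearest_pd(r: np.ndarray) -> tuple[np.ndarray, bool]:
    """Eigenvalue-clip a symmetric matrix to positive definiteness.

    Eigenvalues below the floor are raised to it and the diagonal is
    re-normalized to 1 so the result stays a correlation matrix.
    """
    w, v = np.linalg.eigh(r)
    if w.min() > _PD_EIG_FLOOR:
        return r, False
    w = np.clip(w, _PD_EIG_FLOOR, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed, True


def build_target_covariance(spec: CohortSpec, group: str) -> tuple[np.ndarray, bool]:
    """Unit-variance target correlation matrix for one group.

    Within-network off-diagonals get ``base_within_block_r``, between-network
    entries ``base_between_block_r``; for the patient group the requested
    edge/block deltas are added, clipped to |r| <= 0.95, then repaired to
    positive definiteness by eigenvalue clipping if needed.

    Returns (matrix, repaired_flag).
    """
    if group not in ("patient", "control"):
        raise ValidationError(f"unknown group {group!r}")
    labels = spec.atlas.network_labels
    same = labels[:, None] == labels[None, :]
    r = np.where(same, spec.base_within_block_r, spec.base_between_block_r)
    np.fill_diagonal(r, 1.0)
    if group == "patient":
        for net_a, net_b, delta in spec.effect_blocks:
            ia = spec.atlas.network_indices(net_a)
            ib = spec.atlas.network_indices(net_b)
            mask = np.zeros_like(r, dtype=bool)
            mask[np.ix_(ia, ib)] = True
            mask[np.ix_(ib, ia)] = True
            np.fill_diagonal(mask, False)
            r = np.where(mask, r + delta, r)
        for i, j, delta in spec.effect_edges:
            if i == j:
                raise ValidationError("effect_edges must reference distinct nodes")
            r[i, j] += delta
            r[j, i] += delta
    off = ~np.eye(len(r), dtype=bool)
    r[off] = np.clip(r[off], -0.95, 0.95)
    r = (r + r.T) / 2
    min_eig = np.linalg.eigvalsh(r).min()
    if min_eig < -0.5:
        raise ValidationError(
            f"injected effects make the target correlation grossly indefinite "
            f"(minimum eigenvalue {min_eig:.3f})"
        )
    r, repaired = _nearest_pd(r)
    return r, repaired


def _draw_series(
    rng: np.random.Generator, chol: np.ndarray, n_t: int, phi: float
) -> np.ndarray:
    """T x N Gaussian series with target spatial covariance and AR(1) rows.

    x_t = phi * x_{t-1} + sqrt(1-phi^2) * e_t keeps the stationary marginal
    covariance equal to the target for every t; phi = 0 reduces exactly to
    i.i.d. rows (same draws from the same generator state).
    """
    n = chol.shape[0]
    e = rng.standard_normal((n_t, n)) @ chol.T
    if phi == 0.0:
        return e
    x = np.empty_like(e)
    x[0] = e[0]
    scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, n_t):
        x[t] = phi * x[t - 1] + scale * e[t]
    return x


def _draw_phenotypes(
    rng: np.random.Generator, spec: CohortSpec, subject_ids: list[str], groups: list[str]
) -> PhenotypeTable:
    cm = spec.covariates
    rows = []
    for sid, grp in zip(subject_ids, groups):
        pat = grp == "patient"
        age = rng.normal(
            cm.age_mean_patient if pat else cm.age_mean_control,
            cm.age_sd_patient if pat else cm.age_sd_control,
        )
        sex = int(rng.random() < (cm.male_prop_patient if pat else cm.male_prop_control))
        fd = float(np.exp(rng.normal(cm.fd_log_mean, cm.fd_log_sd)))
        vol = rng.normal(cm.cortex_volume_mean, cm.cortex_volume_sd)
        sas = rng.normal(
            cm.sas_mean_patient if pat else cm.sas_mean_control,
            cm.sas_sd_patient if pat else cm.sas_sd_control,
        )
        sds = rng.normal(
            cm.sds_mean_patient if pat else cm.sds_mean_control,
            cm.sds_sd_patient if pat else cm.sds_sd_control,
        )
        wex = rng.normal(cm.wexner_mean, cm.wexner_sd) if pat else np.nan
        rows.append(
            dict(
                subject_id=sid,
                group=grp,
                age=float(np.clip(age, 18, 90)),
                sex=sex,
                mean_fd=fd,
                cortex_volume=float(vol),
                sas=float(sas),
                sds=float(sds),
                wexner=float(wex) if pat else np.nan,
            )
        )
    return PhenotypeTable(pd.DataFrame(rows))


def sample_cohort(
    spec: CohortSpec,
) -> tuple[list[TimeSeriesSet], PhenotypeTable, CohortTruth]:
    """Draw the full cohort: time series, phenotypes and the truth record."""
    rng = np.random.default_rng(spec.seed)
    r_pat, rep_pat = build_target_covariance(spec, "patient")
    r_con, rep_con = build_target_covariance(spec, "control")
    chol = {"patient": np.linalg.cholesky(r_pat), "control": np.linalg.cholesky(r_con)}

    n_pat, n_con = spec.n_patients, spec.n_controls
    width = len(str(n_pat + n_con))
    subject_ids = [f"sub-P{i + 1:0{width}d}" for i in range(n_pat)] + [
        f"sub-C{i + 1:0{width}d}" for i in range(n_con)
    ]
    groups = ["patient"] * n_pat + ["control"] * n_con

    series = [
        TimeSeriesSet(
            subject_id=sid,
            data=_draw_series(rng, chol[grp], spec.n_timepoints, spec.temporal_smoothing),
            tr_seconds=spec.tr_seconds,
        )
        for sid, grp in zip(subject_ids, groups)
    ]
    pheno = _draw_phenotypes(rng, spec, subject_ids, groups)
    truth = CohortTruth(
        target_r_patient=r_pat,
        target_r_control=r_con,
        effect_edges=tuple(spec.effect_edges),
        effect_blocks=tuple(spec.effect_blocks),
        pd_repaired={"patient": rep_pat, "control": rep_con},
        seed=spec.seed,
    )
    return series, pheno, truth


def demo_atlas(n_parcels: int = 14, parcels_per_network: Sequence[int] | None = None) -> Atlas:
    """Build a synthetic Yeo-7 atlas with ``n_parcels`` parcels.

    Parcels are dealt to the 7 networks as evenly as possible (each gets at
    least 2), alternating hemispheres. This is a generator for tests and
    simulations, not a real parcellation lookup table.
    """
    if parcels_per_network is None:
        base, extra = divmod(n_parcels, 7)
        if base < 2:
            raise ValidationError("need at least 14 parcels (2 per network)")
        parcels_per_network = [base + (1 if k < extra else 0) for k in range(7)]
    rows = []
    pid = 1
    for net, count in zip(YEO7_NETWORKS, parcels_per_network):
        for k in range(count):
            hemi = "L" if k % 2 == 0 else "R"
            rows.append(
                dict(
                    parcel_id=pid,
                    parcel_name=f"{net}_{hemi}_{k + 1}",
                    hemisphere=hemi,
                    network=net,
                )
            )
            pid += 1
    return Atlas(pd.DataFrame(rows))
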