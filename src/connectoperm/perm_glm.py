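"""Covariate-adjusted group inference by permutation.

This is the shared inference engine: an OLS linear model with the group
indicator as the tested contrast and age, sex, mean framewise
displacement and cortex volume as nuisance covariates; Freedman-Lane
residual permutation to build the null (residualize the outcomes on the
nuisance model, permute the residual rows, refit the full model); the
max-statistic over each outcome family for family-wise control; and
Benjamini-Hochberg FDR. P-values use the add-one convention
(1 + #{null >= observed}) / (n_perm + 1), so they are never zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_core import COVARIATE_COLUMNS, PhenotypeTable, ValidationError

DESIGN_COLUMNS = ("intercept", "group") + COVARIATE_COLUMNS


@dataclasses.dataclass(frozen=True)
class DesignMatrix:
    """n_subjects x p design; the group indicator is the tested contrast."""

    X: np.ndarray
    columns: tuple[str, ...]
    contrast: int  # index of the tested column
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        x = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", x)
        if x.ndim != 2 or x.shape[1] != len(self.columns):
            raise ValidationError("design shape does not match column names")
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            # name the collinear columns for the error message
            bad = []
            for j in range(x.shape[1]):
                others = np.delete(x, j, axis=1)
                if np.linalg.matrix_rank(others) == rank:
                    bad.append(self.columns[j])
            raise ValidationError(
                f"design matrix is rank deficient; collinear columns: {bad}"
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def rank(self) -> int:
        return self.X.shape[1]

    @property
    def df_resid(self) -> int:
        return self.n - self.rank


def make_design(
    pheno: PhenotypeTable, subject_order: list[str] | None = None
) -> DesignMatrix:
    """Intercept + group (patient = 1) + the four nuisance covariates."""
    t = pheno.table
    if subject_order is not None:
        t = pheno.aligned_to(subject_order).table
    n = len(t)
    X = np.column_stack(
        [
            np.ones(n),
            (t["group"] == "patient").to_numpy(float),
            *(t[c].to_numpy(float) for c in COVARIATE_COLUMNS),
        ]
    )
    return DesignMatrix(
        X=X,
        columns=DESIGN_COLUMNS,
        contrast=1,
        subject_ids=tuple(t["subject_id"]),
    )


# ---------------------------------------------------------------------------
# vectorized OLS t-statistics


def _tstats(Y: np.ndarray, X: np.ndarray, contrast: int, pinv: np.ndarray,
            cc: float) -> np.ndarray:
    """t of the contrast coefficient for every outcome column of Y."""
    n, p = X.shape
    beta = pinv @ Y
    resid = Y - X @ beta
    df = n - p
    rss = (resid**2).sum(axis=0)
    # numerically zero residuals (constant/perfectly fitted outcome) -> t = 0
    rss[rss <= 1e-20 * (Y**2).sum(axis=0)] = 0.0
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[contrast] / np.sqrt(cc * sigma2)
    t[~np.isfinite(t)] = 0.0
    return t


def glm_tstat(y: np.ndarray, design: DesignMatrix) -> float:
    """OLS t-statistic of the group contrast for a single outcome."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] != design.n:
        raise ValidationError("outcome length does not match design rows")
    pinv = np.linalg.pinv(design.X)
    cc = float(np.linalg.inv(design.X.T @ design.X)[design.contrast, design.contrast])
    return float(_tstats(y[:, None], design.X, design.contrast, pinv, cc)[0])


def glm_tstats(Y: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Vectorized :func:`glm_tstat` over outcome columns."""
    Y = np.asarray(Y, dtype=float)
    pinv = np.linalg.pinv(design.X)
    cc = float(np.linalg.inv(design.X.T @ design.X)[design.contrast, design.contrast])
    return _tstats(Y, design.X, design.contrast, pinv, cc)


def freedman_lane_permute(
    Y: np.ndarray,
    design: DesignMatrix,
    n_perm: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed t plus an (n_perm x n_outcomes) Freedman-Lane null.

    The outcomes are residualized on the nuisance-only model, the
    residual rows are permuted with seeded shuffles, the nuisance fit is
    added back, and the full model is refit on each permuted dataset.
    With no nuisance columns this reduces exactly to permuting the group
    labels.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    Y = np.asarray(Y, dtype=float)
    X = design.X
    c = design.contrast
    pinv = np.linalg.pinv(X)
    cc = float(np.linalg.inv(X.T @ X)[c, c])
    observed = _tstats(Y, X, c, pinv, cc)

    Z = np.delete(X, c, axis=1)  # nuisance model (incl. intercept)
    pinv_z = np.linalg.pinv(Z)
    fitted = Z @ (pinv_z @ Y)
    resid = Y - fitted

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, Y.shape[1]))
    for b in range(n_perm):
        perm = rng.permutation(design.n)
        null[b] = _tstats(fitted + resid[perm], X, c, pinv, cc)
    return observed, null


# ---------------------------------------------------------------------------
# p-values


@dataclasses.dataclass(frozen=True)
class PermResult:
    """Permutation inference for one outcome family."""

    table: pd.DataFrame  # outcome, t, p_unc, p_corr, q, n_dropped info
    n_perm: int
    seed: int
    n_dropped: int  # NaN outcomes excluded from the family


def maxstat_pvalues(
    observed: np.ndarray,
    null: np.ndarray,
    outcome_names: list[str],
    n_perm: int | None = None,
    seed: int = 0,
) -> PermResult:
    """Two-sided uncorrected and max-|t| corrected permutation p, plus FDR q.

    Outcomes whose observed statistic (or any null draw) is NaN are
    dropped pairwise from the family and reported with NaN p-values.
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if null.shape[1] != observed.shape[0]:
        raise ValidationError("null columns must align with observed outcomes")
    n_perm = n_perm if n_perm is not None else null.shape[0]
    keep = np.isfinite(observed) & np.isfinite(null).all(axis=0)
    n_drop = int((~keep).sum())

    p_unc = np.full_like(observed, np.nan)
    p_corr = np.full_like(observed, np.nan)
    q = np.full_like(observed, np.nan)
    if keep.any():
        abs_obs = np.abs(observed[keep])
        abs_null = np.abs(null[:, keep])
        p_unc[keep] = (1 + (abs_null >= abs_obs).sum(axis=0)) / (n_perm + 1)
        max_null = abs_null.max(axis=1)
        p_corr[keep] = (1 + (max_null[:, None] >= abs_obs).sum(axis=0)) / (n_perm + 1)
        q[keep] = bh_fdr(p_unc[keep])

    table = pd.DataFrame(
        {
            "outcome": outcome_names,
            "t": observed,
            "p_unc": p_unc,
            "p_corr": p_corr,
            "q": q,
        }
    )
    return PermResult(table=table, n_perm=n_perm, seed=seed, n_dropped=n_drop)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def family_test(
    Y: np.ndarray,
    design: DesignMatrix,
    outcome_names: list[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermResult:
    """Freedman-Lane + max-stat + FDR for one outcome family.

    Outcome columns containing NaN for any subject (e.g. assortativity
    AUC on degenerate graphs) are excluded from permutation and reported
    with NaN statistics.
    """
    Y = np.asarray(Y, dtype=float)
    keep = np.isfinite(Y).all(axis=0)
    observed = np.full(Y.shape[1], np.nan)
    null = np.full((n_perm, Y.shape[1]), np.nan)
    if keep.any():
        obs_k, null_k = freedman_lane_permute(Y[:, keep], design, n_perm, seed)
        observed[keep] = obs_k
        null[:, keep] = null_k
    return maxstat_pvalues(observed, null, outcome_names, n_perm=n_perm, seed=seed)
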