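"""Covariate-controlled correlation of network indices with clinical scores.

Within the patient group, each network index (by default the AUC global
metrics, plus any significant nodal/block outputs the caller passes) is
correlated with each clinical score (SAS anxiety, SDS depression, Wexner
constipation) after partialling out age, sex, mean FD and cortex volume:
both variables are residualized on the covariates by OLS and the Pearson
correlation of the residuals is tested with the usual t reference,
t = r * sqrt(df / (1 - r^2)) with df = n - 2 - n_covariates. BH-FDR is
applied across the whole scan.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .io_core import ValidationError
from .perm_glm import bh_fdr


def partial_pearson(
    x: np.ndarray, y: np.ndarray, Z: np.ndarray | None = None
) -> tuple[float, float, int]:
    """Partial Pearson r of x and y given covariates Z; returns (r, p, df).

    With Z empty this is the plain Pearson correlation (df = n - 2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValidationError("x and y must align")
    k = 0
    if Z is not None and np.size(Z) > 0:
        Z = np.asarray(Z, dtype=float).reshape(n, -1)
        # constant covariates duplicate the intercept; drop them silently
        Z = Z[:, Z.std(axis=0) > 0]
    if Z is not None and Z.size > 0:
        k = Z.shape[1]
        if n <= k + 2:
            raise ValidationError("too few observations for the covariate count")
        design = np.column_stack([np.ones(n), Z])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValidationError("covariate matrix is rank deficient")
        coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
        coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
        x = x - design @ coef_x
        y = y - design @ coef_y
    else:
        x = x - x.mean()
        y = y - y.mean()
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        raise ValidationError("zero variance after residualization")
    r = float(np.clip((x * y).sum() / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2 * scipy.stats.t.sf(abs(t), df))
    return r, p, df


def assoc_scan(
    indices: pd.DataFrame,
    scores: pd.DataFrame,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """All (index, score) partial correlations with a single BH-FDR family.

    Missing score values are handled pairwise-complete; the per-pair n
    is reported. Rows: index, score, n, r, df, p, q.
    """
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float).reshape(len(indices), -1)
    rows = []
    for idx_name in indices.columns:
        x_full = indices[idx_name].to_numpy(float)
        for score_name in scores.columns:
            y_full = scores[score_name].to_numpy(float)
            ok = np.isfinite(x_full) & np.isfinite(y_full)
            if cov is not None:
                ok &= np.isfinite(cov).all(axis=1)
            z = cov[ok] if cov is not None else None
            r, p, df = partial_pearson(x_full[ok], y_full[ok], z)
            rows.append(
                dict(index=idx_name, score=score_name, n=int(ok.sum()), r=r, df=df, p=p)
            )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
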