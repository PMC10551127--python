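"""Per-subject functional connectivity matrices.

The estimator of record is Tikhonov-regularized (ridge) partial
correlation: the sample correlation matrix R is inverted after adding
lambda to its diagonal, theta = (R + lambda*I)^{-1}, and partial
correlations follow from the standard precision-to-partial map
p_ij = -theta_ij / sqrt(theta_ii * theta_jj). Regularizing the
*correlation* (not covariance) matrix makes the estimator invariant to
affine rescaling of any input channel and well-posed even when the number
of timepoints is below the number of parcels. Plain Pearson correlation
is available as an alternative. Either way the result is Fisher
r-to-z transformed into a symmetric, zero-diagonal z-matrix.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

from .io_core import TimeSeriesSet, ValidationError

#: correlations are clipped to +/- (1 - CLIP_EPS) before arctanh
CLIP_EPS = 1e-7

DEFAULT_LAMBDA = 1.0


@dataclasses.dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity for one subject."""

    subject_id: str
    z: np.ndarray
    method: str  # 'tikhonov_partial' or 'pearson'
    lam: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        z = self.z
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValidationError("z must be square")
        if not np.isfinite(z).all():
            raise ValidationError("z must be finite")
        if not np.allclose(z, z.T, atol=1e-10):
            raise ValidationError("z must be symmetric")
        if np.abs(np.diag(z)).max() > 0:
            raise ValidationError("z diagonal must be 0")

    @property
    def n_parcels(self) -> int:
        return self.z.shape[0]


def _standardize(data: np.ndarray) -> np.ndarray:
    d = data - data.mean(axis=0)
    sd = d.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValidationError("zero-variance column; cannot standardize")
    return d / sd


def sample_correlation(ts: TimeSeriesSet) -> np.ndarray:
    x = _standardize(ts.data)
    r = (x.T @ x) / x.shape[0]
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2


def ridge_precision(ts: TimeSeriesSet, lam: float = DEFAULT_LAMBDA) -> np.ndarray:
    """(R + lambda*I)^{-1} for the sample correlation matrix R.

    For lambda > 0 the inverse always exists; lambda = 0 requires a
    non-singular R (in particular T > N).
    """
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    r = sample_correlation(ts)
    n = r.shape[0]
    a = r + lam * np.eye(n)
    if lam == 0.0:
        t = ts.n_timepoints
        min_eig = scipy.linalg.eigvalsh(a, subset_by_index=[0, 0])[0]
        if t <= n or min_eig <= 1e-12:
            raise ValidationError(
                "sample correlation is singular (T <= N or collinear columns); "
                "use lambda > 0"
            )
    cho = scipy.linalg.cho_factor(a, lower=True)
    theta = scipy.linalg.cho_solve(cho, np.eye(n))
    return (theta + theta.T) / 2


def partial_corr_from_precision(theta: np.ndarray) -> np.ndarray:
    """Map a precision matrix to partial correlations.

    p_ij = -theta_ij / sqrt(theta_ii theta_jj); the diagonal is set to 0.
    """
    d = np.diag(theta)
    if (d <= 0).any():
        raise ValidationError("precision matrix has a non-positive diagonal entry")
    scale = np.sqrt(d)
    p = -theta / np.outer(scale, scale)
    np.fill_diagonal(p, 0.0)
    return np.clip(p, -1.0, 1.0)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """arctanh with clipping at 1 - 1e-7; diagonal forced to 0."""
    z = np.arctanh(np.clip(r, -1 + CLIP_EPS, 1 - CLIP_EPS))
    if z.ndim == 2 and z.shape[0] == z.shape[1] and z.shape[0] > 1:
        np.fill_diagonal(z, 0.0)
    return z


def build_fc_matrix(
    ts: TimeSeriesSet,
    method: str = "tikhonov_partial",
    lam: float = DEFAULT_LAMBDA,
) -> ConnectivityMatrix:
    """Full per-subject pipeline: correlation -> (ridge partial) -> Fisher z."""
    if method == "tikhonov_partial":
        theta = ridge_precision(ts, lam)
        r = partial_corr_from_precision(theta)
    elif method == "pearson":
        r = sample_correlation(ts)
        lam = 0.0
    else:
        raise ValidationError(f"unknown method {method!r}")
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(subject_id=ts.subject_id, z=z, method=method, lam=lam)


# ---------------------------------------------------------------------------
# edge vectorization helpers shared by NBS / IO


def upper_triangle_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the N(N-1)/2 unordered edges, lexicographic."""
    return np.triu_indices(n, k=1)


def stack_edges(fcs: list[ConnectivityMatrix]) -> np.ndarray:
    """Subjects x edges matrix of upper-triangular z values."""
    n = fcs[0].n_parcels
    iu, ju = upper_triangle_indices(n)
    return np.stack([fc.z[iu, ju] for fc in fcs])
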