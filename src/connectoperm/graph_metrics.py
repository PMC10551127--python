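"""Binary graph-theory metrics over a proportional-density grid.

Each subject's Fisher-z connectivity matrix is thresholded at every
density in the grid (default 10%..34% in 1% steps), keeping the k
strongest signed edges, and the resulting binary graphs are summarized
by eight global metrics — clustering coefficient C_P, characteristic
path length L_P, their ratios gamma/lambda to degree-preserving random
rewirings, small-worldness sigma = gamma/lambda, global and local
efficiency, and degree assortativity — and three nodal metrics (degree,
betweenness, nodal efficiency). The area under each metric's curve over
the density axis (trapezoid rule) is the threshold-free summary used
for inference.

The inner loops (BFS all-pairs distances, triangle counting, local
efficiency, Brandes betweenness, Maslov-Sneppen double-edge swaps) are
numba-compiled; unit tests check them against brute-force oracles and
networkx.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from numba import njit

from .connectivity import ConnectivityMatrix
from .io_core import ValidationError

GLOBAL_METRIC_NAMES = (
    "C_P",
    "L_P",
    "gamma",
    "lambda",
    "sigma",
    "E_glob",
    "E_loc",
    "assortativity",
)
NODAL_METRIC_NAMES = ("degree", "betweenness", "nodal_efficiency")

DEFAULT_N_NULL = 100
SWAPS_PER_EDGE = 10


@dataclasses.dataclass(frozen=True)
class DensityGrid:
    """Ordered sparsity fractions, stored as exact integer percents."""

    percents: tuple[int, ...] = tuple(range(10, 35))

    def __post_init__(self) -> None:
        p = self.percents
        if len(p) == 0:
            raise ValidationError("density grid is empty")
        if any(b <= a for a, b in zip(p, p[1:])):
            raise ValidationError("densities must be strictly increasing")
        if p[0] <= 0 or p[-1] >= 100:
            raise ValidationError("densities must lie in (0, 1)")

    @property
    def densities(self) -> np.ndarray:
        return np.asarray(self.percents, dtype=float) / 100.0

    def __len__(self) -> int:
        return len(self.percents)


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _apsp_bfs(adj):  # pragma: no cover - exercised via wrappers
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    queue = np.empty(n, np.int64)
    for s in range(n):
        dist[s, s] = 0.0
        qh, qt = 0, 1
        queue[0] = s
        while qh < qt:
            v = queue[qh]
            qh += 1
            dv = dist[s, v]
            for w in range(n):
                if adj[v, w] and dist[s, w] == np.inf:
                    dist[s, w] = dv + 1.0
                    queue[qt] = w
                    qt += 1
    return dist


@njit(cache=True)
def _local_clustering(adj):  # pragma: no cover
    n = adj.shape[0]
    c = np.zeros(n)
    nb = np.empty(n, np.int64)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j]:
                nb[k] = j
                k += 1
        if k < 2:
            continue
        tri = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nb[a], nb[b]]:
                    tri += 1
        c[i] = 2.0 * tri / (k * (k - 1))
    return c


@njit(cache=True)
def _local_efficiency(adj):  # pragma: no cover
    n = adj.shape[0]
    total = 0.0
    nb = np.empty(n, np.int64)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j]:
                nb[k] = j
                k += 1
        if k < 2:
            continue
        sub = np.zeros((k, k), np.bool_)
        for a in range(k):
            for b in range(k):
                sub[a, b] = adj[nb[a], nb[b]]
        d = _apsp_bfs(sub)
        acc = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and d[a, b] != np.inf:
                    acc += 1.0 / d[a, b]
        total += acc / (k * (k - 1))
    return total / n


@njit(cache=True)
def _brandes_betweenness(adj):  # pragma: no cover
    n = adj.shape[0]
    bc = np.zeros(n)
    sigma = np.zeros(n)
    dist = np.empty(n, np.int64)
    queue = np.empty(n, np.int64)
    order = np.empty(n, np.int64)
    delta = np.zeros(n)
    for s in range(n):
        sigma[:] = 0.0
        sigma[s] = 1.0
        dist[:] = -1
        dist[s] = 0
        qh, qt = 0, 1
        queue[0] = s
        no = 0
        while qh < qt:
            v = queue[qh]
            qh += 1
            order[no] = v
            no += 1
            for w in range(n):
                if adj[v, w]:
                    if dist[w] < 0:
                        dist[w] = dist[v] + 1
                        queue[qt] = w
                        qt += 1
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
        delta[:] = 0.0
        for idx in range(no - 1, -1, -1):
            w = order[idx]
            coeff = (1.0 + delta[w]) / sigma[w]
            for v in range(n):
                if adj[v, w] and dist[v] == dist[w] - 1:
                    delta[v] += sigma[v] * coeff
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0


@njit(cache=True)
def _char_path_from_dist(dist):  # pragma: no cover
    """Mean shortest path over pairs inside the largest connected component."""
    n = dist.shape[0]
    best_i = 0
    best_c = -1
    for i in range(n):
        c = 0
        for j in range(n):
            if dist[i, j] != np.inf:
                c += 1
        if c > best_c:
            best_c = c
            best_i = i
    if best_c < 2:
        return np.nan
    s = 0.0
    cnt = 0
    for i in range(n):
        if dist[best_i, i] == np.inf:
            continue
        for j in range(i + 1, n):
            if dist[best_i, j] == np.inf:
                continue
            s += dist[i, j]
            cnt += 1
    return s / cnt


@njit(cache=True)
def _cp_lp(adj):  # pragma: no cover
    dist = _apsp_bfs(adj)
    return _local_clustering(adj).mean(), _char_path_from_dist(dist)


@njit(cache=True)
def _double_edge_swap(adj, eu, ev, target_swaps, max_tries, seed):  # pragma: no cover
    np.random.seed(seed)
    m = eu.shape[0]
    swaps = 0
    tries = 0
    while swaps < target_swaps and tries < max_tries:
        tries += 1
        e1 = np.random.randint(m)
        e2 = np.random.randint(m)
        if e1 == e2:
            continue
        a, b = eu[e1], ev[e1]
        c, d = eu[e2], ev[e2]
        if np.random.randint(2) == 1:
            c, d = d, c
        # proposed rewiring: (a,b),(c,d) -> (a,d),(c,b)
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        eu[e1], ev[e1] = a, d
        eu[e2], ev[e2] = c, b
        swaps += 1
    return swaps


@njit(cache=True)
def _null_cp_lp_means(adj, eu, ev, n_null, swaps_per_edge, seeds):  # pragma: no cover
    m = eu.shape[0]
    cp_sum = 0.0
    lp_sum = 0.0
    lp_n = 0
    for k in range(n_null):
        a = adj.copy()
        eu_k = eu.copy()
        ev_k = ev.copy()
        _double_edge_swap(
            a, eu_k, ev_k, swaps_per_edge * m, 100 * swaps_per_edge * m, seeds[k]
        )
        cp, lp = _cp_lp(a)
        cp_sum += cp
        if not np.isnan(lp):
            lp_sum += lp
            lp_n += 1
    lp_mean = lp_sum / lp_n if lp_n > 0 else np.nan
    return cp_sum / n_null, lp_mean


# ---------------------------------------------------------------------------
# binarization


def edge_count(n_nodes: int, density: float) -> int:
    """round-half-even of density * N(N-1)/2."""
    return round(density * n_nodes * (n_nodes - 1) / 2)


def binarize_at_density(z: np.ndarray, density: float) -> np.ndarray:
    """Keep the k largest signed z edges; ties by ascending (i, j) index.

    Returns a boolean adjacency matrix (no self-loops).
    """
    if not 0 < density < 1:
        raise ValidationError("density must be in (0, 1)")
    n = z.shape[0]
    k = edge_count(n, density)
    if k == 0:
        raise ValidationError(f"density {density} keeps zero edges for N={n}")
    iu, ju = np.triu_indices(n, k=1)
    vals = z[iu, ju]
    # stable sort on -z keeps lexicographic (i, j) order among ties
    order = np.argsort(-vals, kind="stable")[:k]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[order], ju[order]] = True
    adj |= adj.T
    return adj


def nested_binarize(z: np.ndarray, grid: DensityGrid) -> list[np.ndarray]:
    """Adjacency per density; graphs are nested (edges only added)."""
    return [binarize_at_density(z, d) for d in grid.densities]


# ---------------------------------------------------------------------------
# metrics on one binary graph


def characteristic_path_length(adj: np.ndarray, dist: np.ndarray | None = None) -> float:
    """Mean shortest-path length over pairs in the largest component."""
    if dist is None:
        dist = _apsp_bfs(np.ascontiguousarray(adj, dtype=bool))
    return float(_char_path_from_dist(dist))


def global_efficiency(adj: np.ndarray, dist: np.ndarray | None = None) -> float:
    if dist is None:
        dist = _apsp_bfs(adj)
    n = adj.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def degree_assortativity(adj: np.ndarray) -> float:
    """Pearson correlation of degrees over edge endpoints (NaN if regular)."""
    deg = adj.sum(axis=1).astype(float)
    iu, ju = np.nonzero(np.triu(adj, k=1))
    x = np.concatenate([deg[iu], deg[ju]])
    y = np.concatenate([deg[ju], deg[iu]])
    vx = x - x.mean()
    vy = y - y.mean()
    denom = np.sqrt((vx**2).sum() * (vy**2).sum())
    if denom == 0:
        return float("nan")
    return float((vx * vy).sum() / denom)


def global_metrics(adj: np.ndarray) -> dict[str, float]:
    """C_P, L_P, E_glob, E_loc and assortativity for one binary graph.

    gamma/lambda/sigma need random nulls and are attached by the grid
    driver, not here.
    """
    a = np.ascontiguousarray(adj, dtype=bool)
    dist = _apsp_bfs(a)
    return {
        "C_P": float(_local_clustering(a).mean()),
        "L_P": characteristic_path_length(a, dist),
        "E_glob": global_efficiency(a, dist),
        "E_loc": float(_local_efficiency(a)),
        "assortativity": degree_assortativity(a),
    }


def nodal_metrics(adj: np.ndarray) -> dict[str, np.ndarray]:
    """Per-node degree, unnormalized betweenness and nodal efficiency."""
    a = np.ascontiguousarray(adj, dtype=bool)
    n = a.shape[0]
    dist = _apsp_bfs(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return {
        "degree": a.sum(axis=1).astype(float),
        "betweenness": _brandes_betweenness(a),
        "nodal_efficiency": inv.sum(axis=1) / (n - 1),
    }


def rewired_null(adj: np.ndarray, seed: int) -> np.ndarray:
    """One Maslov-Sneppen degree-preserving rewiring (10 swaps per edge)."""
    a = np.ascontiguousarray(adj, dtype=bool).copy()
    iu, ju = np.nonzero(np.triu(a, k=1))
    m = len(iu)
    if m < 2:
        raise ValidationError("graph has fewer than 2 edges; cannot rewire")
    eu = iu.astype(np.int64).copy()
    ev = ju.astype(np.int64).copy()
    _double_edge_swap(a, eu, ev, SWAPS_PER_EDGE * m, 100 * SWAPS_PER_EDGE * m, seed)
    return a


def random_null_metrics(
    adj: np.ndarray, n_null: int, seed: int
) -> tuple[float, float]:
    """Mean (C_P, L_P) over n_null degree-preserving rewired graphs."""
    if n_null < 1:
        raise ValidationError("n_null must be >= 1")
    a = np.ascontiguousarray(adj, dtype=bool)
    iu, ju = np.nonzero(np.triu(a, k=1))
    if len(iu) < 2:
        raise ValidationError("graph has fewer than 2 edges; cannot rewire")
    seeds = (np.random.SeedSequence(seed).generate_state(n_null) % (2**31 - 1)).astype(
        np.int64
    )
    cp, lp = _null_cp_lp_means(
        a, iu.astype(np.int64), ju.astype(np.int64), n_null, SWAPS_PER_EDGE, seeds
    )
    return float(cp), float(lp)


# ---------------------------------------------------------------------------
# AUC and grid drivers


def auc_over_densities(values: np.ndarray, densities: np.ndarray) -> float:
    """Trapezoidal integral of a metric over the density axis.

    NaN values are excluded pairwise together with their grid point; at
    least two finite points are required.
    """
    values = np.asarray(values, dtype=float)
    densities = np.asarray(densities, dtype=float)
    if values.shape != densities.shape:
        raise ValidationError("values and densities must align")
    ok = np.isfinite(values)
    if ok.sum() < 2:
        raise ValidationError("need at least 2 finite points for AUC")
    return float(np.trapezoid(values[ok], densities[ok]))


def global_metric_curves(
    z: np.ndarray, grid: DensityGrid, n_null: int = DEFAULT_N_NULL, seed: int = 0
) -> pd.DataFrame:
    """All 8 global metrics at every density of the grid for one subject."""
    rows = []
    null_seeds = np.random.SeedSequence(seed).generate_state(len(grid)) % (2**31 - 1)
    for k, (adj, dens) in enumerate(zip(nested_binarize(z, grid), grid.densities)):
        m = global_metrics(adj)
        cp_rand, lp_rand = random_null_metrics(adj, n_null, int(null_seeds[k]))
        gamma = m["C_P"] / cp_rand if cp_rand > 0 else float("nan")
        lam = m["L_P"] / lp_rand if lp_rand > 0 else float("nan")
        rows.append(
            {
                "density": dens,
                "C_P": m["C_P"],
                "L_P": m["L_P"],
                "gamma": gamma,
                "lambda": lam,
                "sigma": gamma / lam if np.isfinite(lam) and lam != 0 else float("nan"),
                "E_glob": m["E_glob"],
                "E_loc": m["E_loc"],
                "assortativity": m["assortativity"],
            }
        )
    return pd.DataFrame(rows)


def nodal_metric_curves(z: np.ndarray, grid: DensityGrid) -> dict[str, np.ndarray]:
    """density x node arrays for the three nodal metrics of one subject."""
    out = {name: [] for name in NODAL_METRIC_NAMES}
    for adj in nested_binarize(z, grid):
        m = nodal_metrics(adj)
        for name in NODAL_METRIC_NAMES:
            out[name].append(m[name])
    return {name: np.stack(vals) for name, vals in out.items()}


@dataclasses.dataclass(frozen=True)
class MetricTable:
    """Per-subject AUC summaries: global (subjects x 8) and nodal."""

    global_auc: pd.DataFrame
    nodal_auc: dict[str, pd.DataFrame]
    grid: DensityGrid


def compute_cohort_metrics(
    fcs: list[ConnectivityMatrix],
    grid: DensityGrid | None = None,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
    include_nodal: bool = True,
) -> MetricTable:
    """AUC metric table for a stack of connectivity matrices."""
    grid = grid or DensityGrid()
    dens = grid.densities
    seeds = np.random.SeedSequence(seed).generate_state(len(fcs)) % (2**31 - 1)
    glob_rows = {}
    nodal_rows: dict[str, dict[str, np.ndarray]] = {
        name: {} for name in NODAL_METRIC_NAMES
    }
    for k, fc in enumerate(fcs):
        curves = global_metric_curves(fc.z, grid, n_null=n_null, seed=int(seeds[k]))
        glob_rows[fc.subject_id] = {
            name: auc_over_densities(curves[name].to_numpy(), dens)
            if np.isfinite(curves[name]).sum() >= 2
            else float("nan")
            for name in GLOBAL_METRIC_NAMES
        }
        if include_nodal:
            nod = nodal_metric_curves(fc.z, grid)
            for name in NODAL_METRIC_NAMES:
                nodal_rows[name][fc.subject_id] = np.array(
                    [auc_over_densities(nod[name][:, i], dens) for i in range(fc.n_parcels)]
                )
    global_auc = pd.DataFrame.from_dict(glob_rows, orient="index")[
        list(GLOBAL_METRIC_NAMES)
    ]
    nodal_auc = {
        name: pd.DataFrame.from_dict(rows, orient="index")
        for name, rows in nodal_rows.items()
        if rows
    }
    return MetricTable(global_auc=global_auc, nodal_auc=nodal_auc, grid=grid)
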