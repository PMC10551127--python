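"""Network-Based Statistic: sub-network inference on suprathreshold edges.

Every edge (unordered parcel pair) gets a covariate-adjusted GLM
t-statistic for the group contrast. Edges passing the primary threshold
(parametric two-tailed p below ``primary_alpha``, default 0.001) and
matching a direction (patients > controls or patients < controls) are
collected, and their connected components are the candidate
sub-networks. Family-wise significance of each component's size (edge
count) is assessed against the permutation distribution of the maximum
component size, computed per direction with the shared Freedman-Lane
engine; components with one-tailed p below ``component_alpha`` (default
0.025) are significant.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .connectivity import ConnectivityMatrix, stack_edges, upper_triangle_indices
from .io_core import Atlas, ValidationError, YEO7_NETWORKS
from .perm_glm import DesignMatrix, _tstats

DIRECTIONS = ("hyper", "hypo")  # patients > controls, patients < controls


@dataclasses.dataclass(frozen=True)
class NBSConfig:
    primary_alpha: float = 0.001  # two-tailed edge threshold
    component_alpha: float = 0.025  # one-tailed, per direction
    n_perm: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.primary_alpha < 1:
            raise ValidationError("primary_alpha must be in (0, 1)")
        if not 0 < self.component_alpha <= 0.5:
            raise ValidationError("component_alpha must be in (0, 0.5]")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")


@dataclasses.dataclass(frozen=True)
class Component:
    """One connected sub-network of suprathreshold edges."""

    nodes: tuple[int, ...]  # 0-based node indices
    edges: tuple[tuple[int, int], ...]
    t_values: tuple[float, ...]
    direction: str
    p_corrected: float = float("nan")

    @property
    def size(self) -> int:
        """Component extent in edges."""
        return len(self.edges)


@dataclasses.dataclass(frozen=True)
class NBSResult:
    components: dict[str, list[Component]]  # per direction, descending size
    null_max_size: dict[str, np.ndarray]
    config: NBSConfig
    n_nodes: int

    def significant(self, direction: str | None = None) -> list[Component]:
        dirs = [direction] if direction else list(DIRECTIONS)
        return [
            c
            for d in dirs
            for c in self.components[d]
            if c.p_corrected < self.config.component_alpha
        ]

    def edge_table(self, atlas: Atlas | None = None) -> pd.DataFrame:
        """All suprathreshold edges with component membership and p."""
        rows = []
        for d in DIRECTIONS:
            for cid, comp in enumerate(self.components[d], start=1):
                for (i, j), t in zip(comp.edges, comp.t_values):
                    rows.append(
                        dict(
                            node1=i + 1,
                            node2=j + 1,
                            t=t,
                            direction=d,
                            component_id=f"{d}{cid}",
                            component_p=comp.p_corrected,
                        )
                    )
        cols = ["node1", "node2", "t", "direction", "component_id", "component_p"]
        df = pd.DataFrame(rows, columns=cols)
        if atlas is not None and len(df):
            labels = atlas.network_labels
            df["network1"] = labels[df["node1"] - 1]
            df["network2"] = labels[df["node2"] - 1]
        return df


def edge_tstats(
    edge_z: np.ndarray, design: DesignMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge t and parametric two-tailed p for the group contrast.

    ``edge_z`` is subjects x edges (upper-triangular vectorization).
    """
    edge_z = np.asarray(edge_z, dtype=float)
    if edge_z.shape[0] != design.n:
        raise ValidationError("edge matrix rows must match design rows")
    pinv = np.linalg.pinv(design.X)
    cc = float(np.linalg.inv(design.X.T @ design.X)[design.contrast, design.contrast])
    t = _tstats(edge_z, design.X, design.contrast, pinv, cc)
    p = 2 * scipy.stats.t.sf(np.abs(t), design.df_resid)
    return t, p


def _components_from_edges(
    kept: np.ndarray, iu: np.ndarray, ju: np.ndarray, n_nodes: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Connected components of the kept-edge graph.

    Returns (node_array, kept_edge_index_array) per component, largest
    first by edge count.
    """
    idx = np.flatnonzero(kept)
    if len(idx) == 0:
        return []
    ei, ej = iu[idx], ju[idx]
    used = np.unique(np.concatenate([ei, ej]))
    remap = np.full(n_nodes, -1)
    remap[used] = np.arange(len(used))
    g = csr_matrix(
        (np.ones(len(idx)), (remap[ei], remap[ej])), shape=(len(used), len(used))
    )
    _, labels = _cc(g, directed=False)
    comps = []
    for lab in np.unique(labels):
        nodes = used[labels == lab]
        edge_mask = labels[remap[ei]] == lab
        comps.append((nodes, idx[edge_mask]))
    comps.sort(key=lambda c: len(c[1]), reverse=True)
    return comps


def _max_component_size(
    kept: np.ndarray, iu: np.ndarray, ju: np.ndarray, n_nodes: int
) -> int:
    n_kept = int(kept.sum())
    if n_kept <= 1:
        return n_kept
    comps = _components_from_edges(kept, iu, ju, n_nodes)
    return len(comps[0][1])


def suprathreshold_components(
    t: np.ndarray,
    p: np.ndarray,
    direction: str,
    config: NBSConfig,
    iu: np.ndarray,
    ju: np.ndarray,
    n_nodes: int,
) -> list[Component]:
    """Connected components of edges with p < primary_alpha in a direction."""
    if direction not in DIRECTIONS:
        raise ValidationError(f"direction must be one of {DIRECTIONS}")
    sign_ok = t > 0 if direction == "hyper" else t < 0
    kept = (p < config.primary_alpha) & sign_ok
    out = []
    for nodes, edge_idx in _components_from_edges(kept, iu, ju, n_nodes):
        out.append(
            Component(
                nodes=tuple(int(x) for x in nodes),
                edges=tuple((int(iu[e]), int(ju[e])) for e in edge_idx),
                t_values=tuple(float(t[e]) for e in edge_idx),
                direction=direction,
            )
        )
    return out


def nbs_test(
    fcs: list[ConnectivityMatrix] | np.ndarray,
    design: DesignMatrix,
    config: NBSConfig | None = None,
    n_nodes: int | None = None,
) -> NBSResult:
    """Full NBS: observed components + permutation null of max size.

    ``fcs`` may be a list of connectivity matrices or a pre-vectorized
    subjects x edges array (then ``n_nodes`` is required).
    """
    config = config or NBSConfig()
    if isinstance(fcs, np.ndarray):
        if n_nodes is None:
            raise ValidationError("n_nodes is required with a pre-vectorized stack")
        edge_z = fcs
    else:
        n_nodes = fcs[0].n_parcels
        edge_z = stack_edges(fcs)
    iu, ju = upper_triangle_indices(n_nodes)
    if edge_z.shape[1] != len(iu):
        raise ValidationError("edge count does not match n_nodes")

    t_obs, p_obs = edge_tstats(edge_z, design)
    observed = {
        d: suprathreshold_components(t_obs, p_obs, d, config, iu, ju, n_nodes)
        for d in DIRECTIONS
    }

    # Freedman-Lane permutation null of the max component size per direction
    X = design.X
    c = design.contrast
    pinv = np.linalg.pinv(X)
    cc = float(np.linalg.inv(X.T @ X)[c, c])
    Z = np.delete(X, c, axis=1)
    fitted = Z @ (np.linalg.pinv(Z) @ edge_z)
    resid = edge_z - fitted
    t_crit = scipy.stats.t.isf(config.primary_alpha / 2, design.df_resid)

    rng = np.random.default_rng(config.seed)
    null_max = {d: np.empty(config.n_perm, dtype=int) for d in DIRECTIONS}
    for b in range(config.n_perm):
        perm = rng.permutation(design.n)
        t_b = _tstats(fitted + resid[perm], X, c, pinv, cc)
        null_max["hyper"][b] = _max_component_size(t_b > t_crit, iu, ju, n_nodes)
        null_max["hypo"][b] = _max_component_size(t_b < -t_crit, iu, ju, n_nodes)

    components = {}
    for d in DIRECTIONS:
        comps = []
        for comp in observed[d]:
            p_corr = (1 + int((null_max[d] >= comp.size).sum())) / (config.n_perm + 1)
            comps.append(dataclasses.replace(comp, p_corrected=p_corr))
        components[d] = comps
    return NBSResult(
        components=components,
        null_max_size=null_max,
        config=config,
        n_nodes=n_nodes,
    )


def network_pair_tally(
    result: NBSResult, atlas: Atlas, significant_only: bool = False
) -> pd.DataFrame:
    """Hypo/hyper suprathreshold-edge counts per Yeo network pair.

    ``ratio`` is count / number of possible edges for that pair; counts
    sum to the total suprathreshold edge count.
    """
    labels = atlas.network_labels
    sizes = {net: len(atlas.network_indices(net)) for net in YEO7_NETWORKS}
    counts = {
        d: {pair: 0 for pair in _network_pairs()} for d in DIRECTIONS
    }
    for d in DIRECTIONS:
        comps = result.significant(d) if significant_only else result.components[d]
        for comp in comps:
            for i, j in comp.edges:
                pair = _canon_pair(labels[i], labels[j])
                counts[d][pair] += 1
    rows = []
    for net_a, net_b in _network_pairs():
        if net_a == net_b:
            possible = sizes[net_a] * (sizes[net_a] - 1) // 2
        else:
            possible = sizes[net_a] * sizes[net_b]
        hypo = counts["hypo"][(net_a, net_b)]
        hyper = counts["hyper"][(net_a, net_b)]
        rows.append(
            dict(
                network1=net_a,
                network2=net_b,
                hypo=hypo,
                hyper=hyper,
                possible_edges=possible,
                hypo_ratio=hypo / possible,
                hyper_ratio=hyper / possible,
            )
        )
    return pd.DataFrame(rows)


def _network_pairs() -> list[tuple[str, str]]:
    pairs = [(n, n) for n in YEO7_NETWORKS]
    for a in range(7):
        for b in range(a + 1, 7):
            pairs.append((YEO7_NETWORKS[a], YEO7_NETWORKS[b]))
    return pairs


def _canon_pair(a: str, b: str) -> tuple[str, str]:
    ia, ib = YEO7_NETWORKS.index(a), YEO7_NETWORKS.index(b)
    return (a, b) if ia <= ib else (b, a)
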