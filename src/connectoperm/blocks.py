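"""Large-scale network analysis: Yeo-7 block-averaged functional connectivity.

Each subject's Fisher-z matrix is reduced to 28 numbers: the mean z over
all unordered parcel pairs inside each of the 7 networks, and over all
pairs spanning each of the 21 network pairs. Signed values are averaged
as-is (negative correlations are not folded). Group inference uses the
shared Freedman-Lane permutation engine with uncorrected per-block
permutation p-values and Benjamini-Hochberg FDR across the 28 blocks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .io_core import Atlas, ValidationError, YEO7_NETWORKS
from .perm_glm import DesignMatrix, PermResult, bh_fdr, freedman_lane_permute


def block_labels() -> list[str]:
    """The 28 block names: 7 within first, then 21 between (canonical order)."""
    labels = [f"{n}-{n}" for n in YEO7_NETWORKS]
    for a in range(7):
        for b in range(a + 1, 7):
            labels.append(f"{YEO7_NETWORKS[a]}-{YEO7_NETWORKS[b]}")
    return labels


def block_average(fc: ConnectivityMatrix, atlas: Atlas) -> pd.Series:
    """28 signed block-mean z values for one subject."""
    if fc.n_parcels != atlas.n_parcels:
        raise ValidationError("connectivity matrix does not match atlas size")
    z = fc.z
    idx = {net: atlas.network_indices(net) for net in YEO7_NETWORKS}
    values = {}
    for net in YEO7_NETWORKS:
        ia = idx[net]
        if len(ia) < 2:
            raise ValidationError(f"network {net} has fewer than 2 parcels")
        sub = z[np.ix_(ia, ia)]
        iu, ju = np.triu_indices(len(ia), k=1)
        values[f"{net}-{net}"] = float(sub[iu, ju].mean())
    for a in range(7):
        for b in range(a + 1, 7):
            na, nb = YEO7_NETWORKS[a], YEO7_NETWORKS[b]
            values[f"{na}-{nb}"] = float(z[np.ix_(idx[na], idx[nb])].mean())
    return pd.Series(values, name=fc.subject_id)[block_labels()]


def block_table(fcs: list[ConnectivityMatrix], atlas: Atlas) -> pd.DataFrame:
    """Subjects x 28 block-FC table."""
    return pd.DataFrame([block_average(fc, atlas) for fc in fcs])


def block_group_test(
    blocks: pd.DataFrame,
    design: DesignMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermResult:
    """Per-block permutation p (Freedman-Lane, two-sided) + BH-FDR over 28."""
    Y = blocks.to_numpy(float)
    observed, null = freedman_lane_permute(Y, design, n_perm, seed)
    p_unc = (1 + (np.abs(null) >= np.abs(observed)).sum(axis=0)) / (n_perm + 1)
    table = pd.DataFrame(
        {
            "outcome": list(blocks.columns),
            "t": observed,
            "p_unc": p_unc,
            "p_corr": np.nan,  # this family is FDR-corrected, not max-stat
            "q": bh_fdr(p_unc),
        }
    )
    return PermResult(table=table, n_perm=n_perm, seed=seed, n_dropped=0)
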