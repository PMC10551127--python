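"""Tabular input/output with strict validation.

Every artifact in the pipeline is plain TSV (or YAML for run metadata):
the atlas lookup table, per-subject parcel time series, the phenotype
table, per-subject connectivity matrices and every result table. Readers
return validated typed objects; node order everywhere downstream is the
atlas file's row order (parcel ids are 1-based in files, arrays are
0-based internally).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: The canonical seven cortical systems (Yeo et al. 7-network solution).
YEO7_NETWORKS = ("VN", "SMN", "DAN", "VAN", "LN", "FPN", "DMN")

ATLAS_COLUMNS = ("parcel_id", "parcel_name", "hemisphere", "network")
COVARIATE_COLUMNS = ("age", "sex", "mean_fd", "cortex_volume")
SCORE_COLUMNS = ("sas", "sds", "wexner")

# float format that round-trips IEEE doubles exactly through text
_FLOAT_FMT = "%.17g"


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclasses.dataclass(frozen=True)
class Atlas:
    """Parcel lookup table: identity, hemisphere and Yeo-7 network label.

    The row order of ``table`` fixes the node order of every matrix in the
    pipeline. Parcel ids are consecutive 1..N; internal array indices are
    ``parcel_id - 1``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ATLAS_COLUMNS:
            if col not in t.columns:
                raise ValidationError(f"atlas is missing required column {col!r}")
        ids = t["parcel_id"].to_numpy()
        if len(ids) != len(np.unique(ids)):
            dup = int(t["parcel_id"][t["parcel_id"].duplicated()].iloc[0])
            raise ValidationError(f"duplicate parcel_id {dup}")
        if not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValidationError("parcel_ids must be consecutive 1..N in file order")
        bad_hemi = ~t["hemisphere"].isin(["L", "R"])
        if bad_hemi.any():
            row = int(np.flatnonzero(bad_hemi.to_numpy())[0])
            raise ValidationError(
                f"row {row + 1}: unknown hemisphere {t['hemisphere'].iloc[row]!r}"
            )
        bad_net = ~t["network"].isin(YEO7_NETWORKS)
        if bad_net.any():
            row = int(np.flatnonzero(bad_net.to_numpy())[0])
            raise ValidationError(
                f"row {row + 1}: unknown network label {t['network'].iloc[row]!r} "
                f"(expected one of {', '.join(YEO7_NETWORKS)})"
            )
        counts = t["network"].value_counts()
        for net in YEO7_NETWORKS:
            if counts.get(net, 0) < 2:
                raise ValidationError(
                    f"network {net} has {counts.get(net, 0)} parcels; "
                    "at least 2 per network are required for block statistics"
                )

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def parcel_ids(self) -> np.ndarray:
        return self.table["parcel_id"].to_numpy()

    @property
    def network_labels(self) -> np.ndarray:
        """Per-node network label, in node order."""
        return self.table["network"].to_numpy()

    def network_indices(self, network: str) -> np.ndarray:
        """0-based node indices belonging to one network."""
        if network not in YEO7_NETWORKS:
            raise ValidationError(f"unknown network {network!r}")
        return np.flatnonzero(self.network_labels == network)


@dataclasses.dataclass(frozen=True)
class TimeSeriesSet:
    """One subject's parcel-level BOLD series, timepoints x parcels."""

    subject_id: str
    data: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        if d.ndim != 2:
            raise ValidationError(f"{self.subject_id}: time series must be 2-D")
        t, n = d.shape
        if not np.isfinite(d).all():
            bad = np.argwhere(~np.isfinite(d))[0]
            raise ValidationError(
                f"{self.subject_id}: non-finite value at timepoint {bad[0]}, "
                f"parcel column {bad[1]}"
            )
        if t < 30:
            raise ValidationError(
                f"{self.subject_id}: {t} timepoints < 30; covariance too unstable"
            )
        if t < n / 10:
            warnings.warn(
                f"{self.subject_id}: only {t} timepoints for {n} parcels "
                "(T < N/10); estimates will be noisy",
                stacklevel=2,
            )
        sd = d.std(axis=0)
        if (sd == 0).any():
            col = int(np.flatnonzero(sd == 0)[0])
            raise ValidationError(
                f"{self.subject_id}: zero-variance parcel column {col}"
            )
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]


@dataclasses.dataclass(frozen=True)
class PhenotypeTable:
    """Per-subject group membership, nuisance covariates and clinical scores.

    Required columns: subject_id, group ('patient'/'control'), age, sex
    (0 = F, 1 = M), mean_fd (mm), cortex_volume (mm^3). Clinical score
    columns (sas, sds, wexner) may contain missing values (controls).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ("subject_id", "group") + COVARIATE_COLUMNS
        for col in required:
            if col not in t.columns:
                raise ValidationError(f"phenotype table is missing column {col!r}")
        if t["subject_id"].duplicated().any():
            dup = t["subject_id"][t["subject_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate subject_id {dup!r}")
        bad_grp = ~t["group"].isin(["patient", "control"])
        if bad_grp.any():
            raise ValidationError(
                f"unknown group label {t['group'][bad_grp].iloc[0]!r}"
            )
        for grp in ("patient", "control"):
            if not (t["group"] == grp).any():
                raise ValidationError(f"group {grp!r} is empty")
        for col in COVARIATE_COLUMNS:
            if t[col].isna().any():
                row = int(np.flatnonzero(t[col].isna().to_numpy())[0])
                raise ValidationError(f"missing covariate {col!r} in row {row + 1}")

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    @property
    def n_patients(self) -> int:
        return int((self.table["group"] == "patient").sum())

    @property
    def n_controls(self) -> int:
        return int((self.table["group"] == "control").sum())

    def aligned_to(self, subject_ids: Sequence[str]) -> "PhenotypeTable":
        """Reorder rows to a given subject order; ids must match exactly."""
        if set(subject_ids) != set(self.subject_ids) or len(subject_ids) != len(
            self.subject_ids
        ):
            raise ValidationError(
                "phenotype subject_ids do not match the time-series subjects"
            )
        t = self.table.set_index("subject_id").loc[list(subject_ids)].reset_index()
        return PhenotypeTable(t)


# ---------------------------------------------------------------------------
# readers


def read_atlas(path: str | Path) -> Atlas:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return Atlas(pd.read_csv(path, sep="\t"))


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    t = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    return PhenotypeTable(t)


def read_timeseries(directory: str | Path, atlas: Atlas) -> list[TimeSeriesSet]:
    """Read every ``<subject_id>.tsv`` in a directory, atlas-aligned.

    Each file holds a header row of parcel ids and T numeric rows; the
    column count must equal the atlas size.
    """
    directory = Path(directory)
    out: list[TimeSeriesSet] = []
    for path in sorted(directory.glob("*.tsv")):
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        if df.shape[1] != atlas.n_parcels:
            raise ValidationError(
                f"{path.name}: {df.shape[1]} columns but atlas has "
                f"{atlas.n_parcels} parcels"
            )
        out.append(TimeSeriesSet(subject_id=path.stem, data=df.to_numpy(float)))
    if not out:
        raise ValidationError(f"no time-series TSV files found in {directory}")
    return out


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a square matrix TSV written by :func:`write_matrix`."""
    df = pd.read_csv(Path(path), sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(float)


# ---------------------------------------------------------------------------
# writers


def write_timeseries(ts: TimeSeriesSet, directory: str | Path, atlas: Atlas) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{ts.subject_id}.tsv"
    df = pd.DataFrame(ts.data, columns=[str(i) for i in atlas.parcel_ids])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def write_matrix(z: np.ndarray, path: str | Path, parcel_ids: np.ndarray) -> Path:
    """Write a square matrix as dense TSV, parcel ids as header row/column.

    Values round-trip bitwise through :func:`read_matrix`.
    """
    path = Path(path)
    labels = [str(int(i)) for i in parcel_ids]
    df = pd.DataFrame(z, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    return path


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> Path:
    pheno.table.to_csv(Path(path), sep="\t", index=False, float_format=_FLOAT_FMT)
    return Path(path)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    df.to_csv(Path(path), sep="\t", index=False, float_format=_FLOAT_FMT)
    return Path(path)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", float_precision="round_trip")


def write_results(
    tables: Mapping[str, pd.DataFrame],
    directory: str | Path,
    metadata: Mapping | None = None,
) -> dict[str, Path]:
    """Write named result tables as TSV plus a YAML run-metadata file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        written[name] = write_table(df, directory / f"{name}.tsv")
    if metadata is not None:
        meta_path = directory / "run_metadata.yaml"
        with open(meta_path, "w") as fh:
            yaml.safe_dump(dict(metadata), fh, sort_keys=True)
        written["run_metadata"] = meta_path
    return written
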