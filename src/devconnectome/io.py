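"""Readers, writers and containers for connectome inputs.

The pipeline consumes four plain-text artifacts: a region metadata table
(TSV), dense per-scan connectivity matrices (TSV/CSV, optionally paired with
a streamline-length matrix), a cohort manifest (CSV) pointing at the matrix
files, and downstream tables (expression, annotations, cortical maps) read
elsewhere.  All region ids are mapped to a contiguous 0-based internal index
on read; file ids may be 1-based.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: relative asymmetry above which a matrix is treated as corrupt rather than
#: silently symmetrized
ASYMMETRY_TOL = 1e-8

REGION_COLUMNS = ["id", "name", "hemisphere", "x", "y", "z", "module", "cortical"]
MANIFEST_COLUMNS = ["subject", "wave", "age", "sex", "tbv", "centre", "matrix_path"]


@dataclass
class RegionTable:
    """Parcellation metadata: one row per region.

    Internally regions are indexed 0..R-1 in file order; ``ids`` keeps the
    original file ids for round-tripping.
    """

    ids: np.ndarray            # original file ids
    names: list
    hemisphere: np.ndarray     # 'L' / 'R'
    centroids: np.ndarray      # R x 3, mm
    module: np.ndarray         # functional-subnetwork label per region
    cortical: np.ndarray       # boolean

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.hemisphere = np.asarray(self.hemisphere)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.module = np.asarray(self.module)
        self.cortical = np.asarray(self.cortical, dtype=bool)
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("duplicate region id in region table")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("non-finite region centroid")
        if self.centroids.shape != (len(self.ids), 3):
            raise ValueError("centroids must be R x 3")

    @property
    def n_regions(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return self.n_regions

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean centroid distances in mm."""
        from scipy.spatial.distance import squareform, pdist

        return squareform(pdist(self.centroids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "name": self.names,
                "hemisphere": self.hemisphere,
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "z": self.centroids[:, 2],
                "module": self.module,
                "cortical": self.cortical,
            }
        )


@dataclass
class Connectome:
    """Symmetric nonnegative weighted adjacency, optional edge lengths (mm)."""

    weights: np.ndarray
    lengths: np.ndarray | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.all(np.isfinite(w)):
            raise ValueError("non-finite weight")
        if np.any(w < 0):
            raise ValueError("negative weight")
        if np.max(np.abs(w - w.T)) > 1e-10 * max(1.0, np.max(np.abs(w))):
            raise ValueError("weights not symmetric")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if self.lengths is not None:
            ln = np.asarray(self.lengths, dtype=float)
            if ln.shape != w.shape:
                raise ValueError("lengths shape mismatch")
            if np.any(ln < 0):
                raise ValueError("negative length")
            self.lengths = ln

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle (i, j) indices of nonzero edges."""
        iu, ju = np.triu_indices(self.n_regions, 1)
        mask = self.weights[iu, ju] > 0
        return iu[mask], ju[mask]


@dataclass
class ScanRecord:
    subject_id: str
    wave: int
    age: float
    sex: str
    tbv: float
    centre: str
    connectome: Connectome


@dataclass
class Cohort:
    scans: list
    regions: RegionTable

    def __post_init__(self):
        R = self.regions.n_regions
        for s in self.scans:
            if s.connectome.n_regions != R:
                raise ValueError(
                    f"scan {s.subject_id} wave {s.wave}: connectome has "
                    f"{s.connectome.n_regions} regions, expected {R}"
                )
        waves = {}
        for s in self.scans:
            waves.setdefault(s.subject_id, []).append(s.wave)
        for sid, ws in waves.items():
            if sorted(ws) != sorted(set(ws)):
                raise ValueError(f"duplicate wave for subject {sid}")

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    @property
    def subjects(self) -> list:
        return sorted({s.subject_id for s in self.scans})

    def scans_per_subject(self) -> dict:
        return dict(Counter(s.subject_id for s in self.scans))

    def to_frame(self) -> pd.DataFrame:
        """Covariate table, one row per scan (no matrices)."""
        return pd.DataFrame(
            {
                "subject": [s.subject_id for s in self.scans],
                "wave": [s.wave for s in self.scans],
                "age": [s.age for s in self.scans],
                "sex": [s.sex for s in self.scans],
                "tbv": [s.tbv for s in self.scans],
                "centre": [s.centre for s in self.scans],
            }
        )


def read_region_table(path) -> RegionTable:
    df = pd.read_csv(path, sep="\t")
    for col in REGION_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"region table missing column '{col}'")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate region id {dup}")
    cortical = df["cortical"]
    if cortical.dtype == object:
        cortical = cortical.astype(str).str.lower().isin(["true", "1", "yes"])
    return RegionTable(
        ids=df["id"].to_numpy(),
        names=df["name"].astype(str).tolist(),
        hemisphere=df["hemisphere"].astype(str).to_numpy(),
        centroids=df[["x", "y", "z"]].to_numpy(float),
        module=df["module"].astype(str).to_numpy(),
        cortical=cortical.to_numpy(),
    )


def write_region_table(regions: RegionTable, path) -> None:
    regions.to_frame().to_csv(path, sep="\t", index=False)


def _read_dense(path) -> np.ndarray:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else r"\s+"
    return pd.read_csv(path, sep=sep, header=None).to_numpy(float)


def read_connectome(path, n_regions: int | None = None) -> Connectome:
    """Read a dense weight matrix; picks up ``<stem>.lengths.tsv`` if present."""
    path = Path(path)
    w = _read_dense(path)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: matrix not square, shape {w.shape}")
    if n_regions is not None and w.shape[0] != n_regions:
        raise ValueError(f"{path}: expected {n_regions} regions, got {w.shape[0]}")
    if np.any(w < 0):
        raise ValueError(f"{path}: negative weight")
    scale = max(1.0, np.max(np.abs(w)))
    asym = np.max(np.abs(w - w.T)) / scale
    if asym > ASYMMETRY_TOL:
        raise ValueError(f"{path}: asymmetry {asym:.2e} above tolerance {ASYMMETRY_TOL}")
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    lengths = None
    lpath = path.with_name(path.stem + ".lengths.tsv")
    if lpath.exists():
        lengths = _read_dense(lpath)
        lengths = 0.5 * (lengths + lengths.T)
        np.fill_diagonal(lengths, 0.0)
        lengths[w == 0] = 0.0
    return Connectome(weights=w, lengths=lengths)


def write_connectome(conn: Connectome, path) -> None:
    """Full-precision TSV writer (repr round-trip)."""
    path = Path(path)
    np.savetxt(path, conn.weights, delimiter="\t", fmt="%.17g")
    if conn.lengths is not None:
        np.savetxt(
            path.with_name(path.stem + ".lengths.tsv"),
            conn.lengths,
            delimiter="\t",
            fmt="%.17g",
        )


def load_cohort(
    manifest_path,
    regions: RegionTable,
    age_bounds: tuple = (6.0, 14.0),
) -> Cohort:
    """Assemble a longitudinal cohort from a manifest CSV.

    Rows whose age falls outside ``age_bounds`` are rejected with a warning
    (mirroring cohort inclusion criteria) and counted in the log.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"manifest missing column '{col}'")
    scans = []
    n_rejected = 0
    for _, row in df.iterrows():
        age = float(row["age"])
        if not (age_bounds[0] <= age <= age_bounds[1]):
            n_rejected += 1
            warnings.warn(
                f"scan {row['subject']} wave {row['wave']}: age {age} outside "
                f"bounds {age_bounds}, row rejected",
                stacklevel=2,
            )
            continue
        mpath = Path(row["matrix_path"])
        if not mpath.is_absolute():
            mpath = manifest_path.parent / mpath
        conn = read_connectome(mpath, n_regions=regions.n_regions)
        scans.append(
            ScanRecord(
                subject_id=str(row["subject"]),
                wave=int(row["wave"]),
                age=age,
                sex=str(row["sex"]),
                tbv=float(row["tbv"]),
                centre=str(row["centre"]),
                connectome=conn,
            )
        )
    if not scans:
        raise ValueError("empty cohort")
    scans.sort(key=lambda s: (s.subject_id, s.wave))
    cohort = Cohort(scans=scans, regions=regions)
    hist = Counter(cohort.scans_per_subject().values())
    logger.info(
        "cohort: %d subjects, %d scans (%d rejected); scans-per-subject %s",
        len(cohort.subjects),
        cohort.n_scans,
        n_rejected,
        dict(sorted(hist.items())),
    )
    return cohort


def group_average_network(cohort: Cohort, prevalence: float = 0.75) -> Connectome:
    """Prevalence-thresholded group-average network.

    An edge is kept iff the fraction of scans in which it is nonzero is at
    least ``prevalence`` (an edge is zeroed when its nonzero count is *less
    than* the threshold).  Kept-edge weight is the mean weight over all scans
    including zeros; lengths are averaged over the scans where present.
    """
    if not 0.0 < prevalence <= 1.0:
        raise ValueError("prevalence must lie in (0, 1]")
    if cohort.n_scans == 0:
        raise ValueError("empty cohort")
    stack = np.stack([s.connectome.weights for s in cohort.scans])
    nonzero_frac = np.mean(stack > 0, axis=0)
    keep = nonzero_frac >= prevalence
    w = np.where(keep, stack.mean(axis=0), 0.0)
    np.fill_diagonal(w, 0.0)
    lengths = None
    if all(s.connectome.lengths is not None for s in cohort.scans):
        lstack = np.stack([s.connectome.lengths for s in cohort.scans])
        present = (lstack > 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            lmean = np.where(present > 0, lstack.sum(axis=0) / np.maximum(present, 1), 0.0)
        lengths = np.where(w > 0, lmean, 0.0)
    return Connectome(weights=w, lengths=lengths)
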