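"""Atlas tables, ROI time series, NIfTI extraction and motion quality control.

The pipeline operates on per-subject region-of-interest (ROI) BOLD matrices
(T volumes x N nodes).  Nodes are defined by an atlas table of MNI
coordinates with spherical ROIs (default 5 mm radius, i.e. 10 mm diameter)
and a functional-network label drawn from the 13-network parcellation
vocabulary (plus "Uncertain").
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NETWORK_VOCABULARY",
    "NodeAtlas",
    "SubjectTimeSeries",
    "MotionRecord",
    "QCResult",
    "load_atlas",
    "extract_roi_timeseries",
    "qc_motion",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "read_motion_params",
    "read_cohort_metadata",
    "write_cohort_metadata",
]

#: The 13 functional networks of the 264-node parcellation, plus the
#: conventional "Uncertain" label for unassigned nodes.
NETWORK_VOCABULARY: frozenset[str] = frozenset(
    {
        "DMN",
        "VN",
        "FPN",
        "CON",
        "AN",
        "SN",
        "SMN_hand",
        "SMN_mouth",
        "DAN",
        "VAN",
        "MN",
        "Subcortical",
        "Cerebellar",
        "Uncertain",
    }
)

PANSS_FIELDS = ("total", "positive", "negative", "general")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeAtlas:
    """A collection of spherical ROI nodes.

    Backed by a DataFrame with columns ``node_id, x, y, z, network,
    radius_mm`` (coordinates in mm, world/MNI space).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["node_id", "x", "y", "z", "network", "radius_mm"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"atlas table missing column(s): {missing}")
        ids = self.table["node_id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate node_id(s) in atlas: {dupes}")
        if (self.table["radius_mm"] <= 0).any():
            raise ValueError("radius_mm must be > 0 for every node")
        unknown = set(self.table["network"]) - NETWORK_VOCABULARY
        if unknown:
            raise ValueError(
                f"unknown network label(s) {sorted(unknown)}; "
                f"expected one of {sorted(NETWORK_VOCABULARY)}"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def node_ids(self) -> list[str]:
        return [str(x) for x in self.table["node_id"]]

    @property
    def networks(self) -> list[str]:
        return list(self.table["network"])

    @property
    def n_networks(self) -> int:
        return int(self.table["network"].nunique())

    def coordinates(self) -> np.ndarray:
        """(N, 3) array of node centres in mm."""
        return self.table[["x", "y", "z"]].to_numpy(float)


@dataclass
class SubjectTimeSeries:
    """One subject's T x N ROI BOLD matrix with metadata.

    ``flagged_nodes`` lists node ids whose extraction produced no voxels;
    their columns hold NaN sentinels and must be handled downstream.
    """

    subject_id: str
    data: np.ndarray
    node_ids: Sequence[str]
    group: str | None = None
    tr_seconds: float = 2.0
    covariates: dict = field(default_factory=dict)
    panss: dict | None = None
    flagged_nodes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be a 2-D (T x N) array")
        if self.data.shape[0] < 2:
            raise ValueError("time series needs at least 2 volumes")
        if self.data.shape[1] != len(self.node_ids):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.node_ids)} node ids"
            )
        self.node_ids = [str(n) for n in self.node_ids]
        ok_nan = {self.node_ids.index(n) for n in self.flagged_nodes}
        bad = [
            j
            for j in range(self.data.shape[1])
            if j not in ok_nan and not np.all(np.isfinite(self.data[:, j]))
        ]
        if bad:
            raise ValueError(
                f"non-finite values in unflagged column(s) {bad}"
            )
        if self.group is not None and self.group not in ("patient", "control"):
            raise ValueError("group must be 'patient' or 'control'")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class MotionRecord:
    """Per-volume rigid-body realignment parameters.

    translations_mm: (T, 3); rotations_deg: (T, 3).
    """

    translations_mm: np.ndarray
    rotations_deg: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.translations_mm, float)
        r = np.asarray(self.rotations_deg, float)
        if t.shape != r.shape or t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("translations and rotations must both be (T, 3)")
        object.__setattr__(self, "translations_mm", t)
        object.__setattr__(self, "rotations_deg", r)

    def __len__(self) -> int:
        return self.translations_mm.shape[0]


@dataclass(frozen=True)
class QCResult:
    passed: bool
    max_translation_mm: float
    max_rotation_deg: float


# ---------------------------------------------------------------------------
# Atlas I/O
# ---------------------------------------------------------------------------


def load_atlas(
    table_path: str | Path,
    default_radius_mm: float = 5.0,
) -> NodeAtlas:
    """Load an atlas coordinate table from TSV/CSV.

    Expected columns: ``node_id, x, y, z, network``; ``radius_mm`` is
    optional and defaults to 5 mm (10 mm diameter spheres).
    """
    table_path = Path(table_path)
    sep = "," if table_path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(table_path, sep=sep, dtype=str)
    for col in ("node_id", "x", "y", "z", "network"):
        if col not in raw.columns:
            raise ValueError(f"atlas table is missing required column '{col}'")
    df = pd.DataFrame({"node_id": raw["node_id"].astype(str)})
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValueError(
                f"non-numeric coordinate in column '{col}', row {row}"
            )
        df[col] = vals.astype(float)
    df["network"] = raw["network"].astype(str)
    if "radius_mm" in raw.columns:
        df["radius_mm"] = pd.to_numeric(raw["radius_mm"]).astype(float)
    else:
        df["radius_mm"] = float(default_radius_mm)
    return NodeAtlas(df)


def write_atlas(atlas: NodeAtlas, path: str | Path) -> None:
    atlas.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# NIfTI ROI extraction
# ---------------------------------------------------------------------------


def extract_roi_timeseries(
    nifti_4d,
    atlas: NodeAtlas,
    subject_id: str = "subject",
    group: str | None = None,
    tr_seconds: float | None = None,
) -> SubjectTimeSeries:
    """Mean BOLD series per spherical node from a 4-D NIfTI image.

    A voxel belongs to a node when its centre (in the affine's world space)
    lies within ``radius_mm`` of the node coordinate.  Nodes whose sphere
    captures no voxel are flagged and their columns filled with NaN, never
    silently dropped.
    """
    import nibabel as nib

    img = nifti_4d if hasattr(nifti_4d, "get_fdata") else nib.load(str(nifti_4d))
    data = np.asarray(img.get_fdata(), float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D image (x, y, z, t)")
    affine = img.affine
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0

    nx, ny, nz, T = data.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
    world = vox @ affine[:3, :3].T + affine[:3, 3]

    flat = data.reshape(-1, T)
    out = np.empty((T, atlas.n_nodes), float)
    flagged: list[str] = []
    centres = atlas.coordinates()
    radii = atlas.table["radius_mm"].to_numpy(float)
    for j, (centre, radius) in enumerate(zip(centres, radii)):
        d2 = np.sum((world - centre) ** 2, axis=1)
        mask = d2 <= radius**2
        if not mask.any():
            flagged.append(atlas.node_ids[j])
            out[:, j] = np.nan
        else:
            out[:, j] = flat[mask].mean(axis=0)
    return SubjectTimeSeries(
        subject_id=subject_id,
        data=out,
        node_ids=atlas.node_ids,
        group=group,
        tr_seconds=tr_seconds,
        flagged_nodes=tuple(flagged),
    )


# ---------------------------------------------------------------------------
# Motion QC
# ---------------------------------------------------------------------------


def qc_motion(
    motion: MotionRecord,
    max_translation_mm: float = 1.5,
    max_rotation_deg: float = 1.5,
    n_volumes: int | None = None,
) -> QCResult:
    """Exclusion rule: fail iff any axis translation exceeds the threshold
    or any rotation exceeds its threshold (strictly "more than")."""
    if len(motion) == 0:
        raise ValueError("motion record is empty")
    if n_volumes is not None and len(motion) != n_volumes:
        raise ValueError(
            f"motion record length {len(motion)} != series length {n_volumes}"
        )
    mt = float(np.max(np.abs(motion.translations_mm)))
    mr = float(np.max(np.abs(motion.rotations_deg)))
    passed = not (mt > max_translation_mm or mr > max_rotation_deg)
    return QCResult(passed=passed, max_translation_mm=mt, max_rotation_deg=mr)


def read_motion_params(
    path: str | Path, rotation_unit: str = "deg"
) -> MotionRecord:
    """Read a 6-column realignment-parameter file (3 translations mm,
    3 rotations).  ``rotation_unit`` is 'deg' or 'rad' (SPM rp files are
    radians)."""
    arr = np.loadtxt(path)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != 6:
        raise ValueError("motion parameter file must have 6 columns")
    rot = arr[:, 3:6]
    if rotation_unit == "rad":
        rot = np.degrees(rot)
    elif rotation_unit != "deg":
        raise ValueError("rotation_unit must be 'deg' or 'rad'")
    return MotionRecord(translations_mm=arr[:, :3], rotations_deg=rot)


# ---------------------------------------------------------------------------
# Time-series TSV round trip
# ---------------------------------------------------------------------------


def write_timeseries_tsv(ts: SubjectTimeSeries, path: str | Path) -> None:
    """Write the T x N matrix as TSV (header = node ids), lossless for
    float64 ('%.17g')."""
    df = pd.DataFrame(ts.data, columns=list(ts.node_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_timeseries_tsv(
    path: str | Path,
    subject_id: str | None = None,
    group: str | None = None,
    tr_seconds: float = 2.0,
    covariates: Mapping | None = None,
    panss: Mapping | None = None,
    atlas: NodeAtlas | None = None,
) -> SubjectTimeSeries:
    """Read a T x N node-time-series TSV; errors name the offending cell."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    data = np.empty(raw.shape, float)
    for j, col in enumerate(raw.columns):
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna())[0])
            raise ValueError(
                f"missing or non-numeric value at row {row}, column '{col}' "
                f"in {path.name}"
            )
        # exact float64 round trip (pandas' fast parser is approximate)
        data[:, j] = [float(v) for v in raw[col]]
    node_ids = [str(c) for c in raw.columns]
    if atlas is not None:
        if node_ids != atlas.node_ids:
            raise ValueError(
                "time-series header does not match the attached atlas node ids"
            )
    return SubjectTimeSeries(
        subject_id=subject_id or path.stem,
        data=data,
        node_ids=node_ids,
        group=group,
        tr_seconds=tr_seconds,
        covariates=dict(covariates or {}),
        panss=dict(panss) if panss else None,
    )


# ---------------------------------------------------------------------------
# Cohort metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "education",
    "panss_total",
    "panss_positive",
    "panss_negative",
    "panss_general",
]


def write_cohort_metadata(subjects: Sequence[SubjectTimeSeries], path: str | Path) -> None:
    rows = []
    for ts in subjects:
        row = {
            "subject_id": ts.subject_id,
            "group": ts.group,
            "age": ts.covariates.get("age"),
            "sex": ts.covariates.get("sex"),
            "education": ts.covariates.get("education"),
        }
        for f in PANSS_FIELDS:
            row[f"panss_{f}"] = (ts.panss or {}).get(f)
        rows.append(row)
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_cohort_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("subject_id", "group") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort metadata missing column(s): {missing}")
    df["subject_id"] = df["subject_id"].astype(str)
    return df
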