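"""Volume, label-table, and tractogram I/O with one spatial contract.

All volumes live on a single affine-defined grid (voxel indices are 0-based;
the affine maps homogeneous voxel indices to RAS world coordinates in mm).
Streamlines are always expressed in world mm regardless of on-disk dialect:
TCK files store RAS mm natively and TRK voxel-space conventions are undone
by nibabel using the transform recorded in the header.  Per-subject volumes
must share one grid (shape and affine); the reader refuses mismatches rather
than resampling, because registration belongs upstream and silent resampling
hides errors.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "IntensityVolume",
    "BinaryMask",
    "LabelRecord",
    "LabelVolume",
    "StreamlineSet",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "read_label_table",
    "write_label_table",
    "default_label_table",
    "read_streamlines",
    "write_streamlines",
    "write_pair_table",
    "read_pair_table",
    "check_same_grid",
]

LOBES = ("frontal", "parietal", "temporal", "occipital", "other")
HEMISPHERES = ("L", "R", "bilateral")

#: shape must match exactly; affines must agree within this absolute tolerance
AFFINE_ATOL = 1e-4


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a grid do not."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if not np.all(np.isfinite(affine)):
        raise ValueError("affine contains non-finite values")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine upper-left 3x3 block is singular")
    return affine


@dataclasses.dataclass
class IntensityVolume:
    """A 3-D scalar image (e.g. T2 FLAIR) on an affine-defined grid."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("intensity volume must be 3-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensity volume contains non-finite values")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclasses.dataclass
class BinaryMask:
    """A boolean 3-D mask (WMH, cerebral, cerebellar reference, ICV ...)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("mask must be 3-D")
        if data.dtype != bool:
            vals = np.unique(data)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(
                    "mask values must be binary (0/1); refusing to threshold "
                    f"values {vals[:10]!r}"
                )
            data = data.astype(bool)
        self.data = data
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_true(self) -> int:
        return int(self.data.sum())


@dataclasses.dataclass(frozen=True)
class LabelRecord:
    """One parcellation region: id, name, lobe/hemisphere, pathology flags."""

    id: int
    name: str
    lobe: str
    hemisphere: str
    in_abeta_set: bool = False
    in_tau_set: bool = False

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ValueError("label id must be a positive integer")
        if self.lobe not in LOBES:
            raise ValueError(f"lobe must be one of {LOBES}, got {self.lobe!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}"
            )


@dataclasses.dataclass
class LabelVolume:
    """An integer parcellation grid (0 = unlabeled) plus its region table."""

    data: np.ndarray
    affine: np.ndarray
    table: list[LabelRecord]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise ValueError("label volume must hold integer labels")
            data = np.round(data).astype(np.int32)
        if data.min() < 0:
            raise ValueError("label values must be non-negative")
        self.data = data
        self.affine = _check_affine(self.affine)
        ids = [rec.id for rec in self.table]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate label ids in table")
        present = set(np.unique(data).tolist()) - {0}
        orphans = sorted(present - set(ids))
        if orphans:
            raise ValueError(
                f"label volume contains ids absent from the table: {orphans}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def by_id(self) -> dict[int, LabelRecord]:
        return {rec.id: rec for rec in self.table}

    def ids_in_set(self, which: str) -> list[int]:
        """Label ids flagged for a pathology set ('abeta' or 'tau')."""
        if which not in ("abeta", "tau"):
            raise ValueError("set must be 'abeta' or 'tau'")
        attr = "in_abeta_set" if which == "abeta" else "in_tau_set"
        return sorted(rec.id for rec in self.table if getattr(rec, attr))


@dataclasses.dataclass
class StreamlineSet:
    """An ordered collection of polylines in world mm."""

    streamlines: list[np.ndarray]
    space_tag: str = "rasmm"

    def __post_init__(self) -> None:
        cleaned = []
        for i, sl in enumerate(self.streamlines):
            sl = np.asarray(sl, dtype=float)
            if sl.ndim != 2 or sl.shape[1] != 3:
                raise ValueError(f"streamline {i} is not an (n,3) polyline")
            if sl.shape[0] < 2:
                raise ValueError(f"streamline {i} has fewer than 2 points")
            if not np.all(np.isfinite(sl)):
                raise ValueError(f"streamline {i} has non-finite coordinates")
            cleaned.append(sl)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


def check_same_grid(*volumes) -> None:
    """Verify that all volumes share one shape and affine (atol 1e-4)."""
    if len(volumes) < 2:
        return
    ref = volumes[0]
    for vol in volumes[1:]:
        if tuple(vol.shape) != tuple(ref.shape):
            raise GridMismatchError(
                f"shape mismatch: {tuple(ref.shape)} vs {tuple(vol.shape)}"
            )
        if not np.allclose(vol.affine, ref.affine, atol=AFFINE_ATOL, rtol=0):
            raise GridMismatchError("affine mismatch beyond tolerance 1e-4")


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def read_volume(path, kind: str, label_table=None):
    """Read a NIfTI image as an IntensityVolume, BinaryMask or LabelVolume.

    Parameters
    ----------
    path : str or Path
        NIfTI-1/NIfTI-2 file (.nii or .nii.gz).
    kind : {'intensity', 'mask', 'label'}
        How to interpret the voxel data.  ``mask`` requires the image to be
        binary-valued already (no silent thresholding); ``label`` requires a
        label table covering every nonzero id.
    label_table : path or list of LabelRecord, required for kind='label'
        TSV side-file (columns id, name, lobe, hemisphere, in_abeta_set,
        in_tau_set) or an in-memory record list.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    affine = img.affine
    if kind == "intensity":
        return IntensityVolume(data, affine)
    if kind == "mask":
        return BinaryMask(data, affine)
    if kind == "label":
        if label_table is None:
            raise ValueError("kind='label' requires a label_table")
        if not isinstance(label_table, list):
            label_table = read_label_table(label_table)
        return LabelVolume(data, affine, label_table)
    raise ValueError(f"unknown kind {kind!r}")


def write_volume(volume, path) -> None:
    """Write a volume back to NIfTI, preserving dtype semantics."""
    data = volume.data
    if isinstance(volume, BinaryMask):
        data = data.astype(np.uint8)
    elif isinstance(volume, LabelVolume):
        data = data.astype(np.int32)
    img = nib.Nifti1Image(data, volume.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Label tables
# ---------------------------------------------------------------------------

_LABEL_COLUMNS = ["id", "name", "lobe", "hemisphere", "in_abeta_set", "in_tau_set"]


def read_label_table(path) -> list[LabelRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    return [
        LabelRecord(
            id=int(row.id),
            name=str(row.name_),
            lobe=str(row.lobe),
            hemisphere=str(row.hemisphere),
            in_abeta_set=bool(row.in_abeta_set),
            in_tau_set=bool(row.in_tau_set),
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def write_label_table(table: Sequence[LabelRecord], path) -> None:
    df = pd.DataFrame(
        [
            (r.id, r.name, r.lobe, r.hemisphere, int(r.in_abeta_set), int(r.in_tau_set))
            for r in table
        ],
        columns=_LABEL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def default_label_table() -> list[LabelRecord]:
    """The packaged Desikan–Killiany + CIC label table.

    Carries the amyloid (42 regions) and meta-temporal tau (12 regions)
    pathology-set flags; see docs/methods.md for how the sets were assembled
    and why a study should normally supply its own table.
    """
    from importlib.resources import files

    path = files("uwmc.data").joinpath("labels_dk_cic.tsv")
    return read_label_table(str(path))


# ---------------------------------------------------------------------------
# Streamlines (TCK / TRK)
# ---------------------------------------------------------------------------

def read_streamlines(path) -> StreamlineSet:
    """Load a TCK or TRK tractogram; points come back in world (RAS) mm.

    TRK files store points in a voxel-space dialect; nibabel converts them
    using the affine recorded in the header.  Files whose header does not
    determine the transform raise rather than guessing.
    """
    path = Path(path)
    tractogram_file = nib.streamlines.load(str(path))
    # nibabel yields streamlines already moved to RAS mm for both formats
    sls = [np.asarray(s, dtype=float) for s in tractogram_file.streamlines]
    return StreamlineSet(sls, space_tag="rasmm") if sls else StreamlineSet([], "rasmm")


def write_streamlines(sset: StreamlineSet, path, affine: np.ndarray | None = None) -> None:
    """Write streamlines (world mm) as TCK or TRK depending on extension.

    TRK needs a reference grid to fill its header; pass the subject affine
    (any shared-grid volume's) when writing TRK.
    """
    path = Path(path)
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=float) for s in sset.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if path.suffix == ".tck":
        nib.streamlines.save(tractogram, str(path))
    elif path.suffix == ".trk":
        header = {}
        if affine is not None:
            header[nib.streamlines.trk.Field.VOXEL_TO_RASMM] = np.asarray(affine, float)
            header[nib.streamlines.trk.Field.VOXEL_SIZES] = np.sqrt(
                (np.asarray(affine)[:3, :3] ** 2).sum(axis=0)
            )
        nib.streamlines.save(tractogram, str(path), header=header or None)
    else:
        raise ValueError(f"unsupported tractogram extension {path.suffix!r}")


# ---------------------------------------------------------------------------
# Pair tables
# ---------------------------------------------------------------------------

_PAIR_COLUMNS = [
    "region_a_id",
    "region_a_name",
    "region_b_id",
    "region_b_name",
    "total_count",
    "unhealthy_count",
    "uwmc",
    "zero_denominator_flag",
]


def write_pair_table(matrix, path, labels: LabelVolume | None = None) -> None:
    """Write a UwmcMatrix as a long-format CSV sorted by (min id, max id)."""
    names = labels.by_id if labels is not None else {}
    rows = []
    for key in sorted(matrix.values):
        t, u = matrix.counts.get(key, (0, 0)) if matrix.counts else (0, 0)
        rows.append(
            (
                key.a,
                names[key.a].name if key.a in names else "",
                key.b,
                names[key.b].name if key.b in names else "",
                t,
                u,
                matrix.values[key],
                int(key in matrix.zero_denominator),
            )
        )
    pd.DataFrame(rows, columns=_PAIR_COLUMNS).to_csv(path, index=False)


def read_pair_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
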