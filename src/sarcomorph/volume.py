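"""Voxel-volume data model and I/O.

All volumes in this package are 3D, isotropic, and follow one axis
convention: axis 0 is the longitudinal (contractile) axis of the muscle,
axes 1-2 span the cross-section. Physical positions are voxel-center
positions, ``index * voxel_nm``; every distance and length downstream is
reported in nanometres.

Volumes are stored either as single-page-per-slice TIFF stacks or as a
single 3D HDF5 dataset carrying ``voxel_nm`` and ``kind`` attributes.
Anisotropic volumes are rejected rather than resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

VOLUME_KINDS = ("grayscale", "binary", "labels", "distance")

HDF5_DATASET = "volume"


@dataclass
class VoxelVolume:
    """A 3D isotropic voxel grid with physical scale.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Axis 0 is the longitudinal axis.
    voxel_nm : float
        Isotropic voxel edge length in nanometres; strictly positive.
    kind : {"grayscale", "binary", "labels", "distance"}
        Value semantics. ``binary`` volumes contain only {0, 1}; ``labels``
        only non-negative integers with 0 meaning background.
    """

    data: np.ndarray
    voxel_nm: float
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 2:
            raise ValueError(f"volume needs >=2 voxels per axis, got {self.data.shape}")
        if not (np.isscalar(self.voxel_nm) or np.ndim(self.voxel_nm) == 0):
            raise ValueError("voxel_nm must be a scalar (isotropic voxels)")
        self.voxel_nm = float(self.voxel_nm)
        if not self.voxel_nm > 0:
            raise ValueError(f"voxel_nm must be > 0, got {self.voxel_nm}")
        if self.kind not in VOLUME_KINDS:
            raise ValueError(f"kind must be one of {VOLUME_KINDS}, got {self.kind!r}")
        _validate_values(self.data, self.kind)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def astype_bool(self) -> np.ndarray:
        """Foreground mask as boolean array (binary or labels volumes)."""
        if self.kind not in ("binary", "labels"):
            raise ValueError(f"cannot binarize kind={self.kind!r}")
        return self.data > 0

    def require_kind(self, *kinds: str) -> "VoxelVolume":
        if self.kind not in kinds:
            raise ValueError(f"expected volume kind in {kinds}, got {self.kind!r}")
        return self

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "VoxelVolume":
        return replace(self, data=data, kind=kind or self.kind)

    def transpose(self, axes: tuple[int, int, int]) -> "VoxelVolume":
        """Reorder axes so that a differently-oriented file obeys the
        axis-0-is-longitudinal convention. Never applied silently."""
        return replace(self, data=np.transpose(self.data, axes))


def _validate_values(data: np.ndarray, kind: str) -> None:
    if kind == "binary":
        vals = np.unique(data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"binary volume contains values other than {{0,1}}: {vals[:10]}")
    elif kind == "labels":
        if not np.issubdtype(data.dtype, np.integer):
            if not np.all(np.mod(data, 1) == 0):
                raise ValueError("label volume contains non-integer values")
        if data.min() < 0:
            raise ValueError("label volume contains negative values")
    elif kind == "distance":
        if data.min() < 0:
            raise ValueError("distance volume contains negative values")


def load_volume(
    path: str | Path,
    voxel_nm: float | None = None,
    kind: str | None = None,
    transpose: tuple[int, int, int] | None = None,
) -> VoxelVolume:
    """Load a TIFF stack or HDF5 volume.

    For HDF5 files, ``voxel_nm`` and ``kind`` may be omitted and are then
    read from the dataset attributes; if both are given they must agree
    (a conflicting voxel size is an error, not a resample).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if voxel_nm is None or kind is None:
            raise ValueError("voxel_nm and kind are required when loading TIFF")
    elif suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ds = f[HDF5_DATASET]
            data = ds[()]
            file_voxel = ds.attrs.get("voxel_nm")
            file_kind = ds.attrs.get("kind")
        if voxel_nm is None:
            voxel_nm = file_voxel
        elif file_voxel is not None and not np.isclose(voxel_nm, file_voxel):
            raise ValueError(
                f"voxel_nm={voxel_nm} conflicts with file metadata {file_voxel}"
            )
        if kind is None:
            kind = file_kind
        if voxel_nm is None or kind is None:
            raise ValueError("voxel_nm/kind missing from file and not provided")
    else:
        raise ValueError(f"unknown volume extension {suffix!r} (use .tif/.tiff/.h5/.hdf5)")
    vol = VoxelVolume(data=data, voxel_nm=float(voxel_nm), kind=str(kind))
    if transpose is not None:
        vol = vol.transpose(transpose)
    return vol


def save_volume(vol: VoxelVolume, path: str | Path) -> Path:
    """Write a volume as TIFF (one page per slice) or HDF5 (with attrs)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, vol.data)
    elif suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(HDF5_DATASET, data=vol.data)
            ds.attrs["voxel_nm"] = vol.voxel_nm
            ds.attrs["kind"] = vol.kind
    else:
        raise ValueError(f"unknown volume extension {suffix!r}")
    return path


# ---------------------------------------------------------------------------
# Result tables

PROVENANCE_COLUMNS = ("source_volume", "module_version", "seed")


def make_result_table(
    columns: dict,
    source_volume: str = "",
    seed: int | None = None,
) -> pd.DataFrame:
    """Assemble a result table with the package's provenance columns.

    Column lengths must agree; key (non-provenance) columns must not hold
    NaN.
    """
    from . import __version__

    lengths = {k: len(v) for k, v in columns.items()}
    if len(set(lengths.values())) > 1:
        raise ValueError(f"ragged columns: {lengths}")
    table = pd.DataFrame(columns)
    for col in table.columns:
        if table[col].dtype.kind == "f" and table[col].isna().any():
            raise ValueError(f"NaN in key column {col!r}")
    table["source_volume"] = source_volume
    table["module_version"] = __version__
    table["seed"] = np.nan if seed is None else seed
    return table


def save_results(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as CSV (UTF-8, header) or JSON.

    Numeric columns round-trip losslessly at double precision.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    path = Path(path)
    if path.suffix.lower() == ".csv":
        # 17 significant digits round-trip IEEE doubles exactly
        table.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")
    elif path.suffix.lower() == ".json":
        table.to_json(path, orient="records", double_precision=15)
    else:
        raise ValueError(f"unknown table extension {path.suffix!r} (use .csv/.json)")
    return path


def load_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return pd.read_csv(path)
    if path.suffix.lower() == ".json":
        return pd.read_json(path, orient="records")
    raise ValueError(f"unknown table extension {path.suffix!r}")
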