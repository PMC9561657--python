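"""Per-filament shape statistics: inertia tensors and deviation from
linearity.

Each filament is a set of unit-mass voxels. Deviation from linearity is the
moment of inertia about the filament's *longest* principal axis divided by
its voxel count — i.e. the mean squared perpendicular distance of filament
mass from its best-fit line, in nm^2. For a straight circular rod of radius
r this floors at r^2/2 (the cross-section term); for a thin parabolic arc
of sagitta s it is (4/45) s^2 + r^2/2. For an elongated body the moment
about the longest axis is the *smallest* inertia eigenvalue; the largest
eigenvalue is exposed alongside for comparison with conventions that label
eigenvalues the other way around.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import VoxelVolume


def _inertia_from_points(pts_nm: np.ndarray):
    """Inertia tensor (unit mass per point, about the centroid) of an
    (n, 3) point set; returns (eigvals ascending, eigvecs columns, centroid)."""
    c = pts_nm.mean(axis=0)
    d = pts_nm - c
    # second-moment (scatter) matrix; inertia = trace(S) I - S
    s = d.T @ d
    inertia = np.trace(s) * np.eye(3) - s
    vals, vecs = np.linalg.eigh(inertia)
    vals = np.clip(vals, 0.0, None)
    return vals, vecs, c


def filament_inertia(labels: VoxelVolume, filament_id: int) -> dict:
    """Geometry record for one filament id in a label volume.

    Returns centroid (nm), voxel count, volume (nm^3), inertia eigenvalues
    I1<=I2<=I3 (nm^2 per unit mass; i.e. summed squared distances divided
    out by count downstream), principal axes, axial extent length (nm), and
    the linearity deviation I_long / V (nm^2). Single-voxel filaments yield
    all-zero eigenvalues and are flagged degenerate.
    """
    labels.require_kind("labels")
    idx = np.argwhere(labels.data == filament_id)
    if idx.size == 0:
        raise ValueError(f"filament id {filament_id} absent from label volume")
    return _record_from_voxels(idx, labels.voxel_nm, filament_id)


def _record_from_voxels(idx: np.ndarray, voxel_nm: float, fid: int) -> dict:
    pts = idx * voxel_nm
    n = len(pts)
    vals, vecs, c = _inertia_from_points(pts)
    mean_vals = vals / n  # mean squared perpendicular distance, nm^2
    long_axis = vecs[:, 0]  # smallest moment <-> longest axis
    proj = pts @ long_axis
    length = float(proj.max() - proj.min() + voxel_nm) if n > 1 else voxel_nm
    return {
        "id": int(fid),
        "n_voxels": n,
        "volume_nm3": n * voxel_nm**3,
        "centroid_z": c[0], "centroid_y": c[1], "centroid_x": c[2],
        "I1": mean_vals[0], "I2": mean_vals[1], "I3": mean_vals[2],
        "axis_z": long_axis[0], "axis_y": long_axis[1], "axis_x": long_axis[2],
        "length_nm": length,
        "linearity_deviation_nm2": mean_vals[0],
        "linearity_deviation_largest_nm2": mean_vals[2],
        "degenerate": bool(n == 1),
    }


def compute_filament_records(labels: VoxelVolume,
                             lengths_nm: dict[int, float] | None = None) -> pd.DataFrame:
    """Geometry records for every filament in a label volume.

    ``lengths_nm`` optionally supplies trace polyline lengths, which take
    precedence over the principal-axis voxel extent.
    """
    labels.require_kind("labels")
    data = labels.data
    ids = np.unique(data)
    ids = ids[ids > 0]
    objects = ndimage.find_objects(data)
    rows = []
    for fid in ids:
        sl = objects[int(fid) - 1]
        if sl is None:
            continue
        local = np.argwhere(data[sl] == fid)
        offset = np.array([s.start for s in sl])
        rec = _record_from_voxels(local + offset, labels.voxel_nm, int(fid))
        if lengths_nm and int(fid) in lengths_nm:
            rec["length_nm"] = float(lengths_nm[int(fid)])
        rows.append(rec)
    return pd.DataFrame(rows)


def linearity_deviation(record: dict | pd.Series,
                        use_largest: bool = False) -> float:
    """Deviation-from-linearity metric of a filament record (nm^2).

    By default the moment about the longest principal axis (smallest
    eigenvalue); ``use_largest`` switches to the largest eigenvalue for
    comparison with tools that report it.
    """
    if record["n_voxels"] == 0:
        raise ValueError("empty filament (V=0)")
    key = "linearity_deviation_largest_nm2" if use_largest else "linearity_deviation_nm2"
    return float(record[key])


def filter_filaments(records: pd.DataFrame, labels: VoxelVolume,
                     organelle_masks: list[VoxelVolume] | None = None,
                     min_length_nm: float = 1000.0) -> pd.DataFrame:
    """Keep filaments longer than ``min_length_nm`` that share no voxel
    with any organelle mask — the selection used for proximity analyses.

    An empty result is allowed; callers should treat it as flagged.
    """
    keep = records["length_nm"] > min_length_nm
    if organelle_masks:
        union = np.zeros(labels.shape, dtype=bool)
        for m in organelle_masks:
            if m.shape != labels.shape:
                raise ValueError("organelle mask geometry mismatch")
            union |= m.astype_bool()
        overlapping = np.unique(labels.data[union])
        keep &= ~records["id"].isin(overlapping[overlapping > 0])
    return records[keep].reset_index(drop=True)
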