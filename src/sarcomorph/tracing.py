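"""Myosin filament segmentation: hollow-cylinder correlation and
centerline tracing.

The detector computes, at every voxel, the maximum normalized
cross-correlation (NCC) of the grayscale volume against a hollow
cylindrical template over a set of sampled orientations, keeping the argmax
direction. Filament centerlines are then traced greedily through the
correlation field: seeds are local maxima above a seed threshold taken in
decreasing correlation order; each trace extends bidirectionally in steps
confined to a search cone around a direction blended from the previous step
and the local orientation field, stops when the best candidate correlation
falls below the continuation threshold or leaves the volume, and is
suppressed when it runs closer than a minimum distance to an already
accepted trace. Traces shorter than the minimum length are discarded.

Default parameters are the production settings of the source workflow:
template cylinder length 100 nm, outer radius 19 nm, inner radius 0, mask
radius 20 nm, angular sampling ~5 degrees; seed threshold 115 and
continuation threshold 80 on the 0-255 correlation scale, direction
coefficient 0.3, minimum distance 20 nm, minimum length 500 nm, search
cone 100 nm / 30 degrees with a 10% minimum step. "Angular sampling 5" is
interpreted as a ~5 degree maximum spacing between sampled orientations on
the hemisphere (quasi-uniform spiral sampling), and "minimum distance 20"
as nanometres — both configurable. A ``max_tilt_deg`` cone restricts
orientation sampling around the longitudinal axis when the filaments are
known to be near-axial, which cuts the dominant cost (one FFT correlation
pass per orientation) proportionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume import VoxelVolume


@dataclass
class CylinderTemplateParams:
    """Hollow-cylinder template for normalized cross-correlation."""

    cylinder_length_nm: float = 100.0
    outer_radius_nm: float = 19.0
    inner_radius_nm: float = 0.0
    mask_radius_nm: float = 20.0
    angular_sampling_deg: float = 5.0

    def __post_init__(self):
        if not (self.inner_radius_nm < self.outer_radius_nm <= self.mask_radius_nm):
            raise ValueError("require inner < outer <= mask radius")
        if self.cylinder_length_nm <= 0:
            raise ValueError("cylinder length must be > 0")
        if self.angular_sampling_deg <= 0:
            raise ValueError("angular sampling must be > 0")


@dataclass
class TraceParams:
    """Parameters of the greedy correlation-line tracer (0-255 scale)."""

    min_seed_correlation: float = 115.0
    min_continuation: float = 80.0
    direction_coefficient: float = 0.3
    min_distance_nm: float = 20.0
    min_length_nm: float = 500.0
    search_cone_length_nm: float = 100.0
    search_cone_angle_deg: float = 30.0
    min_step_fraction: float = 0.10

    def __post_init__(self):
        if not 0 < self.min_continuation <= self.min_seed_correlation <= 255:
            raise ValueError("require 0 < min_continuation <= min_seed_correlation <= 255")
        if not 0 <= self.direction_coefficient <= 1:
            raise ValueError("direction_coefficient must be in [0, 1]")


@dataclass
class CorrelationFields:
    """Per-voxel maximum NCC (0-255) and argmax orientation."""

    correlation: np.ndarray  # float32, 0-255
    orientation: np.ndarray  # float32, shape + (3,), axial unit vectors
    voxel_nm: float
    degenerate: bool = False


@dataclass
class Filament:
    id: int
    points_nm: np.ndarray  # (n, 3) ordered centerline points
    correlations: np.ndarray  # (n,)

    @property
    def length_nm(self) -> float:
        if len(self.points_nm) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points_nm, axis=0), axis=1).sum())


@dataclass
class FilamentSet:
    filaments: list[Filament] = field(default_factory=list)
    voxel_nm: float = 1.0

    def __len__(self):
        return len(self.filaments)

    def lengths_nm(self) -> np.ndarray:
        return np.array([f.length_nm for f in self.filaments])

    def to_jsonl(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for f in self.filaments:
                fh.write(json.dumps({
                    "id": f.id,
                    "points_nm": f.points_nm.tolist(),
                    "correlations": f.correlations.tolist(),
                }) + "\n")
        return path

    @classmethod
    def from_jsonl(cls, path: str | Path, voxel_nm: float = 1.0) -> "FilamentSet":
        fs = cls(voxel_nm=voxel_nm)
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            fs.filaments.append(Filament(
                id=d["id"],
                points_nm=np.asarray(d["points_nm"], dtype=float),
                correlations=np.asarray(d["correlations"], dtype=float),
            ))
        return fs


# ---------------------------------------------------------------------------
# orientation sampling

def hemisphere_directions(step_deg: float, max_tilt_deg: float = 90.0) -> np.ndarray:
    """Quasi-uniform spiral sampling of the (capped) hemisphere around the
    longitudinal axis, with ~step_deg spacing; the exact axis direction is
    always included. Directions are axial (sign-free), returned as (n, 3)
    unit vectors in (z, y, x) order with z >= 0."""
    step = np.radians(step_deg)
    cap = 1.0 - np.cos(np.radians(max_tilt_deg))
    n = max(int(np.ceil(2 * np.pi * cap / step**2)), 1)
    k = np.arange(n)
    z = 1.0 - cap * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    dirs = np.column_stack([z, r * np.sin(phi), r * np.cos(phi)])
    dirs[0] = (1.0, 0.0, 0.0)
    return dirs


# ---------------------------------------------------------------------------
# cylinder correlation

class _FFTCorrelator:
    """Correlate one volume against many centered odd-cube kernels, reusing
    the volume's forward FFT."""

    def __init__(self, data: np.ndarray, kernel_side: int):
        self.in_shape = data.shape
        self.k = kernel_side
        self.pad = [sp_fft.next_fast_len(n + kernel_side - 1) for n in data.shape]
        self.fd = sp_fft.rfftn(data, s=self.pad)
        self.fd2 = sp_fft.rfftn(data * data, s=self.pad)

    def kernel_fft(self, kernel: np.ndarray):
        return sp_fft.rfftn(kernel[::-1, ::-1, ::-1], s=self.pad)

    def correlate(self, fkernel, squared: bool = False) -> np.ndarray:
        src = self.fd2 if squared else self.fd
        full = sp_fft.irfftn(src * fkernel, s=self.pad)
        start = (self.k - 1) // 2
        sl = tuple(slice(start, start + n) for n in self.in_shape)
        return full[sl]


def _template_arrays(tmpl: CylinderTemplateParams, direction: np.ndarray,
                     voxel_nm: float):
    """Hollow-cylinder template T and window mask W in a centered odd cube,
    for one axis direction."""
    half_nm = np.sqrt((tmpl.cylinder_length_nm / 2) ** 2 + tmpl.mask_radius_nm**2)
    hb = int(np.ceil(half_nm / voxel_nm))
    ax = np.arange(-hb, hb + 1) * voxel_nm
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    along = zz * direction[0] + yy * direction[1] + xx * direction[2]
    rad2 = zz * zz + yy * yy + xx * xx - along * along
    w = (np.abs(along) <= tmpl.cylinder_length_nm / 2) & (
        rad2 <= tmpl.mask_radius_nm**2)
    t = w & (rad2 <= tmpl.outer_radius_nm**2) & (rad2 >= tmpl.inner_radius_nm**2)
    return t.astype(np.float64), w.astype(np.float64)


def cylinder_correlation(vol: VoxelVolume, tmpl: CylinderTemplateParams,
                         max_tilt_deg: float = 90.0) -> CorrelationFields:
    """Maximum masked NCC of the volume against the hollow-cylinder
    template over sampled orientations, affinely mapped to 0-255, with the
    argmax direction per voxel.

    NCC uses statistics over the mask-cylinder window: the template is
    zero-meaned within the window and the local image variance computed
    from FFT box sums, so a constant-valued volume yields zero correlation
    everywhere and is flagged degenerate.
    """
    vol.require_kind("grayscale")
    data = vol.data.astype(np.float64)
    dirs = hemisphere_directions(tmpl.angular_sampling_deg, max_tilt_deg)

    half_nm = np.sqrt((tmpl.cylinder_length_nm / 2) ** 2 + tmpl.mask_radius_nm**2)
    side = 2 * int(np.ceil(half_nm / vol.voxel_nm)) + 1
    if min(vol.shape) < side:
        raise ValueError(f"volume {vol.shape} smaller than template cube {side}")

    orientation = np.zeros(vol.shape + (3,), dtype=np.float32)
    orientation[..., 0] = 1.0
    if data.std() == 0:
        corr = np.zeros(vol.shape, dtype=np.float32)
        return CorrelationFields(corr, orientation, vol.voxel_nm, degenerate=True)

    corr_engine = _FFTCorrelator(data, side)
    best = np.full(vol.shape, -np.inf, dtype=np.float32)
    best_idx = np.zeros(vol.shape, dtype=np.uint16)
    for i, d in enumerate(dirs):
        t, w = _template_arrays(tmpl, d, vol.voxel_nm)
        nw = w.sum()
        that = (t - t.sum() / nw) * w
        st2 = float((that * that).sum())
        if st2 <= 0:
            continue
        fw = corr_engine.kernel_fft(w)
        fthat = corr_engine.kernel_fft(that)
        num = corr_engine.correlate(fthat)
        s1 = corr_engine.correlate(fw)
        s2 = corr_engine.correlate(fw, squared=True)
        var = s2 - s1 * s1 / nw
        denom = np.sqrt(np.clip(var, 0.0, None) * st2)
        with np.errstate(invalid="ignore", divide="ignore"):
            ncc = np.where(denom > 1e-9, num / denom, 0.0).astype(np.float32)
        mask = ncc > best
        best[mask] = ncc[mask]
        best_idx[mask] = i
    # window statistics are contaminated where the template cube leaves the
    # volume; invalidate that border margin
    m = (side - 1) // 2
    interior = np.zeros(vol.shape, dtype=bool)
    interior[m:-m, m:-m, m:-m] = True
    best[~interior] = 0.0
    corr = np.clip(best, 0.0, 1.0) * 255.0
    orientation = dirs[best_idx].astype(np.float32)
    return CorrelationFields(corr.astype(np.float32), orientation,
                             vol.voxel_nm, degenerate=False)


# ---------------------------------------------------------------------------
# tracing

class _PointGrid:
    """Spatial hash of accepted trace points for minimum-distance
    suppression queries."""

    def __init__(self, cell_nm: float):
        self.cell = max(cell_nm, 1e-6)
        self.cells: dict[tuple, list] = {}

    def add(self, pts: np.ndarray):
        keys = np.floor(pts / self.cell).astype(int)
        for key, p in zip(map(tuple, keys), pts):
            self.cells.setdefault(key, []).append(p)

    def min_dist(self, p: np.ndarray) -> float:
        key = np.floor(p / self.cell).astype(int)
        best = np.inf
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    pts = self.cells.get((key[0] + dz, key[1] + dy, key[2] + dx))
                    if pts:
                        d = np.linalg.norm(np.asarray(pts) - p, axis=1).min()
                        best = min(best, d)
        return best


def _densify(points: np.ndarray, spacing_nm: float) -> np.ndarray:
    if len(points) < 2:
        return points
    out = [points[:1]]
    for a, b in zip(points[:-1], points[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / spacing_nm)), 1)
        ts = np.linspace(0, 1, n + 1)[1:]
        out.append(a + ts[:, None] * (b - a))
    return np.vstack(out)


def _trilinear(arr: np.ndarray, p_vox: np.ndarray) -> float:
    i = np.floor(p_vox).astype(int)
    if np.any(i < 0) or np.any(i + 1 >= arr.shape):
        return -np.inf
    f = p_vox - i
    c = arr[i[0]:i[0] + 2, i[1]:i[1] + 2, i[2]:i[2] + 2]
    wz = np.array([1 - f[0], f[0]])
    wy = np.array([1 - f[1], f[1]])
    wx = np.array([1 - f[2], f[2]])
    return float(np.einsum("i,j,k,ijk->", wz, wy, wx, c))


def _cone_dirs(half_angle_deg: float):
    """Unit directions around +z covering the search cone: the apex plus
    rings at half and full half-angle."""
    dirs = [np.array([1.0, 0.0, 0.0])]
    for tilt in (np.radians(half_angle_deg) / 2, np.radians(half_angle_deg)):
        for az in np.linspace(0, 2 * np.pi, 8, endpoint=False):
            dirs.append(np.array([
                np.cos(tilt),
                np.sin(tilt) * np.sin(az),
                np.sin(tilt) * np.cos(az),
            ]))
    return np.array(dirs)


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping +z (axis 0) onto ``direction``."""
    z = np.array([1.0, 0.0, 0.0])
    d = direction / np.linalg.norm(direction)
    v = np.cross(z, d)
    c = float(z @ d)
    if c > 1 - 1e-9:
        return np.eye(3)
    if c < -1 + 1e-9:
        return np.diag([-1.0, -1.0, 1.0])  # pi rotation about x
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def trace_lines(fields: CorrelationFields, params: TraceParams | None = None) -> FilamentSet:
    """Greedy centerline tracing through a correlation/orientation field.

    Deterministic: seeds are processed in decreasing correlation order with
    lexicographic voxel-index tie-breaks.
    """
    params = params or TraceParams()
    corr = fields.correlation
    if corr.size == 0:
        raise ValueError("empty correlation field")
    vx = fields.voxel_nm
    fs = FilamentSet(voxel_nm=vx)
    if fields.degenerate or corr.max() < params.min_seed_correlation:
        return fs

    local_max = ndimage.maximum_filter(corr, size=3, mode="constant") == corr
    seed_mask = local_max & (corr >= params.min_seed_correlation)
    seeds = np.argwhere(seed_mask)
    if len(seeds) == 0:
        return fs
    vals = corr[tuple(seeds.T)]
    order = np.lexsort((seeds[:, 2], seeds[:, 1], seeds[:, 0], -vals))
    seeds = seeds[order]

    grid = _PointGrid(params.min_distance_nm)
    cone = _cone_dirs(params.search_cone_angle_deg)
    min_step = params.min_step_fraction * params.search_cone_length_nm

    def orient_at(p_nm: np.ndarray) -> np.ndarray:
        i = np.clip(np.rint(p_nm / vx).astype(int), 0,
                    np.array(corr.shape) - 1)
        return fields.orientation[tuple(i)].astype(float)

    def corr_at(p_nm: np.ndarray) -> float:
        return _trilinear(corr, p_nm / vx)

    def grow(start_nm: np.ndarray, d0: np.ndarray):
        pts = []
        cors = []
        p = start_nm.copy()
        d = d0 / np.linalg.norm(d0)
        step = min_step
        while True:
            o = orient_at(p)
            if o @ d < 0:
                o = -o
            blend = params.direction_coefficient * d + (1 - params.direction_coefficient) * o
            nb = np.linalg.norm(blend)
            blend = d if nb < 1e-9 else blend / nb
            rot = _rotation_to(blend)
            cand_dirs = cone @ rot.T
            best = None
            radius = step
            while radius <= params.search_cone_length_nm + 1e-9:
                cand = p + radius * cand_dirs
                cvals = np.array([corr_at(c) for c in cand])
                j = int(np.argmax(cvals))
                if cvals[j] >= params.min_continuation:
                    best = (cand[j], cand_dirs[j], float(cvals[j]))
                    break
                radius *= 2
            if best is None:
                return pts, cors
            newp, newd, v = best
            if grid.min_dist(newp) < params.min_distance_nm:
                return pts, cors
            pts.append(newp)
            cors.append(v)
            d = newd
            p = newp
            step = min(step * 2, params.search_cone_length_nm) \
                if v >= params.min_seed_correlation else min_step
            if len(pts) > 100000:  # safety against pathological loops
                return pts, cors

    next_id = 1
    for s in seeds:
        p0 = s.astype(float) * vx
        if grid.min_dist(p0) < params.min_distance_nm:
            continue
        d0 = orient_at(p0)
        fwd_pts, fwd_c = grow(p0, d0)
        bwd_pts, bwd_c = grow(p0, -d0)
        points = np.array(bwd_pts[::-1] + [p0] + fwd_pts)
        cvals = np.array(bwd_c[::-1] + [corr_at(p0)] + fwd_c)
        length = float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum()) \
            if len(points) > 1 else 0.0
        if length < params.min_length_nm:
            continue
        fs.filaments.append(Filament(id=next_id, points_nm=points,
                                     correlations=cvals))
        grid.add(_densify(points, params.min_distance_nm / 2))
        next_id += 1
    return fs


# ---------------------------------------------------------------------------
# rasterization and evaluation

def rasterize(filaments: FilamentSet, shape: tuple, voxel_nm: float,
              radius_nm: float) -> VoxelVolume:
    """Paint each centerline as a tube with its filament id; overlaps keep
    the earlier (higher-seed-correlation) id."""
    if radius_nm < voxel_nm / 2:
        raise ValueError("tube radius below half a voxel")
    out = np.zeros(shape, dtype=np.int32)
    extent = (np.array(shape) - 1) * voxel_nm
    r_px = radius_nm / voxel_nm
    ir = int(np.ceil(r_px))
    for f in filaments.filaments:
        if np.any(f.points_nm < -voxel_nm / 2) or np.any(f.points_nm > extent + voxel_nm / 2):
            raise ValueError(f"filament {f.id} polyline outside volume bounds")
        dense = _densify(f.points_nm, voxel_nm / 2) / voxel_nm
        for p in dense:
            lo = np.maximum(np.floor(p - r_px).astype(int), 0)
            hi = np.minimum(np.ceil(p + r_px).astype(int) + 1, shape)
            if np.any(lo >= hi):
                continue
            zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            ball = ((zz - p[0]) ** 2 + (yy - p[1]) ** 2 + (xx - p[2]) ** 2
                    <= r_px**2)
            sub = out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            sub[ball & (sub == 0)] = f.id
    return VoxelVolume(data=out, voxel_nm=voxel_nm, kind="labels")


def match_filaments(traced: FilamentSet, true_centerlines: dict[int, np.ndarray],
                    tol_nm: float = 20.0) -> dict:
    """Recall/precision of traced centerlines against ground truth.

    A trace is a true positive if the mean distance of its points to its
    best-matching true centerline is <= tol_nm; a true filament is recalled
    if at least one trace matches it.
    """
    true_ids = list(true_centerlines)
    if not traced.filaments or not true_ids:
        return {"recall": 0.0, "precision": 0.0, "n_true": len(true_ids),
                "n_traced": len(traced.filaments), "n_matched_traces": 0}
    pts, owner = [], []
    for tid, poly in true_centerlines.items():
        dense = _densify(np.asarray(poly, dtype=float), tol_nm / 4)
        pts.append(dense)
        owner.append(np.full(len(dense), tid))
    tree = cKDTree(np.vstack(pts))
    owner = np.concatenate(owner)
    matched_true: set = set()
    n_tp = 0
    for f in traced.filaments:
        dense = _densify(f.points_nm, tol_nm / 4)
        dists, idx = tree.query(dense)
        cands, counts = np.unique(owner[idx], return_counts=True)
        best_tid = cands[np.argmax(counts)]
        sel = owner[idx] == best_tid
        if dists[sel].mean() <= tol_nm and sel.mean() > 0.5:
            n_tp += 1
            matched_true.add(int(best_tid))
    return {
        "recall": len(matched_true) / len(true_ids),
        "precision": n_tp / len(traced.filaments),
        "n_true": len(true_ids),
        "n_traced": len(traced.filaments),
        "n_matched_traces": n_tp,
    }
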