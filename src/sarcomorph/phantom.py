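"""Synthetic voxel phantoms of striated muscle.

The generator builds labeled digital volumes that emulate the structures a
FIB-SEM muscle dataset contains — barrel-shaped sarcomeres whose
cross-sectional area (CSA) shrinks toward the Z-disks, hexagonal myosin
filament lattices with controllable peripheral curvature, thin transverse
Z-disk sheets repeating with the sarcomere period, mitochondrial tubes in
either parallel (longitudinal) or grid (Z-wrapping) network configurations,
thin SR/T tubes, and spherical lipid droplets — together with the exact
ground-truth values every analysis stage should recover.

Geometry conventions follow :mod:`sarcomorph.volume`: axis 0 is the
longitudinal axis, positions are voxel centers, all lengths in nm.

The taper that produces intrasarcomere CSA heterogeneity is applied as a
radial scale factor: a filament whose A-band position is ``p`` (nm from the
myofibril axis) sits at ``p * s(d)`` in the cross-section at distance ``d``
from the nearest Z-disk face, where ``s`` falls from 1 in the A-band to
``sqrt(1 - delta)`` at the Z-disk. Displacement is therefore proportional to
radial position — the outermost shell moves most, the axial filament not at
all — and is confined to within ``iband_width + zdisk_thickness`` of the
Z-disk, with zero slope at the A-band edge of the taper zone (a smooth arc).
Negative ``zdisk_csa_reduction`` expands the ends instead, which emulates
tubular insect muscle where lattice spacing grows toward the filament ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import VoxelVolume, save_volume

# Rendered intensity bands (8-bit): chosen so that at SNR 5 the Gaussian
# noise tails stay >4 sigma away from the 0/255 clip bounds.
RENDER_LEVELS = {
    "background": 90.0,
    "filaments": 190.0,
    "zdisk": 150.0,
    "mito": 130.0,
    "lipid": 120.0,
    "srt": 110.0,
}


@dataclass
class PhantomSpec:
    """Constructive parameters of a synthetic muscle volume.

    Defaults are physiological: 2.1 um sarcomere period, 45 nm myosin
    center-to-center lattice constant, 10 nm filament radius, 200 nm I-band,
    100 nm Z-disk, 10 nm voxels (5 nm for tracing-resolution phantoms).
    """

    shape: tuple[int, int, int]
    voxel_nm: float = 10.0
    sarcomere_period_nm: float = 2100.0
    aband_fraction: float | None = None  # default: (P - zdisk - 2*W_I) / P
    iband_width_nm: float = 200.0
    zdisk_thickness_nm: float = 100.0
    myofibril_radius_nm: float = 240.0
    lattice_constant_nm: float = 45.0
    filament_radius_nm: float = 10.0
    zdisk_csa_reduction: float = 0.0  # delta; negative = ends expanded
    taper_profile: str = "circular_arc"  # or "parabolic"
    z_phase_nm: float | None = None  # Z-disk center offset; default P/2
    mito_config: str = "none"  # "parallel" | "grid" | "none"
    mito_tube_radius_nm: float = 60.0
    n_mito_tubes: int = 4  # parallel tubes around the myofibril
    sr_tube_radius_nm: float = 25.0
    n_sr_tubes: int = 0
    lipid_droplet_radii_nm: tuple = ()
    organelle_gap_nm: float = 20.0
    seed: int = 0

    def __post_init__(self):
        P = self.sarcomere_period_nm
        if self.aband_fraction is None:
            self.aband_fraction = (
                P - self.zdisk_thickness_nm - 2 * self.iband_width_nm
            ) / P
        if self.z_phase_nm is None:
            self.z_phase_nm = P / 2
        self.validate()

    # derived geometry -----------------------------------------------------
    @property
    def end_scale(self) -> float:
        """Radial scale at the Z-disk, sqrt(1 - delta)."""
        return float(np.sqrt(1.0 - self.zdisk_csa_reduction))

    @property
    def taper_length_nm(self) -> float:
        """Axial extent of the taper zone from the Z-disk face."""
        return self.iband_width_nm + self.zdisk_thickness_nm

    @property
    def aband_length_nm(self) -> float:
        return self.aband_fraction * self.sarcomere_period_nm

    def validate(self) -> None:
        a, r = self.lattice_constant_nm, self.filament_radius_nm
        d = self.zdisk_csa_reduction
        if not a > 2 * r:
            raise ValueError(f"lattice constant {a} must exceed filament diameter {2 * r}")
        if not -1 < d < 1:
            raise ValueError(f"zdisk_csa_reduction must be in (-1, 1), got {d}")
        if not (self.iband_width_nm + self.zdisk_thickness_nm
                < self.sarcomere_period_nm):
            raise ValueError("I-band + Z-disk thickness must be below the period")
        for name in ("filament_radius_nm", "mito_tube_radius_nm", "sr_tube_radius_nm"):
            if getattr(self, name) < self.voxel_nm:
                raise ValueError(f"{name} below one voxel ({self.voxel_nm} nm)")
        # filaments must not overlap after taper, nor escape after expansion
        if a * min(self.end_scale, 1.0) <= 2 * r:
            raise ValueError(
                "taper would make neighboring filaments overlap at the Z-disk: "
                f"a*sqrt(1-delta) = {a * self.end_scale:.1f} <= 2r = {2 * r}"
            )
        if self.taper_profile not in ("circular_arc", "parabolic"):
            raise ValueError(f"unknown taper profile {self.taper_profile!r}")
        if self.mito_config not in ("parallel", "grid", "none"):
            raise ValueError(f"unknown mito_config {self.mito_config!r}")

    # taper ----------------------------------------------------------------
    def radial_scale(self, dist_from_z_face) -> np.ndarray:
        """Radial scale factor s(d) at axial distance d (nm) from the
        Z-disk face: end_scale at d=0, rising smoothly to 1 at d >= the
        taper length with zero slope there."""
        d = np.asarray(dist_from_z_face, dtype=float)
        u = np.clip(1.0 - d / self.taper_length_nm, 0.0, 1.0)
        rho = self.end_scale
        return 1.0 - (1.0 - rho) * self._taper_g(u)

    def _taper_g(self, u: np.ndarray) -> np.ndarray:
        """Normalized taper profile on [0,1]: g(0)=0 (A-band edge, zero
        slope), g(1)=1 (Z-disk face)."""
        if self.taper_profile == "parabolic":
            return u**2
        # circular arc through both endpoints, tangent at the A-band edge;
        # arc radius set by the outermost filament's displacement
        h = self.taper_length_nm
        dmax = max(abs(1.0 - self.end_scale) * self.myofibril_radius_nm, 1e-9)
        rc = (h**2 + dmax**2) / (2 * dmax)
        return (rc - np.sqrt(rc**2 - (u * h) ** 2)) / dmax


def hex_lattice_sites(max_radius_nm: float, a_nm: float):
    """Hexagonal lattice points within a disk, with their ring (shell) index.

    Returns ``(points, shells)`` where points are (y, x) offsets in nm from
    the lattice center and shells the hexagonal ring number (0 = axis).
    """
    n = int(np.ceil(max_radius_nm / a_nm)) + 2
    pts, shells = [], []
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            x = a_nm * (i + 0.5 * j)
            y = a_nm * (np.sqrt(3) / 2) * j
            if np.hypot(x, y) <= max_radius_nm:
                pts.append((y, x))
                shells.append((abs(i) + abs(j) + abs(i + j)) // 2)
    order = np.lexsort(np.array(pts).T[::-1]) if pts else []
    pts = np.array(pts, dtype=float)[order]
    shells = np.array(shells, dtype=int)[order]
    return pts, shells


@dataclass
class Phantom:
    """Built phantom: label volumes plus the constructive bookkeeping."""

    spec: PhantomSpec
    volumes: dict[str, VoxelVolume]
    filament_sites: np.ndarray  # (n_sites, 2) A-band (y, x) offsets, nm
    filament_shells: np.ndarray  # (n_sites,)
    filament_site_of_id: dict[int, int]  # label id -> site index
    zdisk_centers_nm: np.ndarray

    @property
    def voxel_nm(self) -> float:
        return self.spec.voxel_nm

    def axial_positions_nm(self) -> np.ndarray:
        return np.arange(self.volumes["zdisk"].shape[0]) * self.voxel_nm

    def dist_to_z_center(self, z_nm) -> np.ndarray:
        """Axial distance (nm) to the nearest Z-disk center plane."""
        z = np.asarray(z_nm, dtype=float)
        P = self.spec.sarcomere_period_nm
        return np.abs((z - self.spec.z_phase_nm + P / 2) % P - P / 2)

    def filament_centerlines(self) -> dict[int, np.ndarray]:
        """Constructive centerline per filament id as (z, y, x) nm points,
        one per occupied slice."""
        spec = self.spec
        nz, ny, nx = self.volumes["zdisk"].shape
        cy = (ny - 1) / 2 * spec.voxel_nm
        cx = (nx - 1) / 2 * spec.voxel_nm
        z = self.axial_positions_nm()
        d = self.dist_to_z_center(z)
        occupied = d >= spec.zdisk_thickness_nm / 2 + spec.voxel_nm
        s = spec.radial_scale(np.maximum(d - spec.zdisk_thickness_nm / 2, 0.0))
        seg = np.floor((z - self.spec.z_phase_nm) / spec.sarcomere_period_nm)
        # ids were assigned as seg_rank * n_sites + site + 1
        segs = np.unique(seg[occupied])
        n_sites = len(self.filament_sites)
        out: dict[int, np.ndarray] = {}
        for si, sv in enumerate(segs):
            sel = occupied & (seg == sv)
            if not sel.any():
                continue
            for site in range(n_sites):
                fid = si * n_sites + site + 1
                if fid not in self.filament_site_of_id:
                    continue
                py, px = self.filament_sites[site]
                pts = np.column_stack([
                    z[sel],
                    cy + py * s[sel],
                    cx + px * s[sel],
                ])
                out[fid] = pts
        return out

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, vol in self.volumes.items():
            save_volume(vol, directory / f"{name}.h5")
        gt = ground_truth(self)
        (directory / "ground_truth.json").write_text(json.dumps(gt.to_dict(), indent=1))
        return directory


def build_phantom(spec: PhantomSpec, seed: int | None = None) -> Phantom:
    """Construct all label volumes of a phantom.

    Emits ``filaments`` (one label per filament segment), ``zdisk``,
    ``aband``, ``mito``, ``srt``, ``lipid`` and ``cell`` volumes. The
    organelle volumes {filaments, zdisk, mito, srt, lipid} are mutually
    disjoint (priority: zdisk > filaments > mito > srt > lipid); ``aband``
    is a region mask of the myosin-bearing span and deliberately contains
    the filaments, and ``cell`` is the full field of view.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    nz, ny, nx = spec.shape
    vx = spec.voxel_nm
    P = spec.sarcomere_period_nm
    zt = spec.zdisk_thickness_nm
    R = spec.myofibril_radius_nm

    z = np.arange(nz) * vx
    dzc = np.abs((z - spec.z_phase_nm + P / 2) % P - P / 2)  # to Z center
    d_face = np.maximum(dzc - zt / 2, 0.0)
    s = spec.radial_scale(d_face)  # per-slice radial scale

    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    rho_xy = np.hypot(yy - cy, xx - cx) * vx  # in-plane radius map, nm

    # surface radius per slice (barrel shape)
    surf = R * s
    in_zslab = dzc <= zt / 2
    zdisk = in_zslab[:, None, None] & (rho_xy[None] <= surf[:, None, None])

    m_dist = np.abs((z - spec.z_phase_nm) % P - P / 2)  # to nearest M-line
    in_aband = m_dist <= spec.aband_length_nm / 2
    aband = in_aband[:, None, None] & (rho_xy[None] <= surf[:, None, None])

    # filaments ------------------------------------------------------------
    sites, shells = hex_lattice_sites(R - spec.filament_radius_nm,
                                      spec.lattice_constant_nm)
    n_sites = len(sites)
    labels = np.zeros(spec.shape, dtype=np.int32)
    r_px = spec.filament_radius_nm / vx
    box = int(np.ceil(r_px)) + 1
    occupied = dzc >= zt / 2 + vx
    # segments bounded by Z-disk center planes at phase + k*P
    seg = np.floor((z - spec.z_phase_nm) / P)
    seg_rank = {v: i for i, v in enumerate(np.unique(seg[occupied]))}
    site_of_id: dict[int, int] = {}
    for iz in range(nz):
        if not occupied[iz]:
            continue
        base = seg_rank[seg[iz]] * n_sites
        sl = s[iz]
        plane = labels[iz]
        for site in range(n_sites):
            fy = cy + sites[site, 0] * sl / vx
            fx = cx + sites[site, 1] * sl / vx
            y0, y1 = int(np.floor(fy)) - box, int(np.ceil(fy)) + box + 1
            x0, x1 = int(np.floor(fx)) - box, int(np.ceil(fx)) + box + 1
            y0, x0 = max(y0, 0), max(x0, 0)
            y1, x1 = min(y1, ny), min(x1, nx)
            if y0 >= y1 or x0 >= x1:
                continue
            py, px = np.meshgrid(np.arange(y0, y1), np.arange(x0, x1), indexing="ij")
            disk = (py - fy) ** 2 + (px - fx) ** 2 <= r_px**2
            if disk.any():
                fid = base + site + 1
                sub = plane[y0:y1, x0:x1]
                sub[disk] = fid
                site_of_id[fid] = site

    filament_mask = labels > 0
    # zdisk has priority (clearance should already keep them disjoint)
    labels[zdisk] = 0
    filament_mask &= ~zdisk

    # mitochondria ---------------------------------------------------------
    gap = spec.organelle_gap_nm
    r_t = spec.mito_tube_radius_nm
    mito = np.zeros(spec.shape, dtype=bool)
    if spec.mito_config == "grid":
        ring = R * min(spec.end_scale, 1.0) + gap + r_t
        mito = np.sqrt((rho_xy[None] - ring) ** 2
                       + dzc[:, None, None] ** 2) <= r_t
    elif spec.mito_config == "parallel":
        ring = R + gap + r_t
        angles = 2 * np.pi * np.arange(spec.n_mito_tubes) / max(spec.n_mito_tubes, 1)
        for th in angles:
            ty = cy + ring * np.sin(th) / vx
            tx = cx + ring * np.cos(th) / vx
            tube = ((yy - ty) ** 2 + (xx - tx) ** 2) * vx**2 <= r_t**2
            mito |= tube[None]
    mito &= ~(zdisk | filament_mask)

    # SR / T-tubules: thin longitudinal tubes at interleaved angles --------
    srt = np.zeros(spec.shape, dtype=bool)
    if spec.n_sr_tubes:
        ring = R + gap + spec.sr_tube_radius_nm
        angles = (2 * np.pi * (np.arange(spec.n_sr_tubes) + 0.5)
                  / spec.n_sr_tubes)
        for th in angles:
            ty = cy + ring * np.sin(th) / vx
            tx = cx + ring * np.cos(th) / vx
            tube = ((yy - ty) ** 2 + (xx - tx) ** 2) * vx**2 <= spec.sr_tube_radius_nm**2
            srt |= tube[None]
        srt &= ~(zdisk | filament_mask | mito)

    # lipid droplets: seeded positions outside the myofibril ---------------
    lipid = np.zeros(spec.shape, dtype=bool)
    for radius in spec.lipid_droplet_radii_nm:
        ring = R + gap + radius
        th = rng.uniform(0, 2 * np.pi)
        zc = rng.uniform(radius, nz * vx - radius)
        center = np.array([zc, cy * vx + ring * np.sin(th), cx * vx + ring * np.cos(th)])
        iz0 = max(int((zc - radius) / vx) - 1, 0)
        iz1 = min(int((zc + radius) / vx) + 2, nz)
        for iz in range(iz0, iz1):
            dz2 = (iz * vx - center[0]) ** 2
            if dz2 > radius**2:
                continue
            sphere = ((yy * vx - center[1]) ** 2 + (xx * vx - center[2]) ** 2
                      <= radius**2 - dz2)
            lipid[iz] |= sphere
    lipid &= ~(zdisk | filament_mask | mito | srt)

    cell = np.ones(spec.shape, dtype=np.uint8)

    def _vol(data, kind):
        return VoxelVolume(data=data, voxel_nm=vx, kind=kind)

    volumes = {
        "filaments": _vol(labels, "labels"),
        "zdisk": _vol(zdisk.astype(np.uint8), "binary"),
        "aband": _vol(aband.astype(np.uint8), "binary"),
        "mito": _vol(mito.astype(np.uint8), "binary"),
        "srt": _vol(srt.astype(np.uint8), "binary"),
        "lipid": _vol(lipid.astype(np.uint8), "binary"),
        "cell": _vol(cell, "binary"),
    }
    zcenters = np.arange(spec.z_phase_nm, nz * vx, P)
    return Phantom(
        spec=spec,
        volumes=volumes,
        filament_sites=sites,
        filament_shells=shells,
        filament_site_of_id=site_of_id,
        zdisk_centers_nm=zcenters,
    )


@dataclass
class GroundTruth:
    """Exact values the analysis stages should recover, obtained by direct
    counting on the emitted label volumes wherever counting is possible."""

    csa_heterogeneity_pct: float
    z_adjacent_fraction: float | None
    mito_content: float
    n_filaments: int
    filament_sagitta_nm: dict[int, float]
    filament_shell: dict[int, int]
    lattice_slab_centers_nm: list[float]
    lattice_constants_nm: list[float]
    period_nm: float
    phase_nm: float

    def to_dict(self) -> dict:
        return {
            "csa_heterogeneity_pct": self.csa_heterogeneity_pct,
            "z_adjacent_fraction": self.z_adjacent_fraction,
            "mito_content": self.mito_content,
            "n_filaments": self.n_filaments,
            "filament_sagitta_nm": {str(k): v for k, v in self.filament_sagitta_nm.items()},
            "filament_shell": {str(k): int(v) for k, v in self.filament_shell.items()},
            "lattice_slab_centers_nm": self.lattice_slab_centers_nm,
            "lattice_constants_nm": self.lattice_constants_nm,
            "period_nm": self.period_nm,
            "phase_nm": self.phase_nm,
        }


def ground_truth(phantom: Phantom, z_adjacent_margin_nm: float = 200.0) -> GroundTruth:
    """Recompute the constructive values by counting voxels.

    CSA heterogeneity: per sarcomere period, max-projected Z-disk sheet area
    versus max-projected A-band area, averaged as 100*(A-Z)/A. Z-adjacent
    mitochondrial fraction: mitochondrial voxels within
    ``iband_width + z_adjacent_margin_nm`` (exact Euclidean distance) of a
    Z-disk voxel over all mitochondrial voxels. Mitochondrial content:
    mitochondrial voxels over cell voxels.
    """
    spec = phantom.spec
    vx = spec.voxel_nm
    P = spec.sarcomere_period_nm
    zmask = phantom.volumes["zdisk"].data > 0
    amask = phantom.volumes["aband"].data > 0
    nz = zmask.shape[0]

    # complete periods tiled at M-lines (Z-disk centered in each slab)
    starts = np.arange(spec.z_phase_nm - P / 2, nz * vx - P + vx / 2, P)
    pct = []
    for z0 in starts:
        if z0 < -vx / 2:
            continue
        i0, i1 = int(round(z0 / vx)), int(round((z0 + P) / vx))
        if i1 > nz:
            break
        zarea = np.count_nonzero(zmask[i0:i1].max(axis=0))
        aarea = np.count_nonzero(amask[i0:i1].max(axis=0))
        if aarea:
            pct.append(100.0 * (aarea - zarea) / aarea)
    csa_pct = float(np.mean(pct)) if pct else float("nan")

    mito = phantom.volumes["mito"].data > 0
    cell = phantom.volumes["cell"].data > 0
    n_mito = int(mito.sum())
    content = n_mito / int(cell.sum())
    if n_mito:
        edt = ndimage.distance_transform_edt(~zmask) * vx
        thr = spec.iband_width_nm + z_adjacent_margin_nm
        frac = float(np.count_nonzero(edt[mito] <= thr) / n_mito)
    else:
        frac = None

    rho = spec.end_scale
    sag = {fid: float(np.hypot(*phantom.filament_sites[site]) * abs(1 - rho))
           for fid, site in phantom.filament_site_of_id.items()}
    shell = {fid: int(phantom.filament_shells[site])
             for fid, site in phantom.filament_site_of_id.items()}

    # lattice constant per 50-nm slab of distance from the Z-disk face:
    # mean of a * s(d) over the slab (only where filaments exist)
    slab = 50.0
    d_max = P / 2 - spec.zdisk_thickness_nm / 2
    centers, consts = [], []
    c = slab / 2
    while c < d_max:
        d = np.linspace(max(c - slab / 2, vx), min(c + slab / 2, d_max), 25)
        consts.append(float(spec.lattice_constant_nm * spec.radial_scale(d).mean()))
        centers.append(c)
        c += slab

    return GroundTruth(
        csa_heterogeneity_pct=csa_pct,
        z_adjacent_fraction=frac,
        mito_content=content,
        n_filaments=len(phantom.filament_site_of_id),
        filament_sagitta_nm=sag,
        filament_shell=shell,
        lattice_slab_centers_nm=centers,
        lattice_constants_nm=consts,
        period_nm=P,
        phase_nm=float(spec.z_phase_nm),
    )


def render_grayscale(phantom: Phantom, snr: float = np.inf,
                     seed: int = 0) -> VoxelVolume:
    """Render the phantom as an 8-bit grayscale volume.

    Filaments are bright solid cylinders; each organelle class gets a
    distinct intensity band; additive Gaussian noise with standard deviation
    ``(filament - background) / snr``. ``snr=inf`` renders noiselessly. The
    same seed always yields a bit-identical volume.
    """
    if not snr > 0:
        raise ValueError(f"snr must be > 0, got {snr}")
    img = np.full(phantom.spec.shape, RENDER_LEVELS["background"], dtype=np.float64)
    for name in ("zdisk", "mito", "srt", "lipid"):
        img[phantom.volumes[name].data > 0] = RENDER_LEVELS[name]
    img[phantom.volumes["filaments"].data > 0] = RENDER_LEVELS["filaments"]
    if np.isfinite(snr):
        sd = (RENDER_LEVELS["filaments"] - RENDER_LEVELS["background"]) / snr
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return VoxelVolume(data=img, voxel_nm=phantom.spec.voxel_nm, kind="grayscale")


# ---------------------------------------------------------------------------
# Presets

def preset_spec(name: str, **overrides) -> PhantomSpec:
    """Named phantom configurations used across the test and acceptance
    suites.

    ``mouse_like``   — grid mitochondria, ends compressed (delta=0.4).
    ``fly_tubular``  — ends expanded (delta=-0.25), grid-style taper
                       direction of tubular insect muscle.
    ``parallel``     — parallel mitochondria, uniform CSA (delta=0).
    ``cylinder``     — bare myofibril, no organelles, delta=0.
    ``tracing``      — 5 nm voxels, Z-disks at the volume edges so interior
                       filaments span a full sarcomere.
    """
    P, vx = 2100.0, 10.0
    base = dict(voxel_nm=vx, sarcomere_period_nm=P)
    n_periods = overrides.pop("n_periods", 3)
    half_xy = overrides.pop("half_xy_nm", 420.0)

    if name == "mouse_like":
        kw = dict(base, zdisk_csa_reduction=0.4, mito_config="grid")
    elif name == "fly_tubular":
        kw = dict(base, zdisk_csa_reduction=-0.25, mito_config="grid")
    elif name == "parallel":
        kw = dict(base, zdisk_csa_reduction=0.0, mito_config="parallel")
    elif name == "cylinder":
        kw = dict(base, zdisk_csa_reduction=0.0, mito_config="none")
    elif name == "tracing":
        kw = dict(base, voxel_nm=5.0, mito_config="none", z_phase_nm=0.0,
                  myofibril_radius_nm=200.0)
        vx = 5.0
    else:
        raise ValueError(f"unknown preset {name!r}")
    kw.update(overrides)
    vx = kw["voxel_nm"]
    P = kw["sarcomere_period_nm"]
    nz = int(round(n_periods * P / vx))
    nxy = 2 * int(round(half_xy / vx)) + 1
    kw.setdefault("shape", (nz, nxy, nxy))
    return PhantomSpec(**kw)


def build_matched_pair(delta: float = 0.3, seed: int = 0, **overrides):
    """Build a grid-mito phantom with Z-disk CSA reduction ``delta`` and a
    parallel-mito phantom of (approximately) equal mitochondrial content.

    The parallel phantom's tube radius is solved from the grid phantom's
    counted mitochondrial volume, so the pair isolates network
    configuration: same mitochondrial investment, different placement.
    """
    grid_spec = preset_spec("mouse_like", zdisk_csa_reduction=delta,
                            seed=seed, **overrides)
    grid = build_phantom(grid_spec)
    n_mito = int((grid.volumes["mito"].data > 0).sum())
    vx = grid_spec.voxel_nm
    nz = grid_spec.shape[0]
    n_tubes = grid_spec.n_mito_tubes
    # solve pi * r^2 * L * n_tubes = mito volume
    r_par = float(np.sqrt(n_mito * vx**3 / (np.pi * nz * vx * n_tubes)))
    par_spec = preset_spec("parallel", mito_tube_radius_nm=max(r_par, vx),
                           n_mito_tubes=n_tubes, seed=seed, **overrides)
    par = build_phantom(par_spec)
    return grid, par
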