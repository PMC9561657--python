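"""Half-sarcomere-sheet cross-sectional-area (CSA) heterogeneity.

The measurement mirrors a projection-based stack workflow: the volume is
tiled into sarcomere-length slabs phase-aligned at M-lines so each slab
holds exactly one Z-disk sheet. Per slab, the Z-disk binary is
max-projected along the longitudinal axis and its foreground area taken;
each Z-disk serves its two flanking half-sarcomeres, so its area is
duplicated. A-band areas come from half-sarcomere-length slabs: average
projection, local-contrast normalization (window radius of a quarter
sarcomere, clipped at +/-10 SD, stretched to 8-bit), masking by the slab's
max projection, then IsoData ("auto default") thresholding. The headline
statistic per half sheet is ``100 * (A - Z) / A`` — positive when the
Z-disk CSA is reduced below the A-band — with the raw Z/A ratio emitted
alongside since the alternative convention ``A/Z - 1`` is also in use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_isodata

from .volume import VoxelVolume


def axial_profile(mask: VoxelVolume) -> np.ndarray:
    """Per-slice foreground voxel count along the longitudinal axis."""
    return np.count_nonzero(mask.astype_bool(), axis=(1, 2))


def estimate_period(zdisk: VoxelVolume, min_period_nm: float = 500.0):
    """Sarcomere period and phase from the Z-disk axial profile.

    Period: dominant non-zero-lag peak of the autocorrelation of the
    mean-subtracted per-slice Z-disk voxel count, refined by parabolic
    interpolation. Phase: centroid of the first Z-disk density maximum.
    Requires at least three Z-disks along the axis.
    """
    profile = axial_profile(zdisk).astype(float)
    vx = zdisk.voxel_nm
    if profile.std() == 0:
        raise ValueError("flat axial profile: no Z-disk periodicity")
    peaks, _ = _profile_peaks(profile)
    if len(peaks) < 3:
        raise ValueError(f"need >= 3 Z-disks along axis 0, found {len(peaks)}")
    p = profile - profile.mean()
    ac = np.correlate(p, p, mode="full")[len(p) - 1:]
    min_lag = max(int(min_period_nm / vx), 2)
    search = ac[min_lag:len(p) // 2 + 1]
    if search.size == 0:
        raise ValueError("volume too short for the requested minimum period")
    lag = min_lag + int(np.argmax(search))
    # parabolic refinement around the integer-lag maximum
    if 1 <= lag < len(ac) - 1:
        y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            lag = lag + 0.5 * (y0 - y2) / denom
    period_nm = float(lag * vx)
    phase_nm = float(peaks[0] * vx)
    return period_nm, phase_nm


def _profile_peaks(profile: np.ndarray):
    """Centroids of connected regions above half of the profile maximum."""
    above = profile > profile.max() / 2
    lab, n = ndimage.label(above)
    centroids = [float(np.mean(np.nonzero(lab == i)[0])) for i in range(1, n + 1)]
    return centroids, above


def _slab_bounds(n_slices: int, voxel_nm: float, period_nm: float,
                 phase_nm: float):
    """Index bounds of complete sarcomere-length slabs whose boundaries sit
    at M-lines, so each slab contains one whole Z-disk sheet."""
    start = phase_nm - period_nm / 2
    while start < -voxel_nm / 2:
        start += period_nm
    bounds = []
    z0 = start
    while True:
        i0 = int(round(z0 / voxel_nm))
        i1 = int(round((z0 + period_nm) / voxel_nm))
        if i1 > n_slices:
            break
        bounds.append((i0, i1))
        z0 += period_nm
    if not bounds:
        raise ValueError("no complete sarcomere period fits in the volume")
    return bounds


def zdisk_sheet_areas(zdisk: VoxelVolume, period_nm: float,
                      phase_nm: float) -> np.ndarray:
    """Max-projected Z-disk sheet area (pixel count) per half sheet.

    One Z-disk per period slab; each area appears twice, once for each
    flanking half-sarcomere, so n periods yield 2n entries.
    """
    mask = zdisk.astype_bool()
    bounds = _slab_bounds(mask.shape[0], zdisk.voxel_nm, period_nm, phase_nm)
    areas = []
    for i0, i1 in bounds:
        proj = mask[i0:i1].max(axis=0)
        area = int(np.count_nonzero(proj))
        if area == 0:
            raise ValueError(f"period slab [{i0},{i1}) contains no Z-disk voxels")
        areas.extend([area, area])
    return np.asarray(areas, dtype=float)


def aband_sheet_areas(aband: VoxelVolume, period_nm: float, phase_nm: float,
                      window_radius_nm: float | None = None,
                      clip_sd: float = 10.0,
                      salt_tolerant: bool = True) -> np.ndarray:
    """A-band sheet area (pixel count) per half-sarcomere slab.

    Average projection -> local contrast normalization (square window of
    radius a quarter sarcomere in-plane, clip at +/-clip_sd SD, affine
    stretch to 8-bit) -> mask by the slab's max projection -> IsoData
    threshold -> foreground count. Works on binary masks or probability
    volumes.
    """
    data = aband.data.astype(float)
    if aband.kind == "grayscale":
        data = data / max(data.max(), 1.0)
    vx = aband.voxel_nm
    if window_radius_nm is None:
        window_radius_nm = period_nm / 4
    bounds = _slab_bounds(data.shape[0], vx, period_nm, phase_nm)
    half = []
    for i0, i1 in bounds:
        mid = (i0 + i1) // 2
        half.append((i0, mid))
        half.append((mid, i1))
    win = 2 * max(int(round(window_radius_nm / vx)), 1) + 1
    areas = []
    for i0, i1 in half:
        avg = data[i0:i1].mean(axis=0)
        mask = data[i0:i1].max(axis=0) > 0.5
        if not mask.any():
            raise ValueError(f"half-sarcomere slab [{i0},{i1}) is empty")
        img = _normalize_local_contrast(avg, win, clip_sd)
        vals = img[mask]
        if vals.min() == vals.max():
            raise ValueError("single-valued slab image: threshold undefined")
        thr = threshold_isodata(img)
        areas.append(int(np.count_nonzero(mask & (img > thr))))
    return np.asarray(areas, dtype=float)


def _normalize_local_contrast(img: np.ndarray, window: int,
                              clip_sd: float) -> np.ndarray:
    """Per-pixel (x - local mean) / local SD over a square window, clipped
    at +/-clip_sd, then affinely stretched and centered into 8-bit range."""
    lm = ndimage.uniform_filter(img, size=window, mode="reflect")
    lm2 = ndimage.uniform_filter(img * img, size=window, mode="reflect")
    lsd = np.sqrt(np.clip(lm2 - lm * lm, 0.0, None))
    norm = np.where(lsd > 1e-12, (img - lm) / np.where(lsd > 1e-12, lsd, 1.0), 0.0)
    norm = np.clip(norm, -clip_sd, clip_sd)
    lo, hi = norm.min(), norm.max()
    if hi == lo:
        return np.zeros_like(norm)
    return (norm - lo) / (hi - lo) * 255.0


def csa_heterogeneity(z_areas: np.ndarray, a_areas: np.ndarray,
                      voxel_nm: float | None = None) -> tuple[pd.DataFrame, dict]:
    """Percent CSA difference per half sheet and the cell-level summary.

    ``percent_difference = 100 * (A - Z) / A``: 40 means the Z-disk CSA is
    40% below the A-band CSA. Negative values (inverted barrel) are
    allowed and flagged. Returns (per-half-sheet table, summary dict).
    """
    z_areas = np.asarray(z_areas, dtype=float)
    a_areas = np.asarray(a_areas, dtype=float)
    if z_areas.shape != a_areas.shape:
        raise ValueError("Z and A area lists must pair one-to-one")
    if np.any(a_areas == 0):
        raise ValueError("zero A-band area: percent difference undefined")
    pct = 100.0 * (a_areas - z_areas) / a_areas
    table = pd.DataFrame({
        "half_sheet": np.arange(len(pct)),
        "zdisk_area_px": z_areas,
        "aband_area_px": a_areas,
        "ratio_z_over_a": z_areas / a_areas,
        "percent_difference": pct,
        "inverted": pct < 0,
    })
    if voxel_nm is not None:
        table["zdisk_area_um2"] = z_areas * (voxel_nm / 1000.0) ** 2
        table["aband_area_um2"] = a_areas * (voxel_nm / 1000.0) ** 2
    summary = {
        "mean_percent_difference": float(pct.mean()),
        "sd_percent_difference": float(pct.std(ddof=1)) if len(pct) > 1 else 0.0,
        "n_half_sheets": int(len(pct)),
        "any_inverted": bool((pct < 0).any()),
    }
    return table, summary


def measure_csa_heterogeneity(zdisk: VoxelVolume, aband: VoxelVolume,
                              period_nm: float | None = None,
                              phase_nm: float | None = None):
    """End-to-end CSA heterogeneity: period estimation (unless overridden),
    Z and A sheet areas, and the per-half-sheet table with summary."""
    if period_nm is None:
        period_nm, est_phase = estimate_period(zdisk)
        if phase_nm is None:
            phase_nm = est_phase
    elif phase_nm is None:
        # phase needs only one Z-disk density maximum
        peaks, _ = _profile_peaks(axial_profile(zdisk).astype(float))
        if not peaks:
            raise ValueError("no Z-disk density maximum for phase estimation")
        phase_nm = float(peaks[0] * zdisk.voxel_nm)
    z_areas = zdisk_sheet_areas(zdisk, period_nm, phase_nm)
    a_areas = aband_sheet_areas(aband, period_nm, phase_nm)
    return csa_heterogeneity(z_areas, a_areas, voxel_nm=zdisk.voxel_nm)
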