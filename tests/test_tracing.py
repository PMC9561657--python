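import numpy as np
import pytest

import sarcomorph as sm
from sarcomorph import tracing
from sarcomorph.volume import VoxelVolume

from helpers import MATCHED_TEMPLATE, MAX_TILT_DEG


def _cylinder_volume(centers_yx_nm, shape, voxel_nm=5.0, radius_nm=10.0,
                     z_range=(2, None), fg=190.0, bg=90.0):
    arr = np.full(shape, bg, np.float64)
    yy, xx = np.meshgrid(np.arange(shape[1]) * voxel_nm,
                         np.arange(shape[2]) * voxel_nm, indexing="ij")
    z1 = shape[0] - 2 if z_range[1] is None else z_range[1]
    for cy, cx in centers_yx_nm:
        m = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_nm**2
        arr[z_range[0]:z1, :, :][:, m] = fg
    return VoxelVolume(arr.astype(np.uint8), voxel_nm, "grayscale")


def matched_template(**overrides):
    return tracing.CylinderTemplateParams(**{**MATCHED_TEMPLATE, **overrides})


def test_parameter_validation():
    with pytest.raises(ValueError):
        tracing.CylinderTemplateParams(outer_radius_nm=25.0, mask_radius_nm=20.0)
    with pytest.raises(ValueError):
        tracing.TraceParams(min_continuation=150.0, min_seed_correlation=100.0)
    with pytest.raises(ValueError):
        tracing.TraceParams(direction_coefficient=1.5)


def test_hemisphere_sampling_density():
    dirs = tracing.hemisphere_directions(10.0)
    assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0)
    assert np.all(dirs[:, 0] >= 0)  # axial, upper hemisphere
    # nearest-neighbor angular spacing stays near the requested step
    cos = np.clip(dirs @ dirs.T, -1, 1)
    np.fill_diagonal(cos, -1)
    nn_deg = np.degrees(np.arccos(cos.max(axis=1)))
    assert np.median(nn_deg) < 15.0


def test_constant_volume_is_degenerate():
    vol = VoxelVolume(np.full((60, 32, 32), 128, np.uint8), 5.0, "grayscale")
    fields = tracing.cylinder_correlation(vol, matched_template(),
                                          max_tilt_deg=MAX_TILT_DEG)
    assert fields.degenerate
    assert fields.correlation.max() == 0.0
    assert len(tracing.trace_lines(fields)) == 0


def test_single_cylinder_orientation_and_trace():
    """A noiseless 2000 nm cylinder along axis 0: the argmax orientation on
    the axis is axial, on-axis correlation exceeds off-axis, and tracing
    yields exactly one filament of the right length on the right line."""
    vol = _cylinder_volume([(75.0, 75.0)], (460, 31, 31),
                           z_range=(30, 430))  # 2000 nm centered
    fields = tracing.cylinder_correlation(vol, matched_template(),
                                          max_tilt_deg=MAX_TILT_DEG)
    axis_dir = fields.orientation[200, 15, 15]
    assert np.degrees(np.arccos(abs(axis_dir[0]))) < 5.0
    assert fields.correlation[200, 15, 15] > fields.correlation[200, 15, 19]
    fs = tracing.trace_lines(fields)
    assert len(fs) == 1
    assert fs.filaments[0].length_nm == pytest.approx(2000.0, rel=0.05)
    dev = np.abs(fs.filaments[0].points_nm[:, 1:] - 75.0)
    assert dev.mean() < vol.voxel_nm  # centerline within one voxel


def test_seven_filament_bundle_spacing():
    pts, _ = sm.hex_lattice_sites(50.0, 45.0)
    assert len(pts) == 7
    centers = [(125.0 + y, 125.0 + x) for y, x in pts]
    vol = _cylinder_volume(centers, (260, 51, 51), z_range=(20, 240))
    fields = tracing.cylinder_correlation(vol, matched_template(),
                                          max_tilt_deg=MAX_TILT_DEG)
    fs = tracing.trace_lines(fields)
    assert len(fs) == 7
    cent = np.array([f.points_nm[:, 1:].mean(axis=0) for f in fs.filaments])
    d = np.linalg.norm(cent[:, None] - cent[None], axis=-1)
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    assert np.all(np.abs(nn - 45.0) <= 5.0)


def test_pure_noise_rarely_reaches_seed_threshold():
    """Across 100 pure-noise volumes the maximum correlation stays below
    the default seed threshold in at least 95."""
    tmpl = matched_template(angular_sampling_deg=20.0)
    rng = np.random.default_rng(42)
    below = 0
    for _ in range(100):
        noise = np.clip(rng.normal(128, 20, (48, 32, 32)), 0, 255)
        vol = VoxelVolume(noise.astype(np.uint8), 5.0, "grayscale")
        f = tracing.cylinder_correlation(vol, tmpl, max_tilt_deg=MAX_TILT_DEG)
        below += f.correlation.max() < tracing.TraceParams().min_seed_correlation
    assert below >= 95


def test_in_plane_rotation_robustness():
    """Rotating a 19-filament bundle 30 degrees in-plane changes the traced
    filament count by at most 5% (here: not at all)."""
    pts, _ = sm.hex_lattice_sites(95.0, 45.0)
    counts = []
    for th in (0.0, np.radians(30.0)):
        c, s = np.cos(th), np.sin(th)
        centers = [(200.0 + c * y - s * x, 200.0 + s * y + c * x)
                   for y, x in pts]
        vol = _cylinder_volume(centers, (260, 81, 81), z_range=(20, 240))
        fields = tracing.cylinder_correlation(vol, matched_template(),
                                              max_tilt_deg=MAX_TILT_DEG)
        counts.append(len(tracing.trace_lines(fields)))
    assert counts[0] == len(pts)
    assert abs(counts[1] - counts[0]) <= 0.05 * counts[0]


def test_all_traces_respect_min_length(traced_filaments):
    assert np.all(traced_filaments.lengths_nm()
                  >= tracing.TraceParams().min_length_nm)


def test_consecutive_point_spacing_within_cone(traced_filaments):
    cone = tracing.TraceParams().search_cone_length_nm
    for f in traced_filaments.filaments:
        steps = np.linalg.norm(np.diff(f.points_nm, axis=0), axis=1)
        assert steps.max() <= cone + 1e-6


class TestRasterize:
    def test_tube_volume(self):
        f = tracing.Filament(1, np.array([[20.0, 100.0, 100.0],
                                          [520.0, 100.0, 100.0]]),
                             np.array([255.0, 255.0]))
        vol = tracing.rasterize(tracing.FilamentSet([f], 5.0),
                                (120, 41, 41), 5.0, 10.0)
        painted = (vol.data > 0).sum() * 5.0**3
        assert painted == pytest.approx(np.pi * 10.0**2 * 500.0, rel=0.10)

    def test_empty_set_and_two_filaments(self):
        empty = tracing.rasterize(tracing.FilamentSet([], 5.0), (20, 20, 20),
                                  5.0, 10.0)
        assert not empty.data.any()
        fs = tracing.FilamentSet([
            tracing.Filament(1, np.array([[10.0, 20.0, 20.0], [80.0, 20.0, 20.0]]),
                             np.zeros(2)),
            tracing.Filament(2, np.array([[10.0, 70.0, 70.0], [80.0, 70.0, 70.0]]),
                             np.zeros(2)),
        ], 5.0)
        vol = tracing.rasterize(fs, (20, 20, 20), 5.0, 10.0)
        assert set(np.unique(vol.data)) == {0, 1, 2}

    def test_out_of_bounds_polyline_rejected(self):
        f = tracing.Filament(1, np.array([[0.0, 0.0, 0.0], [500.0, 0.0, 0.0]]),
                             np.zeros(2))
        with pytest.raises(ValueError, match="bounds"):
            tracing.rasterize(tracing.FilamentSet([f], 5.0), (20, 20, 20),
                              5.0, 10.0)

    def test_radius_below_half_voxel_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            tracing.rasterize(tracing.FilamentSet([], 5.0), (20, 20, 20),
                              5.0, 1.0)


def test_jsonl_round_trip(tmp_path, traced_filaments):
    path = traced_filaments.to_jsonl(tmp_path / "fil.jsonl")
    back = tracing.FilamentSet.from_jsonl(path, voxel_nm=5.0)
    assert len(back) == len(traced_filaments)
    assert np.allclose(back.filaments[0].points_nm,
                       traced_filaments.filaments[0].points_nm)
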