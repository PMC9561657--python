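import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

import sarcomorph as sm
from sarcomorph.phantom import PhantomSpec


def test_spec_invariants():
    with pytest.raises(ValueError, match="lattice constant"):
        PhantomSpec(shape=(60, 30, 30), lattice_constant_nm=18.0)
    with pytest.raises(ValueError, match="overlap"):
        PhantomSpec(shape=(60, 30, 30), zdisk_csa_reduction=0.85)
    with pytest.raises(ValueError, match="taper"):
        PhantomSpec(shape=(60, 30, 30), taper_profile="linear")


def test_zero_delta_gives_straight_filaments_and_equal_csa():
    spec = sm.preset_spec("cylinder", n_periods=1, half_xy_nm=300.0)
    ph = sm.build_phantom(spec)
    for poly in ph.filament_centerlines().values():
        assert np.ptp(poly[:, 1]) == 0 and np.ptp(poly[:, 2]) == 0
    z_area = np.count_nonzero(ph.volumes["zdisk"].data.max(axis=0))
    a_area = np.count_nonzero(ph.volumes["aband"].data.max(axis=0))
    # equal up to a one-voxel ring around the disk circumference
    ring = 2 * np.pi * spec.myofibril_radius_nm / spec.voxel_nm
    assert abs(a_area - z_area) <= ring


def test_taper_compresses_end_lattice_to_sqrt_csa_ratio(grid_phantom,
                                                        grid_ground_truth):
    """At delta=0.4 the nearest-neighbor lattice constant of the filament
    centroids in the Z-end slab approaches a*sqrt(0.6), and matches the
    constructive per-slab ground truth."""
    spec = grid_phantom.spec
    zmask = grid_phantom.volumes["zdisk"].data > 0
    dist = sm.distance_field(grid_phantom.volumes["zdisk"])
    lab = grid_phantom.volumes["filaments"].data
    sel = (lab > 0) & (dist.data < 50.0)
    ids = np.unique(lab[sel])
    # one sarcomere segment only, else both ends flanking a Z-disk
    # contribute coincident centroids
    n_sites = len(grid_phantom.filament_sites)
    ids = ids[ids <= n_sites]
    cents = []
    for fid in ids:
        pts = np.argwhere(sel & (lab == fid))
        cents.append(pts[:, 1:].mean(axis=0) * spec.voxel_nm)
    nn = _pairwise_matrix(np.array(cents)).min(axis=1)
    measured = np.median(nn)
    gt_end = grid_ground_truth.lattice_constants_nm[0]
    assert measured == pytest.approx(gt_end, rel=0.06)
    a = spec.lattice_constant_nm
    assert a * np.sqrt(0.6) < measured < a  # compressed toward sqrt(1-delta)
    assert gt_end == pytest.approx(a * np.sqrt(0.6), rel=0.12)


def _pairwise_matrix(pts):
    d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
    np.fill_diagonal(d, np.inf)
    return d


def test_grid_mitochondria_all_z_adjacent_by_brute_force(grid_phantom):
    spec = grid_phantom.spec
    mito = np.argwhere(grid_phantom.volumes["mito"].data > 0)
    zd = np.argwhere(grid_phantom.volumes["zdisk"].data > 0)
    tree = cKDTree(zd * spec.voxel_nm)
    dists, _ = tree.query(mito * spec.voxel_nm)
    thr = spec.iband_width_nm + 200.0
    assert np.all(dists <= thr)


def test_organelle_volumes_are_disjoint(grid_phantom):
    names = ["filaments", "zdisk", "mito", "srt", "lipid"]
    masks = [grid_phantom.volumes[n].data > 0 for n in names]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            assert not np.any(masks[i] & masks[j]), (names[i], names[j])


def test_render_deterministic_and_noiseless_levels(grid_phantom):
    g1 = sm.render_grayscale(grid_phantom, snr=5.0, seed=11)
    g2 = sm.render_grayscale(grid_phantom, snr=5.0, seed=11)
    assert np.array_equal(g1.data, g2.data)
    clean = sm.render_grayscale(grid_phantom, snr=np.inf)
    fil = grid_phantom.volumes["filaments"].data > 0
    assert np.all(clean.data[fil] == 190)
    with pytest.raises(ValueError, match="snr"):
        sm.render_grayscale(grid_phantom, snr=0.0)


def test_render_empirical_snr(grid_phantom):
    snr = 5.0
    g = sm.render_grayscale(grid_phantom, snr=snr, seed=3)
    fil = grid_phantom.volumes["filaments"].data > 0
    bg = ~np.any([grid_phantom.volumes[n].data > 0
                  for n in ("filaments", "zdisk", "mito", "srt", "lipid")], axis=0)
    contrast = g.data[fil].mean() - g.data[bg].mean()
    assert contrast / g.data[bg].std() == pytest.approx(snr, rel=0.10)


def test_ground_truth_counts(grid_phantom, grid_ground_truth):
    gt = grid_ground_truth
    assert gt.csa_heterogeneity_pct == pytest.approx(40.0, abs=2.0)
    mito = grid_phantom.volumes["mito"].data
    cell = grid_phantom.volumes["cell"].data
    assert gt.mito_content == np.count_nonzero(mito) / np.count_nonzero(cell)
    assert gt.z_adjacent_fraction == 1.0
    assert gt.n_filaments == len(grid_phantom.filament_site_of_id)


def test_no_mitochondria_flags_undefined_fraction():
    spec = sm.preset_spec("cylinder", n_periods=1, half_xy_nm=300.0)
    gt = sm.ground_truth(sm.build_phantom(spec))
    assert gt.z_adjacent_fraction is None
    assert gt.mito_content == 0.0


def test_resolution_scaling_stability():
    """Halving the voxel size changes continuous ground-truth values <2%."""
    vals = {}
    for vx in (10.0, 5.0):
        spec = sm.preset_spec("cylinder", n_periods=1, voxel_nm=vx,
                              half_xy_nm=300.0, zdisk_csa_reduction=0.3)
        vals[vx] = sm.ground_truth(sm.build_phantom(spec)).csa_heterogeneity_pct
    assert vals[5.0] == pytest.approx(vals[10.0], rel=0.02)


def test_phantom_save_round_trip(grid_phantom, tmp_path):
    out = grid_phantom.save(tmp_path / "ph")
    back = sm.load_volume(out / "zdisk.h5")
    assert np.array_equal(back.data, grid_phantom.volumes["zdisk"].data)
    assert (out / "ground_truth.json").exists()
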