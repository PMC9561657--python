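import numpy as np
import pytest
from scipy.spatial import cKDTree

from sarcomorph import proximity
from sarcomorph.volume import VoxelVolume


def _vol(data, vx=10.0, kind="binary"):
    return VoxelVolume(np.asarray(data), vx, kind)


def test_face_adjacent_distance_is_one_voxel():
    m = np.zeros((5, 5, 5), np.uint8)
    m[2, 2, 2] = 1
    f = proximity.distance_field(_vol(m, 7.0))
    assert f.data[2, 2, 3] == pytest.approx(7.0)
    assert f.data[2, 2, 2] == 0.0
    assert f.data[2, 3, 3] == pytest.approx(7.0 * np.sqrt(2))


def test_distance_field_matches_brute_force_exactly():
    rng = np.random.default_rng(0)
    mask = rng.random((24, 24, 24)) < 0.01
    mask[0, 0, 0] = True
    vx = 7.0
    f = proximity.distance_field(_vol(mask.astype(np.uint8), vx))
    src = np.argwhere(mask) * vx
    sample = np.argwhere(~mask)
    sample = sample[rng.choice(len(sample), 1000, replace=False)]
    brute = cKDTree(src).query(sample * vx)[0]
    assert np.allclose(f.data[tuple(sample.T)], brute, atol=1e-9)


def test_empty_mask_rejected():
    with pytest.raises(ValueError, match="empty"):
        proximity.distance_field(_vol(np.zeros((4, 4, 4), np.uint8)))


def test_min_distance_per_filament_constructed_gap():
    """Two parallel tubes with an 80 nm face gap: per-filament minimum
    distance equals the gap within a voxel diagonal, and a touching
    filament reports zero."""
    vx = 10.0
    lab = np.zeros((40, 30, 30), np.int32)
    org = np.zeros_like(lab)
    org[:, 5:8, 5:8] = 1
    lab[:, 16:19, 5:8] = 1       # gap: rows 8..15 -> 8 voxels = 80 nm
    lab[:, 5:8, 8:11] = 2
    lab[0, 6, 6] = 2             # one voxel on the organelle itself
    fld = proximity.distance_field(_vol(org.astype(np.uint8), vx))
    table = proximity.min_distance_per_filament(_vol(lab, vx, "labels"), fld)
    got = dict(zip(table["id"], table["min_distance_nm"]))
    assert got[1] == pytest.approx(90.0, abs=vx * np.sqrt(3))  # center-to-center
    assert got[2] == 0.0


def test_min_distance_equals_brute_force_on_64_cube():
    rng = np.random.default_rng(3)
    vx = 8.0
    org = rng.random((64, 64, 64)) < 0.002
    org[1, 1, 1] = True
    lab = np.zeros((64, 64, 64), np.int32)
    for fid, y in enumerate((10, 30, 50), start=1):
        lab[5:60, y, y] = fid
    lab[org] = 0
    fld = proximity.distance_field(_vol(org.astype(np.uint8), vx))
    table = proximity.min_distance_per_filament(_vol(lab, vx, "labels"), fld)
    tree = cKDTree(np.argwhere(org) * vx)
    for fid in (1, 2, 3):
        brute = tree.query(np.argwhere(lab == fid) * vx)[0].min()
        got = float(table.loc[table.id == fid, "min_distance_nm"].iloc[0])
        assert got == pytest.approx(brute, abs=1e-9)


def test_geometry_mismatch_rejected():
    lab = _vol(np.ones((4, 4, 4), np.int32), 10.0, "labels")
    fld = VoxelVolume(np.zeros((5, 5, 5)), 10.0, "distance")
    with pytest.raises(ValueError, match="mismatch"):
        proximity.min_distance_per_filament(lab, fld)


def test_proximity_bins_are_half_open():
    assert proximity.proximity_bin(0.0) == 0
    assert proximity.proximity_bin(0.5) == 1
    assert proximity.proximity_bin(100.0) == 1
    assert proximity.proximity_bin(100.001) == 2


class TestPartition:
    def test_constructed_30_70_split(self):
        vx = 10.0
        zd = np.zeros((160, 20, 20), np.uint8)
        zd[0] = 1
        mito = np.zeros_like(zd)
        mito[5:35, 5:8, 5:8] = 1    # within 400 nm of the Z plane
        mito[45:115, 5:8, 5:8] = 1  # beyond
        part = proximity.partition_mitochondria(_vol(mito, vx), _vol(zd, vx),
                                                iband_width_nm=200.0)
        assert part.z_adjacent_fraction == pytest.approx(0.300, abs=0.01)
        assert part.z_adjacent_voxels + part.non_adjacent_voxels == \
            part.total_mito_voxels

    def test_distant_tubes_give_zero_fraction(self):
        vx = 10.0
        zd = np.zeros((160, 20, 20), np.uint8)
        zd[0] = 1
        mito = np.zeros_like(zd)
        mito[100:150, 5:8, 5:8] = 1  # 1000+ nm away
        part = proximity.partition_mitochondria(_vol(mito, vx), _vol(zd, vx),
                                                iband_width_nm=200.0)
        assert part.z_adjacent_fraction == 0.0

    def test_fraction_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        zd = np.zeros((60, 16, 16), np.uint8)
        zd[0] = 1
        mito = (rng.random(zd.shape) < 0.05).astype(np.uint8)
        mito[0] = 0
        fracs = [proximity.partition_mitochondria(
            _vol(mito), _vol(zd), iband_width_nm=0.0, margin_nm=m
        ).z_adjacent_fraction for m in (50, 100, 200, 400, 800)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_no_mitochondria_flagged(self):
        zd = np.zeros((10, 8, 8), np.uint8)
        zd[0] = 1
        part = proximity.partition_mitochondria(
            _vol(np.zeros_like(zd)), _vol(zd), iband_width_nm=200.0)
        assert part.z_adjacent_fraction is None
        assert part.mito_content == 0.0

    def test_empty_zdisk_rejected(self):
        mito = np.ones((8, 8, 8), np.uint8)
        with pytest.raises(ValueError, match="empty"):
            proximity.partition_mitochondria(
                _vol(mito), _vol(np.zeros_like(mito)), iband_width_nm=200.0)


class TestLocalThickness:
    def test_solid_sphere(self):
        shape = (31, 31, 31)
        zz, yy, xx = np.indices(shape)
        sph = ((zz - 15) ** 2 + (yy - 15) ** 2 + (xx - 15) ** 2) * 100 <= 100.0**2
        fld, summary = proximity.local_thickness(_vol(sph.astype(np.uint8), 10.0))
        vals = fld.data[sph]
        assert np.all(np.abs(vals - 200.0) <= 2 * 10.0)
        assert summary["median_nm"] == pytest.approx(200.0, abs=10.0)

    def test_slab(self):
        m = np.zeros((40, 40, 40), np.uint8)
        m[:, 10:25, :] = 1  # 15 voxels at 8 nm = 120 nm
        _, summary = proximity.local_thickness(_vol(m, 8.0))
        assert summary["median_nm"] == pytest.approx(120.0, abs=8.0)

    def test_two_tube_populations_recover_diameter_ratio(self):
        """Tubes of diameter d and 2.45 d: the ratio of the population
        median thicknesses recovers 2.45 within 5%."""
        vx = 4.0
        shape = (40, 120, 60)
        yy, xx = np.meshgrid(np.arange(shape[1]) * vx,
                             np.arange(shape[2]) * vx, indexing="ij")
        t1 = (yy - 100) ** 2 + (xx - 120) ** 2 <= 40.0**2
        t2 = (yy - 320) ** 2 + (xx - 120) ** 2 <= 98.0**2
        m = np.zeros(shape, bool)
        m[:, t1] = True
        m[:, t2] = True
        fld, _ = proximity.local_thickness(_vol(m.astype(np.uint8), vx))
        ratio = np.median(fld.data[:, t2]) / np.median(fld.data[:, t1])
        assert ratio == pytest.approx(2.45, rel=0.05)
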