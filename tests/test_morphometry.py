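"""Morphometry against phantom ground truth and exact topology oracles."""

import numpy as np
import pytest
from scipy import ndimage

from bonefrag.morphometry import (
    SegmentationParams,
    cortical_morphometry,
    euler_characteristic_3d,
    local_thickness,
    segment_volume,
    trabecular_morphometry,
)
from bonefrag.phantoms import (
    VoxelVolume,
    make_cortical_tube_phantom,
    make_trabecular_lattice_phantom,
)


def _plate_interior_voi(n, voxel_mm, n_cells, pitch):
    c = (np.arange(n) - (n - 1) / 2) * voxel_mm
    half = n_cells * pitch / 2
    i0 = int(np.argmin(np.abs(c + half)))
    i1 = int(np.argmin(np.abs(c - half)))
    return slice(i0, i1 + 1)


class TestSegmentation:
    def test_background_volume_gives_empty_mask(self):
        vol = VoxelVolume(np.zeros((8, 8, 8), np.float32), 12.0)
        with pytest.warns(UserWarning, match="empty mask"):
            mask = segment_volume(vol, SegmentationParams(threshold=100.0))
        assert not mask.any()

    def test_noiseless_tube_mask_equals_ground_truth(self):
        vol, gt = make_cortical_tube_phantom(1.0, 0.6, 0.05, tmd_mean=900)
        mask = segment_volume(vol, SegmentationParams(gauss_sigma=0,
                                                      threshold=450))
        assert np.array_equal(mask, gt["mask"])

    def test_noisy_tube_misclassification_below_one_percent(self):
        vol, gt = make_cortical_tube_phantom(1.0, 0.6, 0.05, tmd_mean=900,
                                             noise_sd=100.0, seed=4)
        mask = segment_volume(vol, SegmentationParams(gauss_sigma=1.2,
                                                      gauss_support=2,
                                                      threshold=450))
        frac = np.mean(mask != gt["mask"])
        assert frac < 0.01


class TestLocalThickness:
    def test_slab_thickness_is_exact(self):
        m = np.zeros((30, 20, 20), bool)
        m[10:20] = True  # 10-voxel slab
        th = local_thickness(m)
        assert th[15, 10, 10] == pytest.approx(10.0, abs=1.0)

    def test_background_is_zero(self):
        m = np.zeros((10, 10, 10), bool)
        m[4:6, 4:6, 4:6] = True
        th = local_thickness(m)
        assert th[0, 0, 0] == 0.0


class TestEuler:
    @pytest.mark.parametrize("builder,expected", [
        (lambda: np.ones((1, 1, 1), bool), 1),            # ball
        (lambda: np.ones((3, 3, 3), bool), 1),            # solid cube
        (lambda: _torus(), 0),                            # solid torus
        (lambda: _hollow_cube(), 2),                      # spherical shell
    ])
    def test_known_topologies(self, builder, expected):
        assert euler_characteristic_3d(builder()) == expected

    def test_matches_set_enumeration_on_random_volumes(self):
        from _oracles import euler_characteristic_sets

        rng = np.random.default_rng(0)
        for _ in range(8):
            m = rng.random((7, 7, 7)) < 0.4
            assert euler_characteristic_3d(m) == euler_characteristic_sets(m)


def _torus():
    m = np.zeros((3, 9, 9), bool)
    m[1, 2:7, 2:7] = True
    m[1, 4, 4] = False
    return m


def _hollow_cube():
    m = np.ones((5, 5, 5), bool)
    m[2, 2, 2] = False
    return m


class TestTrabecular:
    def test_solid_block_flags(self):
        vol = VoxelVolume(np.full((10, 10, 10), 900.0, np.float32), 12.0)
        tm = trabecular_morphometry(np.ones((10, 10, 10), bool), vol)
        assert tm.bvtv == 1.0
        assert tm.flags.get("tb_sp_undefined")

    def test_empty_phase_flags(self):
        vol = VoxelVolume(np.zeros((6, 6, 6), np.float32), 12.0)
        tm = trabecular_morphometry(np.zeros((6, 6, 6), bool), vol)
        assert tm.flags.get("empty_bone_phase")
        assert tm.bvtv == 0.0

    def test_rod_lattice_recovery(self):
        vol, gt = make_trabecular_lattice_phantom(0.06, 0.30, n_cells=2,
                                                  voxel_size_um=12.0,
                                                  tmd_mean=900)
        mask = segment_volume(vol, SegmentationParams(gauss_sigma=0,
                                                      threshold=450))
        tm = trabecular_morphometry(mask, vol)
        assert tm.bvtv == pytest.approx(gt["bvtv"], rel=1e-6)
        assert abs(tm.tb_th - gt["tb_th"]) <= 2 * 0.012  # 2 voxels at 12 um
        assert tm.conn_d == pytest.approx(gt["conn_d"], rel=1e-9)

    def test_plate_lattice_spacing_and_number(self):
        vol, gt = make_trabecular_lattice_phantom(0.06, 0.30, n_cells=3,
                                                  style="plates",
                                                  voxel_size_um=12.0)
        mask = segment_volume(vol, SegmentationParams(gauss_sigma=0,
                                                      threshold=450))
        voi = _plate_interior_voi(mask.shape[0], 0.012, 3, 0.30)
        tm = trabecular_morphometry(mask, vol, voi=voi)
        assert tm.tb_sp == pytest.approx(gt["tb_sp"], abs=0.012)
        assert tm.tb_n == pytest.approx(gt["tb_n"], rel=0.10)
        assert abs(tm.tb_th - gt["tb_th"]) <= 2 * 0.012

    def test_torus_connectivity_density(self):
        # one loop in an empty VOI: chi = 0 so Conn.D = 1/TV
        m = np.zeros((8, 12, 12), bool)
        m[3:5, 2:9, 2:9] = True
        m[3:5, 4:7, 4:7] = False
        vol = VoxelVolume(np.where(m, 900, 0).astype(np.float32), 12.0)
        tm = trabecular_morphometry(m, vol, peel_voxels=0)
        tv = m.size * 0.012**3
        assert euler_characteristic_3d(m) == 0
        assert tm.conn_d == pytest.approx(1.0 / tv)

    def test_bvtv_rotation_invariance(self):
        vol, _ = make_trabecular_lattice_phantom(0.08, 0.3, n_cells=2,
                                                 voxel_size_um=24.0)
        mask = segment_volume(vol, SegmentationParams(gauss_sigma=0,
                                                      threshold=450))
        base = trabecular_morphometry(mask, vol)
        rot = np.rot90(mask, axes=(0, 1)).copy()
        vol_r = VoxelVolume(np.rot90(vol.data, axes=(0, 1)).copy(), 24.0)
        got = trabecular_morphometry(rot, vol_r)
        assert got.bvtv == pytest.approx(base.bvtv, rel=1e-12)
        assert abs(got.tb_th - base.tb_th) <= 0.024  # 1 voxel

    def test_peel_raises_tmd_with_depressed_surface(self):
        # partial-volume emulation: surface voxels get lowered density
        vol, gt = make_trabecular_lattice_phantom(0.1, 0.3, n_cells=2,
                                                  voxel_size_um=12.0,
                                                  tmd_mean=900)
        mask = gt["mask"]
        surface = mask & ~ndimage.binary_erosion(mask)
        data = vol.data.copy()
        data[surface] *= 0.6
        vol2 = VoxelVolume(data, 12.0)
        t0 = trabecular_morphometry(mask, vol2, peel_voxels=0).tb_tmd
        t2 = trabecular_morphometry(mask, vol2, peel_voxels=2).tb_tmd
        assert t2 >= t0


class TestCortical:
    def test_annulus_closed_forms_at_12um(self):
        vol, gt = make_cortical_tube_phantom(1.0, 0.6, 0.036, tmd_mean=900,
                                             voxel_size_um=12.0)
        mask = segment_volume(vol, SegmentationParams(gauss_sigma=0,
                                                      threshold=450))
        cm = cortical_morphometry(mask, vol)
        assert cm.ct_ar == pytest.approx(gt["ct_ar"], rel=0.02)
        assert cm.tt_ar == pytest.approx(gt["tt_ar"], rel=0.02)
        assert cm.ct_th == pytest.approx(gt["ct_th"], rel=0.02)
        assert cm.i_min == pytest.approx(gt["i_min"], rel=0.02)
        assert cm.z_min == pytest.approx(gt["z_min"], rel=0.02)
        assert cm.ct_po == 0.0

    def test_porosity_recovery(self):
        vol, gt = make_cortical_tube_phantom(1.0, 0.6, 0.036, tmd_mean=900,
                                             porosity=0.05, seed=9,
                                             voxel_size_um=12.0)
        cm = cortical_morphometry(gt["mask"], vol)
        assert cm.ct_po == pytest.approx(gt["ct_po_voxel"], abs=0.005)

    def test_uniform_density_tmd_exact_after_peel(self):
        vol, gt = make_cortical_tube_phantom(1.0, 0.6, 0.06, tmd_mean=900,
                                             voxel_size_um=12.0)
        cm = cortical_morphometry(gt["mask"], vol, peel_voxels=2)
        assert cm.ct_tmd == pytest.approx(900.0)

    def test_imin_rotation_invariance(self):
        # in-plane rotation by 90 deg must leave I_min unchanged within
        # discretization (exact for array rotation)
        vol, gt = make_cortical_tube_phantom(0.8, 0.5, 0.036, tmd_mean=900,
                                             voxel_size_um=12.0)
        mask = gt["mask"]
        cm = cortical_morphometry(mask, vol)
        rot = np.rot90(mask, axes=(1, 2)).copy()
        vol_r = VoxelVolume(np.rot90(vol.data, axes=(1, 2)).copy(), 12.0)
        cm_r = cortical_morphometry(rot, vol_r)
        assert cm_r.i_min == pytest.approx(cm.i_min, rel=0.005)

    def test_broken_ring_everywhere_raises(self):
        # half-annulus: the ring never closes
        n = 80
        c = (np.arange(n) - (n - 1) / 2) * 0.012
        yy, xx = np.meshgrid(c, c, indexing="ij")
        rr = np.hypot(yy, xx)
        half_ring = (rr >= 0.25) & (rr < 0.4) & (yy > 0)
        m = np.broadcast_to(half_ring, (2, n, n)).copy()
        vol = VoxelVolume(np.where(m, 900, 0).astype(np.float32), 12.0)
        with pytest.raises(ValueError, match="broken"):
            cortical_morphometry(m, vol, closing_radius=0)
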