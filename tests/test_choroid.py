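import numpy as np
import pytest

from octamnv import OctVolume, ScanGrid, Surface, phantoms
from octamnv.choroid import (
    attenuation_compensate,
    circle_mask,
    ct_map,
    cvi_metrics,
    segment_choroid_vessels,
)


class TestAttenuationCompensation:
    def test_constant_ascan_becomes_increasing(self):
        grid = ScanGrid(nx=4, ny=4, pitch_x=24, pitch_y=24, pitch_z=8)
        vol = OctVolume(np.full((50, 4, 4), 10.0), grid)
        out = attenuation_compensate(vol)
        profile = out.voxels[:, 0, 0]
        assert (np.diff(profile) > 0).all()

    def test_shadow_contrast_reduced(self):
        """A shadow cast below a bright layer shrinks at least 2x."""
        grid = ScanGrid(nx=40, ny=20, pitch_x=24, pitch_y=24, pitch_z=8)
        vox = np.full((60, 20, 40), 100.0)
        vox[10:13, :, :20] = 400.0  # bright layer over the left half
        vox[13:, :, :20] *= 0.5  # its shadow
        vol = OctVolume(vox, grid)
        out = attenuation_compensate(vol)
        # contrast across the shadow boundary at a deep plane
        before = vox[40, 0, 25] / vox[40, 0, 15]
        after = out.voxels[40, 0, 25] / out.voxels[40, 0, 15]
        assert abs(after - 1) < abs(before - 1) / 2

    def test_global_scale_invariance(self):
        grid = ScanGrid(nx=10, ny=10, pitch_x=24, pitch_y=24, pitch_z=8)
        rng = np.random.default_rng(0)
        vox = rng.uniform(1, 200, (40, 10, 10))
        a = attenuation_compensate(OctVolume(vox, grid))
        b = attenuation_compensate(OctVolume(vox * 13.7, grid))
        # identical up to the output dynamic range, which follows the input
        np.testing.assert_allclose(b.voxels, a.voxels * 13.7, rtol=1e-9)

    def test_all_zero_ascan_left_unchanged(self):
        grid = ScanGrid(nx=4, ny=4, pitch_x=24, pitch_y=24, pitch_z=8)
        vox = np.full((20, 4, 4), 50.0)
        vox[:, 2, 2] = 0.0
        out = attenuation_compensate(OctVolume(vox, grid))
        assert (out.voxels[:, 2, 2] == 0.0).all()


class TestThicknessMap:
    def test_uniform_phantom(self, choroid_grid):
        p = phantoms.make_choroid_phantom(choroid_grid, thickness_um=200.0)
        _, mct = ct_map(p.bm, p.csi)
        assert mct == 200.0

    def test_symmetric_ramp_averages_to_center_value(self, choroid_grid):
        g = choroid_grid
        x = np.arange(g.nx)[None, :] * np.ones((g.ny, 1))
        thick = 150.0 + 0.5 * (x - g.fovea_xy[0]) * g.pitch_x / 1000.0
        bm = Surface("bm", np.full((g.ny, g.nx), 80.0), g)
        csi = Surface("csi", 80.0 + thick, g)
        _, mct = ct_map(bm, csi)
        assert mct == pytest.approx(150.0, abs=1e-9)

    def test_matches_per_pixel_mean_oracle(self, choroid_grid):
        g = choroid_grid
        rng = np.random.default_rng(5)
        thick = rng.uniform(120, 350, (g.ny, g.nx))
        bm = Surface("bm", np.full((g.ny, g.nx), 80.0), g)
        csi = Surface("csi", 80.0 + thick, g)
        tmap, mct = ct_map(bm, csi)
        circ = circle_mask(g, 5.0)
        oracle = thick[circ].sum() / circ.sum()
        assert mct == pytest.approx(oracle, abs=1e-9)
        np.testing.assert_allclose(tmap, thick)

    def test_clipped_circle_rejected(self):
        g = ScanGrid(nx=100, ny=100, pitch_x=24, pitch_y=24, pitch_z=8)  # 2.4 mm scan
        bm = Surface("bm", np.full((100, 100), 80.0), g)
        csi = Surface("csi", np.full((100, 100), 280.0), g)
        with pytest.raises(ValueError, match="clipped"):
            ct_map(bm, csi)


class TestVesselSegmentation:
    def test_two_valued_phantom_recovered_exactly(self, choroid_grid):
        p = phantoms.make_choroid_phantom(
            choroid_grid, seed=0, thickness_um=240.0, n_cylinders=20
        )
        vessels = segment_choroid_vessels(p.volume, p.bm, p.csi)
        truth = p.volume.voxels == 50.0
        zc = (np.arange(p.volume.nz) + 0.5) * choroid_grid.pitch_z
        slab = (zc[:, None, None] >= p.bm.z_um[None]) & (zc[:, None, None] < p.csi.z_um[None])
        assert (vessels == (truth & slab)).all()

    def test_vessel_free_slab_gives_empty_mask(self, choroid_grid):
        p = phantoms.make_choroid_phantom(choroid_grid, vessel_fraction=0.0)
        vessels = segment_choroid_vessels(p.volume, p.bm, p.csi)
        assert not vessels.any()


class TestCvi:
    def test_constructed_fraction_recovered_exactly(self, choroid_grid):
        p = phantoms.make_choroid_phantom(
            choroid_grid, thickness_um=240.0, vessel_fraction=0.30
        )
        vessels = segment_choroid_vessels(p.volume, p.bm, p.csi)
        cm = cvi_metrics(vessels, p.volume, p.bm, p.csi)
        assert cm.cvi == pytest.approx(0.30, abs=1e-9)
        assert cm.mct_um == 240.0

    def test_all_vessel_slab_gives_one(self, choroid_grid):
        p = phantoms.make_choroid_phantom(choroid_grid, vessel_fraction=0.5)
        zc = (np.arange(p.volume.nz) + 0.5) * choroid_grid.pitch_z
        slab = (zc[:, None, None] >= p.bm.z_um[None]) & (zc[:, None, None] < p.csi.z_um[None])
        cm = cvi_metrics(slab, p.volume, p.bm, p.csi)
        assert cm.cvi == 1.0

    def test_cvi_is_slab_weighted_mean_of_map(self, choroid_grid):
        p = phantoms.make_choroid_phantom(
            choroid_grid, seed=3, thickness_um=240.0, n_cylinders=25
        )
        vessels = segment_choroid_vessels(p.volume, p.bm, p.csi)
        cm = cvi_metrics(vessels, p.volume, p.bm, p.csi)
        zc = (np.arange(p.volume.nz) + 0.5) * choroid_grid.pitch_z
        slab = (zc[:, None, None] >= p.bm.z_um[None]) & (zc[:, None, None] < p.csi.z_um[None])
        w = slab.sum(axis=0)
        circ = circle_mask(choroid_grid, 5.0)
        weighted = np.nansum(cm.cvi_map[circ] * w[circ]) / w[circ].sum()
        assert cm.cvi == pytest.approx(weighted, abs=1e-12)

    def test_random_cylinders_recovered_within_tolerance(self, choroid_grid):
        """CVI within ±0.02 and MCT within 0.5 µm across seeded phantoms."""
        for seed in range(5):
            p = phantoms.make_choroid_phantom(
                choroid_grid, seed=seed, thickness_um=240.0, n_cylinders=40
            )
            vessels = segment_choroid_vessels(p.volume, p.bm, p.csi)
            cm = cvi_metrics(vessels, p.volume, p.bm, p.csi)
            assert cm.cvi == pytest.approx(p.truth_cvi, abs=0.02)
            assert cm.mct_um == pytest.approx(p.truth_mct_um, abs=0.5)

    def test_cvi_invariant_to_global_intensity_scale(self, choroid_grid):
        p = phantoms.make_choroid_phantom(
            choroid_grid, seed=4, thickness_um=240.0, n_cylinders=30
        )
        scaled = OctVolume(p.volume.voxels * 5.0, choroid_grid)
        v1 = segment_choroid_vessels(p.volume, p.bm, p.csi)
        v2 = segment_choroid_vessels(scaled, p.bm, p.csi)
        cm1 = cvi_metrics(v1, p.volume, p.bm, p.csi)
        cm2 = cvi_metrics(v2, scaled, p.bm, p.csi)
        assert cm2.cvi == pytest.approx(cm1.cvi, abs=1e-12)

    def test_thickening_at_fixed_fraction_leaves_cvi_stable(self, choroid_grid):
        cvis = []
        for thick in (160.0, 320.0):
            p = phantoms.make_choroid_phantom(
                choroid_grid, thickness_um=thick, vessel_fraction=0.30
            )
            vessels = segment_choroid_vessels(p.volume, p.bm, p.csi)
            cvis.append(cvi_metrics(vessels, p.volume, p.bm, p.csi).cvi)
        assert abs(cvis[1] - cvis[0]) <= 0.01
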