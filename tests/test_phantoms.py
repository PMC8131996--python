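import numpy as np
import pytest

from octamnv import ScanGrid, phantoms


class TestLesionPhantom:
    def test_disk_area_matches_pixel_counting_oracle(self, grid6mm):
        p = phantoms.make_lesion_phantom(grid6mm, seed=0, radius_um=1000.0)
        # independent brute-force rasterization of the same disk
        cx = cy = (grid6mm.nx - 1) / 2
        count = 0
        for yy in range(grid6mm.ny):
            for xx in range(grid6mm.nx):
                if ((xx - cx) * 12.0) ** 2 + ((yy - cy) * 12.0) ** 2 <= 1000.0**2:
                    count += 1
        assert p.truth_mnv.pixels.sum() == count

    def test_empty_lesion_request_gives_all_false_masks(self, grid6mm):
        p = phantoms.make_lesion_phantom(grid6mm, seed=0, empty=True)
        assert not p.truth_mnv.pixels.any()
        assert not p.truth_vessels.pixels.any()

    def test_seed_determinism(self, grid6mm):
        a = phantoms.make_lesion_phantom(grid6mm, seed=5, noise_sd=0.05)
        b = phantoms.make_lesion_phantom(grid6mm, seed=5, noise_sd=0.05)
        assert (a.volume.voxels == b.volume.voxels).all()
        assert (a.truth_vessels.pixels == b.truth_vessels.pixels).all()

    def test_tiny_radius_rejected(self, grid6mm):
        with pytest.raises(ValueError, match="radius"):
            phantoms.make_lesion_phantom(grid6mm, radius_um=20.0)

    def test_skeleton_lies_on_vessels_inside_lesion(self, lesion_phantom):
        p = lesion_phantom
        assert (p.truth_skeleton.pixels & ~p.truth_vessels.pixels).sum() == 0
        assert (p.truth_vessels.pixels & ~p.truth_mnv.pixels).sum() == 0


class TestCcPhantom:
    def test_truth_fraction_matches_pixel_counting(self, grid6mm):
        disks = [(100.0, 100.0, 50.0), (200.0, 120.0, 50.0), (150.0, 220.0, 50.0)]
        p = phantoms.make_cc_phantom(grid6mm, fd_disks=disks)
        # oracle: per-disk pixel-center membership, summed (disks disjoint)
        total = 0
        for (cx, cy, d) in disks:
            y, x = np.mgrid[0:500, 0:500]
            total += int(
                ((((x - cx) * 12.0) ** 2 + ((y - cy) * 12.0) ** 2) <= (d / 2) ** 2).sum()
            )
        assert p.truth_fd.pixels.sum() == total
        assert (p.cc_flow.pixels[p.truth_fd.pixels] < 100).all()

    def test_zero_disks_zero_noise(self, grid6mm):
        p = phantoms.make_cc_phantom(grid6mm, fd_disks=())
        assert not p.truth_fd.pixels.any()
        assert p.cc_flow.pixels.std() == 0

    def test_disk_beyond_grid_rejected(self, grid6mm):
        with pytest.raises(ValueError, match="beyond"):
            phantoms.make_cc_phantom(grid6mm, fd_disks=[(2.0, 2.0, 200.0)])

    def test_random_disks_are_disjoint_and_avoid_lesion(self, grid6mm, lesion_phantom):
        rng = np.random.default_rng(3)
        disks = phantoms.random_fd_disks(
            grid6mm, rng, n=15, forbidden=lesion_phantom.truth_mnv.pixels
        )
        p = phantoms.make_cc_phantom(grid6mm, fd_disks=disks)
        per_disk = sum(
            phantoms._disk_mask(grid6mm, x, y, d / 2).sum() for (x, y, d) in disks
        )
        assert p.truth_fd.pixels.sum() == per_disk  # no overlap
        assert not (p.truth_fd.pixels & lesion_phantom.truth_mnv.pixels).any()


class TestPedPhantom:
    def test_analytic_volume_cross_checked_by_fine_grid_integration(self):
        h, sigma = 100.0, 250.0
        grid = ScanGrid(nx=500, ny=500, pitch_x=12, pitch_y=12, pitch_z=4)
        p = phantoms.make_ped_phantom(grid, bumps=[(249.5, 249.5, h, sigma)])
        assert p.truth_total_mm3 == pytest.approx(2 * np.pi * sigma**2 * h * 1e-9)
        assert p.truth_total_mm3 == pytest.approx(0.0393, abs=5e-5)
        # independent fine-grid numeric integration of the Gaussian
        step = 2.0  # µm
        r = np.arange(0, 3000, step)
        integ = np.trapezoid(2 * np.pi * r * h * np.exp(-(r**2) / (2 * sigma**2)), r)
        assert p.truth_total_mm3 == pytest.approx(integ * 1e-9, rel=1e-5)

    def test_no_bumps_rpe_equals_bm(self, grid_small):
        p = phantoms.make_ped_phantom(grid_small, bumps=[])
        assert (p.rpe.z_um == p.bm.z_um).all()
        assert p.truth_total_mm3 == 0.0

    def test_two_disjoint_bumps_double_the_volume(self, grid6mm):
        one = phantoms.make_ped_phantom(grid6mm, bumps=[(150.0, 150.0, 80.0, 150.0)])
        two = phantoms.make_ped_phantom(
            grid6mm, bumps=[(150.0, 150.0, 80.0, 150.0), (350.0, 350.0, 80.0, 150.0)]
        )
        assert two.truth_total_mm3 == pytest.approx(2 * one.truth_total_mm3)

    def test_narrow_bump_rejected(self, grid_small):
        with pytest.raises(ValueError, match="sigma"):
            phantoms.make_ped_phantom(grid_small, bumps=[(50.0, 50.0, 80.0, 5.0)])


class TestChoroidPhantom:
    def test_constructed_fraction_and_thickness(self, choroid_grid):
        p = phantoms.make_choroid_phantom(
            choroid_grid, thickness_um=240.0, vessel_fraction=0.30
        )
        assert p.truth_mct_um == 240.0
        assert p.truth_cvi == pytest.approx(0.30, abs=1e-9)

    def test_zero_fraction_gives_zero_cvi(self, choroid_grid):
        p = phantoms.make_choroid_phantom(choroid_grid, vessel_fraction=0.0)
        assert p.truth_cvi == 0.0

    def test_cylinder_truth_equals_brute_force_count(self, choroid_grid):
        p = phantoms.make_choroid_phantom(
            choroid_grid, seed=2, thickness_um=240.0, n_cylinders=25
        )
        # recount from the emitted voxel values, inside the 5-mm circle
        grid = choroid_grid
        zc = (np.arange(p.volume.nz) + 0.5) * grid.pitch_z
        slab = (zc[:, None, None] >= p.bm.z_um[None]) & (zc[:, None, None] < p.csi.z_um[None])
        y, x = np.mgrid[0 : grid.ny, 0 : grid.nx]
        fx, fy = grid.fovea_xy
        circ = ((x - fx) * grid.pitch_x) ** 2 + ((y - fy) * grid.pitch_y) ** 2 <= 2500.0**2
        vessel = (p.volume.voxels == 50.0) & slab
        expect = vessel[:, circ].sum() / slab[:, circ].sum()
        assert p.truth_cvi == pytest.approx(expect, abs=1e-12)

    def test_excessive_fraction_rejected(self, choroid_grid):
        with pytest.raises(ValueError, match="0.95"):
            phantoms.make_choroid_phantom(choroid_grid, vessel_fraction=0.99)


class TestCohort:
    def test_large_sample_means_match_configured_moments(self):
        n = 100_000
        coh = phantoms.make_cohort(seed=0, n_no=n, n_yes=n)
        for metric, moms in phantoms.DEFAULT_COHORT_MOMENTS.items():
            for group, gname in (("no", "no_exudation"), ("yes", "exudation")):
                mean, sd = moms["v2"][group]
                got = coh.loc[coh.group == gname, f"{metric}_v2"].mean()
                assert got == pytest.approx(mean, abs=max(3 * sd / np.sqrt(n), 1e-9))

    def test_zero_sd_collapses_to_mean(self):
        moments = {"vad": {"v2": {"no": (0.5, 0.0), "yes": (0.4, 0.0)},
                           "rate": {"no": (0.0, 0.0), "yes": (0.0, 0.0)}}}
        coh = phantoms.make_cohort(seed=1, moments=moments)
        assert (coh.loc[coh.group == "no_exudation", "vad_v2"] == 0.5).all()
        assert (coh["vad_v1"] == coh["vad_v2"]).all()

    def test_seed_determinism(self):
        a = phantoms.make_cohort(seed=9)
        b = phantoms.make_cohort(seed=9)
        assert a.equals(b)

    def test_minimum_group_size_enforced(self):
        with pytest.raises(ValueError):
            phantoms.make_cohort(n_no=1)

    def test_lognormal_option_is_skewed(self):
        moments = {"vad": {"v2": {"no": (1.0, 0.5), "yes": (1.0, 0.5)},
                           "rate": {"no": (0.0, 0.1), "yes": (0.0, 0.1)}}}
        coh = phantoms.make_cohort(seed=2, n_no=5000, n_yes=2,
                                   moments=moments, distribution="lognormal-shifted")
        x = coh.loc[coh.group == "no_exudation", "vad_v2"]
        assert x.mean() == pytest.approx(1.0, abs=0.05)
        assert x.skew() > 1.0
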