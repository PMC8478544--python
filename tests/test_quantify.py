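import numpy as np
import pytest

from aortamorph.plaque_seg import PlaqueResult
from aortamorph.quantify import (
    build_report,
    lesion_surface,
    mask_surface,
    mask_volume,
    per_slice_metrics,
    volume_fractions,
    wall_thickness,
)
from aortamorph.volume_io import BinaryMask
from aortamorph.wall_lumen_seg import WallLumenResult

VS = 0.01


def sphere_mask(r, pad=4, vs=VS):
    n = 2 * (r + pad) + 1
    c = r + pad + 0.21  # off-lattice center avoids raster aliasing
    z, y, x = np.ogrid[:n, :n, :n]
    return BinaryMask((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= r * r, vs, "lumen")


class TestMaskVolume:
    def test_voxel_counting_at_10_micron(self):
        data = np.zeros((10, 10, 10), bool)
        data.ravel()[:1000] = True
        assert mask_volume(BinaryMask(data, 0.01, "plaque")) == pytest.approx(0.001)

    def test_empty_mask_is_zero(self):
        assert mask_volume(BinaryMask(np.zeros((4, 4, 4), bool), VS, "plaque")) == 0.0

    def test_matches_counting_oracle(self, rng):
        import oracles

        data = rng.random((12, 12, 12)) > 0.5
        mask = BinaryMask(data, VS, "plaque")
        assert mask_volume(mask) == pytest.approx(oracles.count_voxels(data) * VS**3)


class TestMaskSurface:
    def test_sphere_surface_within_3pct(self):
        mask = sphere_mask(20)
        exact = 4 * np.pi * 20**2 * VS**2
        assert abs(mask_surface(mask) / exact - 1) < 0.03

    def test_cube_surface_within_10pct(self):
        data = np.zeros((30, 30, 30), bool)
        data[5:25, 5:25, 5:25] = True
        exact = 6 * 20**2 * VS**2
        assert abs(mask_surface(BinaryMask(data, VS, "lumen")) / exact - 1) < 0.10

    def test_single_voxel_positive_finite(self):
        data = np.zeros((3, 3, 3), bool)
        data[1, 1, 1] = True
        area = mask_surface(BinaryMask(data, VS, "lesion"))
        assert np.isfinite(area) and area > 0

    def test_sphere_error_decreases_with_radius(self):
        errs = []
        for r in (10, 20, 40):
            exact = 4 * np.pi * r**2 * VS**2
            errs.append(abs(mask_surface(sphere_mask(r)) / exact - 1))
        assert errs[2] < errs[0]

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            mask_surface(BinaryMask(np.zeros((4, 4, 4), bool), VS, "lumen"))


class TestLesionSurface:
    def test_empty_lesion_is_zero(self):
        assert lesion_surface(BinaryMask(np.zeros((4, 4, 4), bool), VS, "lesion")) == 0.0

    def test_half_of_full_surface_by_definition(self, rng):
        data = rng.random((10, 10, 10)) > 0.6
        mask = BinaryMask(data, VS, "lesion")
        assert lesion_surface(mask) == pytest.approx(0.5 * mask_surface(mask))

    def test_one_voxel_disc_approximates_single_face_area(self):
        data = np.zeros((7, 31, 31), bool)
        y, x = np.ogrid[:31, :31]
        data[3] = (y - 15.2) ** 2 + (x - 15.3) ** 2 <= 100
        got = lesion_surface(BinaryMask(data, VS, "lesion"))
        assert abs(got / (np.pi * 100 * VS**2) - 1) < 0.15


class TestWallThickness:
    def test_slab_five_voxels(self):
        data = np.zeros((20, 20, 11), bool)
        data[:, :, 3:8] = True
        mean, values = wall_thickness(BinaryMask(data, VS, "wall"))
        assert mean == pytest.approx(5 * VS, abs=VS)
        assert values.shape[0] == data.sum()

    def test_hollow_cylinder_three_voxels(self):
        yy, xx = np.ogrid[:40, :40]
        rho2 = (yy - 20.2) ** 2 + (xx - 20.3) ** 2
        ring = (rho2 > 12**2) & (rho2 <= 15**2)
        data = np.broadcast_to(ring, (12, 40, 40)).copy()
        mean, _ = wall_thickness(BinaryMask(data, VS, "wall"))
        assert mean == pytest.approx(3 * VS, abs=VS)

    def test_one_voxel_sheet_reads_one_voxel(self):
        data = np.zeros((9, 9, 9), bool)
        data[4] = True
        mean, _ = wall_thickness(BinaryMask(data, VS, "wall"))
        assert mean == pytest.approx(VS)

    def test_empty_wall_raises(self):
        with pytest.raises(ValueError):
            wall_thickness(BinaryMask(np.zeros((4, 4, 4), bool), VS, "wall"))


def _results_from_masks(wall, lumen, plaque, lesion, vs=VS):
    wl = WallLumenResult(
        wall_mask=BinaryMask(wall, vs, "wall"),
        lumen_mask=BinaryMask(lumen, vs, "lumen"),
        aorta_mask=BinaryMask(wall | lumen, vs, "aorta"),
    )
    pr = PlaqueResult(
        plaque_mask=BinaryMask(plaque, vs, "plaque"),
        lesion_mask=BinaryMask(lesion, vs, "lesion"),
    )
    return wl, pr


class TestFractionsAndPerSlice:
    def test_fraction_arithmetic(self):
        shape = (10, 12, 12)
        lumen = np.zeros(shape, bool)
        lumen[:, 2:10, 2:10] = True  # 640
        plaque = np.zeros(shape, bool)
        plaque[:, 2:10, 2:6] = True  # half: 320... use quarter for 10%? keep exact halves
        wall = np.zeros(shape, bool)
        wall[:, 0:2, :] = True
        wl, pr = _results_from_masks(wall, lumen, plaque, np.zeros(shape, bool))
        fr = volume_fractions(wl, pr)
        assert fr["plaque_volume_fraction"] == pytest.approx(50.0)
        assert fr["lesion_surface_fraction"] == 0.0

    def test_empty_plaque_gives_zero_fractions(self, small_pipeline):
        *_, wall_lumen, _ = small_pipeline
        empty = PlaqueResult(
            plaque_mask=BinaryMask(np.zeros(wall_lumen.wall_mask.shape, bool), VS, "plaque"),
            lesion_mask=BinaryMask(np.zeros(wall_lumen.wall_mask.shape, bool), VS, "lesion"),
        )
        fr = volume_fractions(wall_lumen, empty)
        assert fr["plaque_volume_fraction"] == 0.0
        assert fr["lesion_surface_fraction"] == 0.0

    def test_empty_lumen_rejected(self):
        shape = (4, 8, 8)
        wall = np.zeros(shape, bool)
        wall[:, :2, :] = True
        wl, pr = _results_from_masks(wall, np.zeros(shape, bool), np.zeros(shape, bool), np.zeros(shape, bool))
        with pytest.raises(ValueError):
            volume_fractions(wl, pr)

    def test_phantom_fraction_within_one_point(self):
        # a specimen with a ~5% plaque/lumen volume ratio
        from aortamorph import interpolate_roi, phantom_contours, segment_plaques, segment_wall_lumen
        from aortamorph.phantom import PhantomSpec, PlaqueSpec, generate_phantom

        spec = PhantomSpec(plaques=[PlaqueSpec(0.0, 0.52, 0.25, 0.083)])
        volume, truth = generate_phantom(spec)
        roi = interpolate_roi(phantom_contours(spec), volume.shape, volume.voxel_size)
        wall_lumen = segment_wall_lumen(volume, roi)
        plaques = segment_plaques(volume, wall_lumen)
        fr = volume_fractions(wall_lumen, plaques)
        analytic = 100 * truth.analytic_plaque_volume / truth.analytic_lumen_volume
        assert 3.0 < analytic < 8.0
        assert abs(fr["plaque_volume_fraction"] - analytic) < 1.0

    def test_disc_slice_perimeter_and_zero_stenosis(self):
        shape = (3, 50, 50)
        y, x = np.ogrid[:50, :50]
        disc = (y - 25.2) ** 2 + (x - 25.3) ** 2 <= 400
        lumen = np.broadcast_to(disc, shape).copy()
        wl, pr = _results_from_masks(
            np.zeros(shape, bool), lumen, np.zeros(shape, bool), np.zeros(shape, bool)
        )
        df = per_slice_metrics(wl, pr)
        assert (df["stenosis_pct"] == 0).all()
        want = 2 * np.pi * 20 * VS
        assert np.allclose(df["lumen_perimeter"], want, rtol=0.05)

    def test_fully_occluded_slice_is_100pct(self):
        shape = (1, 20, 20)
        lumen = np.zeros(shape, bool)
        lumen[0, 5:15, 5:15] = True
        wl, pr = _results_from_masks(np.zeros(shape, bool), lumen, lumen.copy(), np.zeros(shape, bool))
        df = per_slice_metrics(wl, pr)
        assert df["stenosis_pct"].iloc[0] == pytest.approx(100.0)

    def test_stenosis_integrates_to_plaque_volume_exactly(self, small_pipeline):
        *_, wall_lumen, plaques = small_pipeline
        df = per_slice_metrics(wall_lumen, plaques)
        total = (df["plaque_area"] * VS).sum()
        assert total == pytest.approx(mask_volume(plaques.plaque_mask), rel=1e-12)

    def test_half_annulus_contact_near_50pct(self):
        # plaque lining half the wall circumference -> lesion length ~50%
        shape = (5, 60, 60)
        y, x = np.ogrid[:60, :60]
        rho2 = (y - 30.2) ** 2 + (x - 30.3) ** 2
        disc = rho2 <= 20**2
        ring = (rho2 > 20**2) & (rho2 <= 23**2)
        half_annulus = disc & (rho2 > 16**2) & (y - 30.2 > 0)
        lumen = np.broadcast_to(disc, shape).copy()
        wall = np.broadcast_to(ring, shape).copy()
        plaque = np.broadcast_to(half_annulus, shape).copy()
        import oracles

        lesion = np.stack([oracles.face_adjacent_contact(plaque[i:i+1], wall[i:i+1])[0] for i in range(5)])
        wl, pr = _results_from_masks(wall, lumen, plaque, lesion)
        df = per_slice_metrics(wl, pr)
        assert abs(df["lesion_length_fraction_pct"].mean() - 50.0) < 10.0

    def test_report_assembles_all_fields(self, small_pipeline):
        *_, wall_lumen, plaques = small_pipeline
        rep = build_report(wall_lumen, plaques)
        assert rep.plaque_volume <= rep.lumen_volume
        assert rep.aorta_volume == pytest.approx(rep.wall_volume + rep.lumen_volume, rel=1e-12)
        assert 0 <= rep.plaque_volume_fraction <= 100
        assert 0 <= rep.lesion_surface_fraction <= 100
        assert not rep.per_slice.empty
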