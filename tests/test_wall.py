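"""Wall geometry, cropping, projection and analysis-region behaviour."""

import numpy as np
import pytest

from rsomvasc.io import Image2D, Landmark, LandmarkSet, Volume3D
from rsomvasc.wall import (
    AnalysisRegion,
    WallGeometry,
    analysis_region,
    interpolate_wall_geometry,
    mask_colon_wall,
    project_wall,
    segment_projections,
)


def _lm(idx, apex_x, apex_z, thickness=60.0):
    return Landmark(idx, apex=(apex_x, apex_z), guide=(apex_x, apex_z + thickness))


def _vol(nx=32, ny=50, nz=40, value=0.0):
    return Volume3D(data=np.full((nx, ny, nz), value, dtype=np.float32))


class TestSegmentProjections:
    def test_five_1mm_segments_from_5mm(self):
        vol = _vol(ny=250)  # 250 slices x 20 µm = 5 mm
        assert len(segment_projections(vol, 1000.0)) == 5

    def test_block_means_match_arithmetic(self):
        data = np.zeros((4, 120, 6), dtype=np.float32)
        for k in range(120):
            data[:, k, :] = k
        vol = Volume3D(data=data)
        projs = segment_projections(vol, 1000.0)  # blocks of 50 slices
        assert len(projs) == 2  # trailing 20 slices < half a segment -> dropped
        np.testing.assert_allclose(projs[0].data, np.mean(np.arange(50)))
        np.testing.assert_allclose(projs[1].data, np.mean(np.arange(50, 100)))
        assert projs[0].pixel_size == (20.0, 4.0)

    def test_single_partial_block(self):
        vol = _vol(ny=40)  # 0.8 mm >= half a segment
        assert len(segment_projections(vol, 1000.0)) == 1

    def test_too_thin_volume_rejected(self):
        with pytest.raises(ValueError, match="thinner"):
            segment_projections(_vol(ny=20), 1000.0)


class TestInterpolateWallGeometry:
    def test_linear_interpolation_midway(self):
        lms = LandmarkSet(entries=[_lm(0, 600.0, 100.0), _lm(2, 600.0, 300.0)])
        vol = _vol(ny=150)
        geom = interpolate_wall_geometry(lms, vol, "fixed", standard_radius_um=1000.0)
        # landmark y-positions are 500 and 2500 µm; slice at y=1500 µm is midway
        j = int(1500.0 / 20.0)
        assert geom.apex_z[j] == pytest.approx(200.0, abs=2.0)

    def test_identical_landmarks_give_constant_geometry(self):
        lms = LandmarkSet(entries=[_lm(0, 500.0, 150.0), _lm(3, 500.0, 150.0)])
        geom = interpolate_wall_geometry(lms, _vol(ny=200), "fixed", standard_radius_um=800.0)
        assert geom.is_constant()
        assert geom.apex_z[0] == pytest.approx(150.0)

    def test_collinear_landmarks_reproduce_middle(self):
        lms = LandmarkSet(
            entries=[_lm(0, 100.0, 100.0), _lm(1, 200.0, 200.0), _lm(2, 300.0, 300.0)]
        )
        geom = interpolate_wall_geometry(lms, _vol(ny=150), "fixed", standard_radius_um=1000.0)
        j = int(1500.0 / 20.0)  # y of the middle landmark
        assert geom.apex_x[j] == pytest.approx(200.0, abs=1.0)
        assert geom.apex_z[j] == pytest.approx(200.0, abs=1.0)

    def test_extrapolation_is_nearest_landmark(self):
        lms = LandmarkSet(entries=[_lm(1, 600.0, 100.0), _lm(2, 600.0, 300.0)])
        geom = interpolate_wall_geometry(lms, _vol(ny=250), "fixed", standard_radius_um=1000.0)
        assert geom.apex_z[0] == pytest.approx(100.0)
        assert geom.apex_z[-1] == pytest.approx(300.0)

    def test_fewer_than_two_landmarks_rejected(self):
        lms = LandmarkSet(entries=[_lm(0, 600.0, 100.0)])
        with pytest.raises(ValueError, match="at least 2"):
            interpolate_wall_geometry(lms, _vol(), "fixed")

    def test_apex_below_guide_rejected(self):
        lms = LandmarkSet(
            entries=[
                Landmark(0, apex=(600.0, 200.0), guide=(600.0, 100.0)),
                Landmark(1, apex=(600.0, 200.0), guide=(600.0, 100.0)),
            ]
        )
        with pytest.raises(ValueError, match="degenerate"):
            interpolate_wall_geometry(lms, _vol(), "fixed")

    def test_apex_guide_policy_radius(self):
        # guide annotated at the far guide boundary, 2R below the apex
        lms = LandmarkSet(
            entries=[
                Landmark(0, apex=(600.0, 100.0), guide=(600.0, 2100.0)),
                Landmark(1, apex=(600.0, 100.0), guide=(600.0, 2100.0)),
            ]
        )
        geom = interpolate_wall_geometry(lms, _vol(ny=100), "apex_guide", wall_offset_um=30.0)
        assert geom.radius[0] == pytest.approx(1030.0)


def _constant_geom(ny, cx, cz, R):
    return WallGeometry(
        center_x=np.full(ny, cx), center_z=np.full(ny, cz), radius=np.full(ny, R)
    )


class TestMaskAndProject:
    def test_retained_voxels_satisfy_band_predicate(self, rng):
        nx, ny, nz = 60, 10, 100
        vol = Volume3D(data=rng.random((nx, ny, nz)).astype(np.float32) + 1.0)
        geom = _constant_geom(ny, cx=600.0, cz=500.0, R=300.0)
        masked, bands = mask_colon_wall(vol, geom, band_fraction=0.1)
        xs, ys, zs = np.nonzero(masked.data)
        x_um = (xs + 0.5) * 20.0
        z_um = (zs + 0.5) * 4.0
        assert np.all((x_um - 600.0) ** 2 + (z_um - 500.0) ** 2 <= 300.0**2)
        assert np.all(z_um >= bands[0, 0]) and np.all(z_um <= bands[0, 1])
        assert bands[0, 0] == pytest.approx(200.0)  # apex depth
        assert bands[0, 1] == pytest.approx(200.0 + 0.1 * 600.0)

    def test_full_band_fraction_keeps_circle_interior(self, rng):
        nx, ny, nz = 60, 4, 200
        vol = Volume3D(data=np.ones((nx, ny, nz), dtype=np.float32))
        geom = _constant_geom(ny, cx=600.0, cz=500.0, R=300.0)
        masked, _ = mask_colon_wall(vol, geom, band_fraction=1.0)
        xs, ys, zs = np.nonzero(masked.data)
        x_um = (xs + 0.5) * 20.0
        z_um = (zs + 0.5) * 4.0
        inside = (x_um - 600.0) ** 2 + (z_um - 500.0) ** 2 <= 300.0**2
        assert inside.all()
        # every interior voxel is retained
        n_inside = int(
            np.sum(
                ((np.arange(nx)[:, None] + 0.5) * 20.0 - 600.0) ** 2
                + ((np.arange(nz)[None, :] + 0.5) * 4.0 - 500.0) ** 2
                <= 300.0**2
            )
        )
        assert len(xs) == n_inside * ny

    def test_band_thickness_arithmetic(self):
        # R = 2000 µm -> band 400 µm = 100 depth voxels at 4 µm
        ny = 4
        vol = Volume3D(data=np.ones((10, ny, 700), dtype=np.float32))
        geom = _constant_geom(ny, cx=100.0, cz=2100.0, R=2000.0)
        _, bands = mask_colon_wall(vol, geom, band_fraction=0.1)
        thickness = bands[0, 1] - bands[0, 0]
        assert thickness == pytest.approx(400.0)
        assert thickness / 4.0 == pytest.approx(100.0)

    def test_projection_is_band_mean(self):
        nx, ny, nz = 20, 6, 120
        data = np.zeros((nx, ny, nz), dtype=np.float32)
        geom = _constant_geom(ny, cx=200.0, cz=400.0, R=300.0)
        masked_shape, bands = mask_colon_wall(Volume3D(data=np.ones_like(data)), geom, 0.1)
        k0 = int(np.floor(bands[0, 0] / 4.0))
        k1 = int(np.ceil(bands[0, 1] / 4.0))
        n_band = k1 - k0
        data[10, 3, k0 + 2] = 7.0  # single bright voxel inside the band
        proj = project_wall(Volume3D(data=data), geom, 0.1)
        assert proj.data[10, 3] == pytest.approx(7.0 / n_band)
        assert proj.pixel_size == (20.0, 20.0)

    def test_constant_shell_projects_to_constant(self):
        nx, ny, nz = 40, 6, 150
        vol = Volume3D(data=np.ones((nx, ny, nz), dtype=np.float32) * 3.0)
        geom = _constant_geom(ny, cx=400.0, cz=400.0, R=300.0)
        masked, bands = mask_colon_wall(vol, geom, 0.1)
        proj = project_wall(masked, geom, 0.1)
        # at the apex column the full band is inside the circle -> mean = 3
        apex_col = int(400.0 / 20.0)
        assert proj.data[apex_col, 0] == pytest.approx(3.0, rel=0.05)


class TestAnalysisRegion:
    def _proj(self, nx=120, ny=60):
        return Image2D(data=np.zeros((nx, ny), dtype=np.float32), pixel_size=(20.0, 20.0))

    def test_half_width_is_r_sin_theta(self):
        ny = 60
        geom = _constant_geom(ny, cx=1200.0, cz=2400.0, R=2000.0)
        region = analysis_region(geom, self._proj(), half_angle_deg=18.0, erosion_um=0.0)
        rows = np.nonzero(region.mask.any(axis=1))[0]
        x_um = (rows + 0.5) * 20.0
        half_width = 2000.0 * np.sin(np.deg2rad(18.0))  # ~618 µm
        assert np.abs(x_um - 1200.0).max() <= half_width
        assert np.abs(x_um - 1200.0).max() >= half_width - 25.0

    def test_wide_angle_spans_full_projection(self):
        ny = 60
        geom = _constant_geom(ny, cx=1200.0, cz=2400.0, R=2000.0)
        region = analysis_region(geom, self._proj(), half_angle_deg=89.9, erosion_um=0.0)
        assert region.mask.all()  # strip wider than the 2.4 mm image

    def test_erosion_retreats_10px_per_side(self):
        ny = 60
        geom = _constant_geom(ny, cx=1200.0, cz=2400.0, R=2000.0)
        r0 = analysis_region(geom, self._proj(), 18.0, erosion_um=0.0)
        r1 = analysis_region(geom, self._proj(), 18.0, erosion_um=200.0)
        w0 = r0.mask.any(axis=1).sum()
        w1 = r1.mask.any(axis=1).sum()
        assert w0 - w1 == 20  # 10 px per side
        h0 = r0.mask.any(axis=0).sum()
        h1 = r1.mask.any(axis=0).sum()
        assert h0 - h1 == 20

    def test_monotone_in_angle_antitone_in_erosion(self):
        ny = 60
        geom = _constant_geom(ny, cx=1200.0, cz=2400.0, R=2000.0)
        small = analysis_region(geom, self._proj(), 10.0, 0.0).mask
        large = analysis_region(geom, self._proj(), 30.0, 0.0).mask
        assert np.all(large | ~small)  # small subset of large
        eroded = analysis_region(geom, self._proj(), 30.0, 100.0).mask
        assert np.all(large | ~eroded)

    def test_lateral_translation_equivariance(self):
        ny = 60
        geom = _constant_geom(ny, cx=1000.0, cz=2400.0, R=2000.0)
        shifted = geom.translated(100.0)  # 5 px
        r0 = analysis_region(geom, self._proj(), 18.0, 0.0).mask
        r1 = analysis_region(shifted, self._proj(), 18.0, 0.0).mask
        np.testing.assert_array_equal(np.roll(r0, 5, axis=0), r1)

    def test_area_matches_pixel_count(self):
        ny = 60
        geom = _constant_geom(ny, cx=1200.0, cz=2400.0, R=2000.0)
        region = analysis_region(geom, self._proj(), 18.0, 200.0)
        assert region.area_um2 == pytest.approx(region.mask.sum() * 400.0)

    def test_total_erosion_rejected(self):
        ny = 60
        geom = _constant_geom(ny, cx=1200.0, cz=2400.0, R=200.0)
        with pytest.raises(ValueError, match="consumed"):
            analysis_region(geom, self._proj(), 5.0, erosion_um=1000.0)
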