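"""Colon-wall localization, cropping, projection and the analysis region.

The transrectal absorber guide (TAG) distends the colon into a cylinder of
known, standardized radius.  Per depth-slice along the guide (y) axis the
wall is modelled as a circle (center, radius); operator landmarks mark the
apex (topmost wall point) and the guide per 1-mm segment, and per-slice
coordinates come from linear interpolation.  Everything but the upper
band of the colon tube is discarded before the depth projection, and all
descriptors are later normalized to an eroded ±18° strip around the apex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import Image2D, LandmarkSet, Volume3D

__all__ = [
    "WallGeometry",
    "AnalysisRegion",
    "segment_projections",
    "interpolate_wall_geometry",
    "mask_colon_wall",
    "project_wall",
    "analysis_region",
]


@dataclass
class WallGeometry:
    """Per-slice circle model of the guide-distended colon.

    Arrays are indexed by the y (TAG-axis) slice; units are µm in the
    volume frame (x lateral, z depth, origin at the voxel grid corner).
    """

    center_x: np.ndarray
    center_z: np.ndarray
    radius: np.ndarray

    def __post_init__(self) -> None:
        self.center_x = np.asarray(self.center_x, dtype=np.float64)
        self.center_z = np.asarray(self.center_z, dtype=np.float64)
        self.radius = np.asarray(self.radius, dtype=np.float64)
        if not (self.center_x.shape == self.center_z.shape == self.radius.shape):
            raise ValueError("geometry arrays must share one length")
        if np.any(self.radius <= 0):
            raise ValueError("all radii must be positive")

    @property
    def n_slices(self) -> int:
        return self.center_x.shape[0]

    @property
    def apex_x(self) -> np.ndarray:
        return self.center_x

    @property
    def apex_z(self) -> np.ndarray:
        """Depth of the topmost wall point per slice (center_z - R)."""
        return self.center_z - self.radius

    def is_constant(self) -> bool:
        return (
            np.ptp(self.center_x) == 0 and np.ptp(self.center_z) == 0 and np.ptp(self.radius) == 0
        )

    def translated(self, dx_um: float) -> "WallGeometry":
        return WallGeometry(self.center_x + dx_um, self.center_z.copy(), self.radius.copy())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "slice": np.arange(self.n_slices),
                "center_x_um": self.center_x,
                "center_z_um": self.center_z,
                "radius_um": self.radius,
            }
        )


@dataclass
class AnalysisRegion:
    """Binary region on the wall projection over which descriptors are normalized."""

    mask: np.ndarray
    pixel_size: tuple[float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size[0] * self.pixel_size[1]

    def bbox_origin(self) -> tuple[int, int]:
        rows, cols = np.nonzero(self.mask)
        if rows.size == 0:
            raise ValueError("empty analysis region")
        return int(rows.min()), int(cols.min())


def segment_projections(vol: Volume3D, segment_length_um: float = 1000.0) -> list[Image2D]:
    """Average-intensity x–z projections of consecutive 1-mm blocks along y.

    The last partial block is kept if it spans at least half a segment.
    """
    vy = vol.voxel_size[1]
    block = int(round(segment_length_um / vy))
    if block < 1:
        raise ValueError("segment length below one slice")
    ny = vol.data.shape[1]
    if ny * vy < segment_length_um / 2:
        raise ValueError("volume thinner than half a segment along the TAG axis")
    projections: list[Image2D] = []
    start = 0
    while start < ny:
        stop = min(start + block, ny)
        if stop - start < block and (stop - start) * vy < segment_length_um / 2:
            break
        proj = vol.data[:, start:stop, :].mean(axis=1)
        projections.append(Image2D(data=proj, pixel_size=(vol.voxel_size[0], vol.voxel_size[2])))
        start = stop
    return projections


def interpolate_wall_geometry(
    landmarks: LandmarkSet,
    vol: Volume3D,
    radius_policy: str = "fixed",
    *,
    standard_radius_um: float = 1800.0,
    wall_offset_um: float = 0.0,
    segment_length_um: float = 1000.0,
) -> WallGeometry:
    """Linearly interpolate per-segment landmarks to every y-slice.

    Landmarks sit at the center of their 1-mm segment.  Slices before the
    first / after the last landmark take the nearest landmark's values.
    Radius policies:

    * ``"fixed"`` — standardized circles: every slice gets
      ``standard_radius_um``, circle top anchored at the interpolated apex.
    * ``"apex_guide"`` — radius from the apex-to-guide depth distance,
      ``R = (guide_z - apex_z)/2 + wall_offset_um`` (for annotations that
      mark the far guide boundary).
    """
    landmarks.require_interpolatable()
    apex_z = np.array([e.apex[1] for e in landmarks.entries])
    guide_z = np.array([e.guide[1] for e in landmarks.entries])
    if np.any(apex_z >= guide_z):
        raise ValueError("degenerate geometry: apex must lie above (shallower than) the guide")

    y_lm = np.array([(e.segment_index + 0.5) * segment_length_um for e in landmarks.entries])
    apex_x = np.array([e.apex[0] for e in landmarks.entries])
    ny = vol.data.shape[1]
    y_slices = (np.arange(ny) + 0.5) * vol.voxel_size[1]
    # np.interp clamps outside the landmark range = nearest-landmark extrapolation
    ax = np.interp(y_slices, y_lm, apex_x)
    az = np.interp(y_slices, y_lm, apex_z)
    gz = np.interp(y_slices, y_lm, guide_z)

    if radius_policy == "fixed":
        R = np.full(ny, float(standard_radius_um))
    elif radius_policy == "apex_guide":
        R = (gz - az) / 2.0 + wall_offset_um
        if np.any(R <= 0):
            raise ValueError("apex_guide policy yielded non-positive radius")
    else:
        raise ValueError(f"unknown radius policy {radius_policy!r}")
    return WallGeometry(center_x=ax, center_z=az + R, radius=R)


def _band_bounds(geom: WallGeometry, band_fraction: float) -> np.ndarray:
    """Per-slice retained depth band [apex_z, apex_z + band_fraction*2R], µm."""
    lo = geom.apex_z
    hi = geom.apex_z + band_fraction * 2.0 * geom.radius
    return np.stack([lo, hi], axis=1)


def mask_colon_wall(
    vol: Volume3D, geom: WallGeometry, band_fraction: float = 0.1, *, in_place: bool = False
) -> tuple[Volume3D, np.ndarray]:
    """Zero out everything but the upper band of the colon tube.

    A voxel survives iff it lies inside its slice's circle and its depth is
    within ``[apex_z, apex_z + band_fraction * 2R]``.  Returns the masked
    volume and the per-slice retained band bounds in µm, shape (ny, 2).
    """
    if not 0 < band_fraction <= 1:
        raise ValueError("band_fraction must be in (0, 1]")
    if geom.n_slices != vol.data.shape[1]:
        raise ValueError("geometry must cover every y-slice of the volume")
    nx, ny, nz = vol.data.shape
    vx, vy, vz = vol.voxel_size
    bands = _band_bounds(geom, band_fraction)
    if np.any(bands[:, 1] - bands[:, 0] < vz):
        raise ValueError("empty retained band for at least one slice")
    x_um = (np.arange(nx) + 0.5) * vx
    z_um = (np.arange(nz) + 0.5) * vz
    out = vol.data if in_place else np.zeros_like(vol.data)

    def slice_mask(cx: float, cz: float, R: float, lo: float, hi: float) -> np.ndarray:
        in_circle = (x_um[:, None] - cx) ** 2 + (z_um[None, :] - cz) ** 2 <= R * R
        in_band = (z_um[None, :] >= lo) & (z_um[None, :] <= hi)
        return in_circle & in_band

    if geom.is_constant():
        m = slice_mask(geom.center_x[0], geom.center_z[0], geom.radius[0], bands[0, 0], bands[0, 1])
        if in_place:
            out *= m[:, None, :]
        else:
            out[:] = vol.data * m[:, None, :]
    else:
        for j in range(ny):
            m = slice_mask(
                geom.center_x[j], geom.center_z[j], geom.radius[j], bands[j, 0], bands[j, 1]
            )
            if in_place:
                out[:, j, :] *= m
            else:
                out[:, j, :] = vol.data[:, j, :] * m
    return Volume3D(data=out, voxel_size=vol.voxel_size), bands


def project_wall(
    masked: Volume3D, geom: WallGeometry, band_fraction: float = 0.1
) -> Image2D:
    """Average-intensity depth projection of the extracted wall.

    Each (x, y) pixel is the mean over its slice's retained depth band
    (voxels outside the band are excluded from the mean, so the value is
    independent of the volume's total depth extent).
    """
    nx, ny, nz = masked.data.shape
    vz = masked.voxel_size[2]
    bands = _band_bounds(geom, band_fraction)
    out = np.zeros((nx, ny), dtype=np.float32)

    def band_indices(lo: float, hi: float) -> tuple[int, int]:
        k0 = max(int(np.floor(lo / vz)), 0)
        k1 = min(int(np.ceil(hi / vz)), nz)
        if k1 <= k0:
            raise ValueError("empty projection band")
        return k0, k1

    if geom.is_constant():
        k0, k1 = band_indices(bands[0, 0], bands[0, 1])
        out[:] = masked.data[:, :, k0:k1].mean(axis=2)
    else:
        for j in range(ny):
            k0, k1 = band_indices(bands[j, 0], bands[j, 1])
            out[:, j] = masked.data[:, j, k0:k1].mean(axis=1)
    return Image2D(data=out, pixel_size=(masked.voxel_size[0], masked.voxel_size[1]))


def analysis_region(
    geom: WallGeometry,
    projection: Image2D,
    half_angle_deg: float = 18.0,
    erosion_um: float = 200.0,
) -> AnalysisRegion:
    """±half-angle strip around the apex, morphologically eroded.

    Per slice the lateral extent is ``|x - apex_x| <= R sin(half_angle)``
    (orthographic projection of the cylinder sector); the union over
    slices is then eroded by a disk of radius ``erosion_um``.
    """
    if not 0 < half_angle_deg < 90:
        raise ValueError("half_angle_deg must be in (0, 90)")
    if erosion_um < 0:
        raise ValueError("erosion_um must be >= 0")
    nx, ny = projection.data.shape
    px, py = projection.pixel_size
    if geom.n_slices != ny:
        raise ValueError("geometry must cover every projection column (y-slice)")
    x_um = (np.arange(nx) + 0.5) * px
    half_width = geom.radius * np.sin(np.deg2rad(half_angle_deg))
    strip = np.abs(x_um[:, None] - geom.apex_x[None, :]) <= half_width[None, :]
    if erosion_um > 0:
        r_px = int(round(erosion_um / px))
        if r_px > 0:
            yy, xx = np.mgrid[-r_px : r_px + 1, -r_px : r_px + 1]
            disk = xx * xx + yy * yy <= r_px * r_px
            strip = ndimage.binary_erosion(strip, structure=disk, border_value=0)
    if not strip.any():
        raise ValueError("erosion consumed the entire analysis strip")
    return AnalysisRegion(mask=strip, pixel_size=(px, py))
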