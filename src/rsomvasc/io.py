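"""Volume/image/landmark/config I/O with physical metadata.

Axis convention (frozen for the whole package):

* ``Volume3D.data`` has axes ``(x, y, z)`` where ``x`` is the lateral scan
  axis, ``y`` runs along the transrectal absorber guide (TAG, i.e. along the
  colon), and ``z`` is depth into tissue.  On disk, a multi-page grayscale
  TIFF stores one depth slice per page: page ``k`` is the x-y plane at
  ``z = k`` with rows = x and columns = y.
* 2D wall projections are ``(x, y)`` grids; per-segment orientation
  projections are ``(x, z)`` grids.  Both are carried as :class:`Image2D`
  with an explicit pixel size in micrometres.

All intensities are processed in floating point regardless of the on-disk
bit depth; histogram thresholds later quantize to 256 bins internally.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "Volume3D",
    "Image2D",
    "Landmark",
    "LandmarkSet",
    "PipelineConfig",
    "read_volume",
    "write_volume",
    "read_image",
    "write_image",
    "read_landmarks",
    "write_landmarks",
    "load_config",
    "save_config",
]

DEFAULT_VOXEL_SIZE_UM = (20.0, 20.0, 4.0)


@dataclass
class Volume3D:
    """Reconstructed 3D intensity grid with physical voxel size.

    ``data`` axes are ``(x, y, z)``; ``voxel_size`` is in µm per axis.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive values, got {self.voxel_size}")
        self.voxel_size = vs
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent along (x, y, z) in µm."""
        return tuple(n * v for n, v in zip(self.data.shape, self.voxel_size))  # type: ignore[return-value]


@dataclass
class Image2D:
    """A 2D scalar grid with pixel size in µm (row axis first)."""

    data: np.ndarray
    pixel_size: tuple[float, float] = (20.0, 20.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"image data must be 2D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        ps = tuple(float(v) for v in self.pixel_size)
        if len(ps) != 2 or any(v <= 0 for v in ps):
            raise ValueError(f"pixel_size must be two positive values, got {self.pixel_size}")
        self.pixel_size = ps
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image data contains non-finite values")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size[0] * self.pixel_size[1]


@dataclass(frozen=True)
class Landmark:
    """Operator annotation for one 1-mm segment along the TAG axis.

    ``apex`` is the (x, z) position in µm of the highest (shallowest) point
    of the colon wall; ``guide`` is the (x, z) of the TAG boundary used by
    the radius policy.
    """

    segment_index: int
    apex: tuple[float, float]
    guide: tuple[float, float]


@dataclass
class LandmarkSet:
    """Ordered per-segment apex/guide annotations."""

    entries: list[Landmark]

    def __post_init__(self) -> None:
        idx = [e.segment_index for e in self.entries]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("segment indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.entries)

    def require_interpolatable(self) -> None:
        if len(self.entries) < 2:
            raise ValueError("at least 2 landmark segments are required for interpolation")


# --- pipeline configuration -------------------------------------------------

# documented bounds for validated parameters (inclusive)
_BOUNDS = {
    "wall_band_fraction": (0.0, 1.0),
    "half_angle_deg": (0.0, 90.0),
    "erosion_um": (0.0, 2000.0),
    "frangi_scale_um": (20.0, 300.0),
    "rf_sigma_px": (0.1, 10.0),
    "rf_prob_threshold": (0, 255),
}


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline with their defaults.

    Units are µm unless stated otherwise.  Defaults follow the published
    workflow where a value is printed (segment length 1 mm, wall band 1/10,
    Frangi scales 40–100 µm, RF probability cut 128, edge erosion 200 µm,
    half-angle 18°, box sizes up to 64); the remaining values are this
    package's documented choices.
    """

    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    gaussian_sigma_um: tuple[float, float, float] = (20.0, 20.0, 8.0)
    ball_radius_um: float = 1000.0
    paraboloid_radius_um: float = 1000.0
    segment_length_um: float = 1000.0
    wall_band_fraction: float = 0.1
    radius_policy: str = "fixed"  # "fixed" | "apex_guide"
    standard_radius_um: float = 1800.0
    wall_offset_um: float = 0.0
    frangi_scales_um: tuple[float, ...] = (40.0, 60.0, 80.0, 100.0)
    frangi_beta: float = 0.5
    frangi_c: float | None = None  # None -> half of max Hessian norm per scale
    rf_sigmas_px: tuple[float, ...] = (0.3, 0.7, 1.0, 1.6, 3.5, 5.0, 10.0)
    rf_prob_threshold: int = 128
    rf_n_trees: int = 100
    median_kernel_px: int = 3
    erosion_um: float = 200.0
    half_angle_deg: float = 18.0
    box_sizes: tuple[int, ...] = (2, 4, 8, 16, 32, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _chk(name: str, value: float, lo: float, hi: float, open_lo=False, open_hi=False):
            bad = value < lo or value > hi or (open_lo and value == lo) or (open_hi and value == hi)
            if bad:
                raise ValueError(f"config parameter {name}={value} outside documented bounds [{lo}, {hi}]")

        if any(v <= 0 for v in self.voxel_size_um) or len(self.voxel_size_um) != 3:
            raise ValueError("voxel_size_um must be three positive values")
        if any(s <= 0 for s in self.gaussian_sigma_um):
            raise ValueError("gaussian_sigma_um must be positive")
        if self.ball_radius_um <= 0 or self.paraboloid_radius_um <= 0:
            raise ValueError("background radii must be positive")
        if self.segment_length_um <= 0:
            raise ValueError("segment_length_um must be positive")
        lo, hi = _BOUNDS["wall_band_fraction"]
        _chk("wall_band_fraction", self.wall_band_fraction, lo, hi, open_lo=True)
        lo, hi = _BOUNDS["half_angle_deg"]
        _chk("half_angle_deg", self.half_angle_deg, lo, hi, open_lo=True, open_hi=True)
        lo, hi = _BOUNDS["erosion_um"]
        _chk("erosion_um", self.erosion_um, lo, hi)
        if self.radius_policy not in ("fixed", "apex_guide"):
            raise ValueError(f"unknown radius_policy {self.radius_policy!r}")
        if self.standard_radius_um <= 0:
            raise ValueError("standard_radius_um must be positive")
        lo, hi = _BOUNDS["frangi_scale_um"]
        for s in self.frangi_scales_um:
            _chk("frangi_scales_um", s, lo, hi)
        if list(self.frangi_scales_um) != sorted(self.frangi_scales_um):
            raise ValueError("frangi_scales_um must be sorted ascending")
        if self.frangi_beta <= 0:
            raise ValueError("frangi_beta must be positive")
        if self.frangi_c is not None and self.frangi_c <= 0:
            raise ValueError("frangi_c must be positive or null")
        lo, hi = _BOUNDS["rf_sigma_px"]
        for s in self.rf_sigmas_px:
            _chk("rf_sigmas_px", s, lo, hi)
        lo, hi = _BOUNDS["rf_prob_threshold"]
        _chk("rf_prob_threshold", self.rf_prob_threshold, lo, hi)
        if self.rf_n_trees < 1:
            raise ValueError("rf_n_trees must be >= 1")
        if self.median_kernel_px < 1 or self.median_kernel_px % 2 == 0:
            raise ValueError("median_kernel_px must be odd and >= 1")
        if len(self.box_sizes) < 3 or any(b < 1 for b in self.box_sizes):
            raise ValueError("box_sizes needs >= 3 positive sizes")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
        return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML/JSON config; unspecified keys take the documented defaults."""
    path = Path(path)
    text = path.read_text()
    try:
        d = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config file {path}: {exc}") from exc
    if d is None:
        d = {}
    if not isinstance(d, dict):
        raise ValueError(f"malformed config file {path}: expected a mapping")
    return PipelineConfig.from_dict(d)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


# --- volumes ----------------------------------------------------------------


def read_volume(path: str | Path, voxel_size: Sequence[float] = DEFAULT_VOXEL_SIZE_UM) -> Volume3D:
    """Read a multi-page grayscale TIFF stack as a :class:`Volume3D`.

    Page ``k`` of the stack is the depth slice ``z = k`` (rows = x,
    columns = y), so a stack of 750 pages of 600×600 yields data of shape
    ``(600, 600, 750)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"unreadable volume: no such file {path}")
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:
        raise ValueError(f"unreadable volume {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"unreadable volume {path}: expected grayscale pages, got array of shape {arr.shape}"
        )
    # pages-first on disk -> (x, y, z) in memory
    data = np.moveaxis(arr, 0, -1).astype(np.float32)
    return Volume3D(data=data, voxel_size=tuple(voxel_size))


def write_volume(vol: Volume3D, path: str | Path) -> None:
    """Write a volume as a 32-bit multi-page TIFF (one page per depth slice)."""
    arr = np.moveaxis(np.asarray(vol.data, dtype=np.float32), -1, 0)
    tifffile.imwrite(str(path), arr)
    _write_sidecar(path, {"voxel_size_um": list(vol.voxel_size), "axes": "zxy-pages"})


# --- 2D images and masks ----------------------------------------------------


def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".meta.json")


def _write_sidecar(path: str | Path, meta: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def write_image(img, path: str | Path) -> None:
    """Write a 2D image or mask losslessly.

    Binary masks are stored as 8-bit 0/255; float images as 32-bit float
    TIFF (PNG only supports masks).  Pixel size goes into a JSON sidecar.
    """
    from .segment import VesselMask  # local import to avoid a cycle

    path = Path(path)
    if isinstance(img, VesselMask):
        data = (img.data.astype(np.uint8) * 255)
        pixel_size = img.pixel_size
        meta = {"pixel_size_um": list(pixel_size), "kind": "mask", "method": img.method}
    else:
        if not np.all(np.isfinite(img.data)):
            raise ValueError("refusing to write image with non-finite values")
        arr = np.asarray(img.data)
        if arr.dtype == bool or set(np.unique(arr)).issubset({0.0, 1.0}):
            data = (arr > 0).astype(np.uint8) * 255
            meta = {"pixel_size_um": list(img.pixel_size), "kind": "mask"}
        else:
            data = arr.astype(np.float32)
            meta = {"pixel_size_um": list(img.pixel_size), "kind": "float32"}
        pixel_size = img.pixel_size
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        if data.dtype != np.uint8:
            raise ValueError("PNG output supports binary masks only; use TIFF for float images")
        iio.imwrite(str(path), data)
    else:
        tifffile.imwrite(str(path), data)
    _write_sidecar(path, meta)


def read_image(path: str | Path, pixel_size: Sequence[float] | None = None) -> Image2D:
    """Read a single-page TIFF/PNG; pixel size from the sidecar if present."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image {path}")
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(str(path)))
    else:
        arr = np.asarray(tifffile.imread(str(path)))
    if arr.ndim != 2:
        raise ValueError(f"expected single-page grayscale image, got shape {arr.shape}")
    if pixel_size is None:
        sc = _sidecar_path(path)
        if sc.exists():
            pixel_size = json.loads(sc.read_text())["pixel_size_um"]
        else:
            pixel_size = (20.0, 20.0)
    return Image2D(data=arr.astype(np.float32), pixel_size=tuple(pixel_size))


# --- landmarks --------------------------------------------------------------

_LM_COLUMNS = ["segment_index", "apex_x_um", "apex_z_um", "guide_x_um", "guide_z_um"]


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read the landmark CSV (one row per 1-mm segment)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such landmark file {path}")
    df = pd.read_csv(path)
    missing = [c for c in _LM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"landmark file {path} missing columns {missing}")
    entries = [
        Landmark(
            segment_index=int(r.segment_index),
            apex=(float(r.apex_x_um), float(r.apex_z_um)),
            guide=(float(r.guide_x_um), float(r.guide_z_um)),
        )
        for r in df.itertuples()
    ]
    return LandmarkSet(entries=entries)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    rows = [
        {
            "segment_index": e.segment_index,
            "apex_x_um": e.apex[0],
            "apex_z_um": e.apex[1],
            "guide_x_um": e.guide[0],
            "guide_z_um": e.guide[1],
        }
        for e in landmarks.entries
    ]
    pd.DataFrame(rows, columns=_LM_COLUMNS).to_csv(path, index=False)
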