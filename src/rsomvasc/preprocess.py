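"""Denoising and background removal.

Three operations mirror the imaging workflow:

* :func:`gaussian3d` — separable 3D Gaussian smoothing of the volume.
* :func:`rolling_ball_subtract` — slice-wise (x–y planes along depth)
  rolling-ball background subtraction.  The background is the grayscale
  morphological opening of each slice with a non-flat ball structuring
  element, i.e. the surface traced by a ball rolled under the intensity
  landscape.
* :func:`sliding_paraboloid_subtract` — background as the fixpoint of 1-D
  parabolic openings (lower envelopes) along rows, columns and both
  diagonals.  A parabola can slide under a narrow bright ridge where a ball
  of the same nominal radius cannot, so elongated structures such as
  vessels are preserved better than under the rolling ball.

The ball/paraboloid "radius" follows the 8-bit convention of interactive
image tools: one intensity unit corresponds to one pixel of ball height
once the image span is mapped to 0–255.  ``intensity_scale`` overrides that
mapping (``1.0`` treats intensities as heights directly).  All filters use
reflective boundaries so edges are not darkened.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from .io import Image2D, Volume3D

__all__ = [
    "gaussian3d",
    "rolling_ball_subtract",
    "sliding_paraboloid_subtract",
]


def gaussian3d(vol: Volume3D, sigma_um: tuple[float, float, float], *, in_place: bool = False) -> Volume3D:
    """Separable 3D Gaussian smoothing; ``sigma_um`` is physical, per axis."""
    sigma_um = tuple(float(s) for s in sigma_um)
    if any(s <= 0 for s in sigma_um):
        raise ValueError(f"gaussian sigma must be positive, got {sigma_um}")
    sigma_vox = [s / v for s, v in zip(sigma_um, vol.voxel_size)]
    data = vol.data.astype(np.float32, copy=False)
    out = data if in_place else np.empty_like(data)
    ndimage.gaussian_filter(data, sigma=sigma_vox, mode="reflect", output=out)
    return Volume3D(data=out, voxel_size=vol.voxel_size)


# --- rolling ball -----------------------------------------------------------


def _ball_structure(radius_px: float, intensity_scale: float):
    """Non-flat half-ball structuring element (footprint, heights)."""
    r = int(math.floor(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = xx * xx + yy * yy
    footprint = d2 <= radius_px * radius_px
    heights = np.zeros_like(d2, dtype=np.float64)
    heights[footprint] = np.sqrt(radius_px * radius_px - d2[footprint]) * intensity_scale
    return footprint, heights


def _auto_shrink(radius_px: float) -> int:
    if radius_px <= 10:
        return 1
    if radius_px <= 20:
        return 2
    if radius_px <= 40:
        return 4
    return 8


def _rolling_ball_background(img: np.ndarray, radius_px: float, intensity_scale: float | None, downscale: int | None) -> np.ndarray:
    span = float(img.max() - img.min()) if img.size else 0.0
    scale = intensity_scale if intensity_scale is not None else (span / 255.0 if span > 0 else 1.0)
    shrink = _auto_shrink(radius_px) if downscale is None else int(downscale)
    if shrink < 1:
        raise ValueError("downscale must be >= 1")
    work = img.astype(np.float64, copy=False)
    if shrink > 1:
        ny, nx = work.shape
        py = (-ny) % shrink
        px = (-nx) % shrink
        padded = np.pad(work, ((0, py), (0, px)), mode="edge")
        # block minimum keeps the shrunken surface below the original
        blocks = padded.reshape(padded.shape[0] // shrink, shrink, padded.shape[1] // shrink, shrink)
        small = blocks.min(axis=(1, 3))
        r_small = max(radius_px / shrink, 1.0)
        fp, st = _ball_structure(r_small, scale)
        bg_small = ndimage.grey_dilation(
            ndimage.grey_erosion(small, footprint=fp, structure=st, mode="reflect"),
            footprint=fp,
            structure=st,
            mode="reflect",
        )
        zoomed = ndimage.zoom(bg_small, shrink, order=1, mode="nearest")
        bg = zoomed[:ny, :nx]
        bg = np.minimum(bg, work)
    else:
        fp, st = _ball_structure(radius_px, scale)
        bg = ndimage.grey_dilation(
            ndimage.grey_erosion(work, footprint=fp, structure=st, mode="reflect"),
            footprint=fp,
            structure=st,
            mode="reflect",
        )
    return bg


def _rolling_ball_background_stack(
    data: np.ndarray, radius_px: float, intensity_scale: float | None, shrink: int
) -> np.ndarray:
    """Shrunken-ball background for a whole (x, y, z) stack in one pass.

    Intensity scale is taken from the global stack span (the slices share
    one acquisition), the block-minimum shrink and the opening run as a
    single 3D morphology call with a slice-wise (k, k, 1) ball footprint.
    """
    span = float(data.max() - data.min())
    scale = intensity_scale if intensity_scale is not None else (span / 255.0 if span > 0 else 1.0)
    nx, ny, nz = data.shape
    px = (-nx) % shrink
    py = (-ny) % shrink
    work = np.pad(data, ((0, px), (0, py), (0, 0)), mode="edge")
    blocks = work.reshape(work.shape[0] // shrink, shrink, work.shape[1] // shrink, shrink, nz)
    small = blocks.min(axis=(1, 3)).astype(np.float64)
    r_small = max(radius_px / shrink, 1.0)
    fp, st = _ball_structure(r_small, scale)
    fp3 = fp[:, :, None]
    st3 = st[:, :, None]
    bg_small = ndimage.grey_dilation(
        ndimage.grey_erosion(small, footprint=fp3, structure=st3, mode="reflect"),
        footprint=fp3,
        structure=st3,
        mode="reflect",
    )
    zoomed = ndimage.zoom(bg_small.astype(np.float32), (shrink, shrink, 1), order=1, mode="nearest")
    return zoomed[:nx, :ny, :]


def rolling_ball_subtract(
    vol: Volume3D,
    radius_um: float,
    *,
    intensity_scale: float | None = None,
    downscale: int | None = None,
    in_place: bool = False,
) -> Volume3D:
    """Subtract the rolling-ball background from every x–y slice.

    ``radius_um`` must exceed the largest foreground structure so that the
    ball cannot enter it.  ``downscale`` enables the standard shrink
    speed-up (block-minimum reduction, small-ball opening, bilinear
    upsampling); ``None`` picks a factor from the radius, ``1`` forces the
    exact per-slice opening.  ``in_place`` reuses the input buffer to halve
    peak memory on large volumes.
    """
    radius_px = radius_um / vol.voxel_size[0]
    if radius_px < 1:
        raise ValueError(f"ball radius {radius_um} µm is smaller than one pixel")
    shrink = _auto_shrink(radius_px) if downscale is None else int(downscale)
    if shrink < 1:
        raise ValueError("downscale must be >= 1")
    if shrink > 1:
        bg = _rolling_ball_background_stack(vol.data, radius_px, intensity_scale, shrink)
        np.minimum(bg, vol.data, out=bg)
        if in_place:
            out = vol.data
            np.subtract(out, bg, out=out)
        else:
            out = vol.data - bg
        np.clip(out, 0.0, None, out=out)
    else:
        out = vol.data if in_place else np.empty_like(vol.data, dtype=np.float32)
        for k in range(vol.data.shape[2]):
            sl = vol.data[:, :, k]
            bg = _rolling_ball_background(sl, radius_px, intensity_scale, 1)
            out[:, :, k] = np.clip(sl - bg, 0.0, None)
    return Volume3D(data=out, voxel_size=vol.voxel_size)


def rolling_ball_subtract_image(
    img: Image2D,
    radius_um: float,
    *,
    intensity_scale: float | None = None,
    downscale: int | None = None,
) -> Image2D:
    """2D convenience wrapper used for method comparisons on projections."""
    radius_px = radius_um / img.pixel_size[0]
    if radius_px < 1:
        raise ValueError(f"ball radius {radius_um} µm is smaller than one pixel")
    bg = _rolling_ball_background(img.data, radius_px, intensity_scale, downscale)
    return Image2D(data=np.clip(img.data - bg, 0.0, None), pixel_size=img.pixel_size)


# --- sliding paraboloid -----------------------------------------------------


def _parabolic_lower_envelope_py(f: np.ndarray, a: float) -> np.ndarray:
    """min_j f[j] + a (i - j)^2 for every i (lower-envelope algorithm)."""
    n = f.shape[0]
    out = np.empty(n, dtype=np.float64)
    v = np.empty(n, dtype=np.int64)  # parabola roots in the envelope
    z = np.empty(n + 1, dtype=np.float64)  # intersection abscissae
    k = 0
    v[0] = 0
    z[0] = -np.inf
    z[1] = np.inf
    for q in range(1, n):
        fq = f[q] + a * q * q
        while True:
            p = v[k]
            s = (fq - (f[p] + a * p * p)) / (2.0 * a * (q - p))
            if s <= z[k]:
                k -= 1
            else:
                break
        k += 1
        v[k] = q
        z[k] = s
        z[k + 1] = np.inf
    k = 0
    for i in range(n):
        while z[k + 1] < i:
            k += 1
        p = v[k]
        out[i] = f[p] + a * (i - p) * (i - p)
    return out


try:  # compiled fast path; the pure-Python envelope is the reference semantics
    from numba import njit as _njit

    _parabolic_lower_envelope = _njit(cache=True)(_parabolic_lower_envelope_py)
except ImportError:  # pragma: no cover
    _parabolic_lower_envelope = _parabolic_lower_envelope_py


def _parabolic_open_line(f: np.ndarray, a: float) -> np.ndarray:
    """1-D parabolic opening: erosion followed by dilation.

    The line's secant (endpoint-to-endpoint linear trend) is removed
    first and the detrended residual is edge-extended with constant
    values before the envelopes, so a tilted background passes through
    unchanged and the parabola cannot sink over the image edge.
    """
    f = np.asarray(f, dtype=np.float64)
    n = f.shape[0]
    if n < 2:
        return f.copy()
    secant = f[0] + (f[-1] - f[0]) / (n - 1) * np.arange(n)
    res = f - secant
    span = float(res.max() - res.min())
    # parabola half-width needed to clear the residual range
    pad = int(math.ceil(math.sqrt(max(span, 1e-12) / a))) + 1
    g = np.concatenate([np.full(pad, res[0]), res, np.full(pad, res[-1])])
    e = _parabolic_lower_envelope(g, a)
    o = -_parabolic_lower_envelope(-e, a)
    # clamp to [line min, f]: the background stays within the data range
    return np.minimum(np.maximum(o[pad : pad + n] + secant, f.min()), f)


def _open_rows(img: np.ndarray, a: float) -> None:
    for i in range(img.shape[0]):
        img[i, :] = _parabolic_open_line(img[i, :], a)


def _open_cols(img: np.ndarray, a: float) -> None:
    for j in range(img.shape[1]):
        img[:, j] = _parabolic_open_line(img[:, j], a)


def _open_diagonals(img: np.ndarray, a: float, anti: bool) -> None:
    # step length along a diagonal is sqrt(2) px -> halve the curvature coeff
    ad = a / 2.0
    work = img[:, ::-1] if anti else img
    ny, nx = work.shape
    for off in range(-ny + 1, nx):
        d = np.diagonal(work, offset=off)
        if d.shape[0] < 2:
            continue
        opened = _parabolic_open_line(d, ad)
        idx = np.arange(d.shape[0])
        if off >= 0:
            work[idx, idx + off] = opened
        else:
            work[idx - off, idx] = opened


def sliding_paraboloid_background(
    img: np.ndarray,
    radius_px: float,
    *,
    intensity_scale: float | None = None,
    max_iter: int = 6,
    tol: float = 1e-9,
) -> np.ndarray:
    """Paraboloid background: fixpoint of 1-D parabolic openings.

    The parabola apex curvature matches a ball of ``radius_px``:
    height = d² / (2 r) in scaled-intensity units.  Sweeps over rows,
    columns and the two diagonal families are repeated until the maximum
    change falls below ``tol`` times the image span.
    """
    if radius_px <= 1:
        raise ValueError("paraboloid radius must exceed one pixel")
    f = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite input")
    span = float(f.max() - f.min())
    scale = intensity_scale if intensity_scale is not None else (span / 255.0 if span > 0 else 1.0)
    a = scale / (2.0 * radius_px)
    bg = f.copy()
    for _ in range(max_iter):
        prev = bg.copy()
        _open_rows(bg, a)
        _open_cols(bg, a)
        _open_diagonals(bg, a, anti=False)
        _open_diagonals(bg, a, anti=True)
        if float(np.max(np.abs(bg - prev))) <= tol * max(span, 1.0):
            break
    return bg


def sliding_paraboloid_subtract(
    img: Image2D,
    radius_um: float,
    *,
    intensity_scale: float | None = None,
    max_iter: int = 6,
    tol: float = 1e-9,
) -> Image2D:
    """Subtract the sliding-paraboloid background from a 2D projection."""
    radius_px = radius_um / img.pixel_size[0]
    bg = sliding_paraboloid_background(
        img.data, radius_px, intensity_scale=intensity_scale, max_iter=max_iter, tol=tol
    )
    out = np.clip(img.data.astype(np.float64) - bg, 0.0, None)
    return Image2D(data=out.astype(np.float32), pixel_size=img.pixel_size)
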