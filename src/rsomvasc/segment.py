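"""Vessel segmentation of the projected colon wall.

Three alternative methods produce a binary vessel mask:

* **AT** — moment-preserving automatic threshold (Tsai): the threshold is
  chosen so the binary image preserves the first three gray-level moments
  of the input histogram.
* **VF** — multiscale Frangi vesselness (bright tubular structures from
  the Hessian eigenvalues at vessel-radius-matched Gaussian scales)
  followed by the minimum-error threshold (Kittler–Illingworth).
* **RF** — random-forest pixel classification on a filter-bank feature
  stack (Gaussian smoothing, Laplacian of Gaussian, gradient magnitude,
  difference of Gaussians, structure-tensor and Hessian eigenvalues at
  several scales), binarized at probability 128/255.

Both rule-based thresholds operate on a 256-bin quantization of the image
range, which makes them invariant to affine intensity rescaling, and both
break ties toward the smallest optimal threshold.  The foreground rule is
``value >= threshold`` everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage
from skimage.feature import hessian_matrix, hessian_matrix_eigvals, structure_tensor, structure_tensor_eigenvalues

from .io import Image2D

__all__ = [
    "VesselMask",
    "FrangiParams",
    "FeatureStack",
    "frangi_vesselness",
    "threshold_minimum_error",
    "threshold_moments",
    "segment_at",
    "segment_vf",
    "rf_features",
    "RandomForestVesselModel",
    "rf_segment",
]


@dataclass
class VesselMask:
    """Binary vessel segmentation tagged with the method that produced it."""

    data: np.ndarray
    method: str
    pixel_size: tuple[float, float]
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.method not in ("AT", "RF", "VF", "truth"):
            raise ValueError(f"unknown segmentation method tag {self.method!r}")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size[0] * self.pixel_size[1]


@dataclass
class FrangiParams:
    """Frangi filter parameters; scales are target vessel diameters in µm."""

    scales_um: tuple[float, ...] = (40.0, 60.0, 80.0, 100.0)
    beta: float = 0.5
    c: float | None = None  # None -> half of max Hessian norm, per scale
    bright_on_dark: bool = True

    def __post_init__(self) -> None:
        if not self.scales_um or any(s <= 0 for s in self.scales_um):
            raise ValueError("scales must be positive")
        if list(self.scales_um) != sorted(self.scales_um):
            raise ValueError("scales must be sorted ascending")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


def _hessian_eigvals_sorted(img: np.ndarray, sigma_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Gamma-normalized Hessian eigenvalues with |λ1| <= |λ2|."""
    H = hessian_matrix(img, sigma=sigma_px, mode="reflect", use_gaussian_derivatives=True)
    ev = hessian_matrix_eigvals(H) * sigma_px**2  # ev[0] >= ev[1] numerically
    swap = np.abs(ev[0]) > np.abs(ev[1])
    lam1 = np.where(swap, ev[1], ev[0])
    lam2 = np.where(swap, ev[0], ev[1])
    return lam1, lam2


def frangi_vesselness(img: Image2D, params: FrangiParams | None = None) -> Image2D:
    """Multiscale Frangi vesselness, pixelwise max over scales, in [0, 1].

    Scales (µm) are vessel diameters; the Gaussian sigma per scale is
    ``scale / 2`` converted to pixels (the ridge response of a bar of
    width w peaks near sigma ≈ w/2).  Per scale, with |λ1| <= |λ2|:
    the response is 0 where λ2 > 0 (bright vessels), otherwise
    ``exp(-R_b²/2β²) (1 - exp(-S²/2c²))`` with R_b = λ1/λ2 and
    S = sqrt(λ1² + λ2²) from the sigma²-normalized Hessian.
    """
    params = params or FrangiParams()
    px = img.pixel_size[0]
    out = np.zeros_like(img.data, dtype=np.float64)
    for scale in params.scales_um:
        sigma_px = (scale / 2.0) / px
        if 2 * int(3 * sigma_px) + 1 > min(img.data.shape):
            raise ValueError(f"image smaller than the kernel at scale {scale} µm")
        lam1, lam2 = _hessian_eigvals_sorted(img.data.astype(np.float64), sigma_px)
        if not params.bright_on_dark:
            lam1, lam2 = -lam1, -lam2
        S2 = lam1 * lam1 + lam2 * lam2
        c = params.c if params.c is not None else 0.5 * np.sqrt(S2.max())
        if c <= 0:
            continue  # flat image at this scale
        with np.errstate(divide="ignore", invalid="ignore"):
            Rb2 = np.where(lam2 != 0, (lam1 / np.where(lam2 != 0, lam2, 1.0)) ** 2, 0.0)
        v = np.exp(-Rb2 / (2.0 * params.beta**2)) * (1.0 - np.exp(-S2 / (2.0 * c**2)))
        v[lam2 > 0] = 0.0
        out = np.maximum(out, v)
    vmax = out.max()
    if vmax > 0:
        out /= vmax
    return Image2D(data=out.astype(np.float32), pixel_size=img.pixel_size)


# --- histogram thresholds ---------------------------------------------------


def _quantize_256(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """256-bin quantization over the image range -> (hist, levels, min, width)."""
    vmin = float(img.min())
    vmax = float(img.max())
    if vmax <= vmin:
        raise ValueError("degenerate histogram: constant image")
    width = (vmax - vmin) / 256.0
    idx = np.clip(((img - vmin) / width).astype(np.int64), 0, 255)
    hist = np.bincount(idx.ravel(), minlength=256).astype(np.float64)
    levels = np.arange(256, dtype=np.float64)
    return hist, levels, vmin, width


def minimum_error_criterion(hist: np.ndarray) -> np.ndarray:
    """Kittler–Illingworth J(t) for thresholds t = 0..256 over a 256-bin histogram.

    A threshold t splits bins into [0, t) and [t, 256).  Splits with an
    empty class get J = +inf.  Class variances are floored at 1/12 bin²
    (the variance of a uniform distribution within one quantization bin),
    so a class collapsed onto a single level is modelled as one bin wide
    rather than degenerate.
    """
    hist = np.asarray(hist, dtype=np.float64)
    n = hist.sum()
    p = hist / n
    levels = np.arange(hist.size, dtype=np.float64)
    J = np.full(hist.size + 1, np.inf)
    c0 = np.cumsum(p)
    c1 = np.cumsum(p * levels)
    c2 = np.cumsum(p * levels * levels)
    var_floor = 1.0 / 12.0
    for t in range(1, hist.size):
        P1 = c0[t - 1]
        P2 = 1.0 - P1
        if P1 <= 0 or P2 <= 0:
            continue
        mu1 = c1[t - 1] / P1
        mu2 = (c1[-1] - c1[t - 1]) / P2
        var1 = max(c2[t - 1] / P1 - mu1 * mu1, var_floor)
        var2 = max((c2[-1] - c2[t - 1]) / P2 - mu2 * mu2, var_floor)
        J[t] = (
            1.0
            + 2.0 * (P1 * np.log(np.sqrt(var1)) + P2 * np.log(np.sqrt(var2)))
            - 2.0 * (P1 * np.log(P1) + P2 * np.log(P2))
        )
    return J


def threshold_minimum_error(img: Image2D) -> tuple[float, VesselMask]:
    """Minimum-error (Kittler–Illingworth) threshold on a 256-bin quantization."""
    hist, _, vmin, width = _quantize_256(img.data)
    J = minimum_error_criterion(hist)
    if not np.any(np.isfinite(J) | np.isneginf(J)):
        raise ValueError("degenerate histogram: no valid split")
    t = int(np.argmin(J))  # argmin returns the smallest index among ties
    thr = vmin + t * width
    mask = VesselMask(data=img.data >= thr, method="VF", pixel_size=img.pixel_size, threshold_used=thr)
    return thr, mask


def moments_background_fraction(hist: np.ndarray) -> float:
    """Tsai moment preservation: target background fraction p0.

    Solves for the two representative levels (z0, z1) of a binary image
    whose first three moments match the input histogram, and returns the
    fraction p0 assigned to the lower level.
    """
    hist = np.asarray(hist, dtype=np.float64)
    p = hist / hist.sum()
    z = np.arange(hist.size, dtype=np.float64)
    m1 = float((p * z).sum())
    m2 = float((p * z * z).sum())
    m3 = float((p * z * z * z).sum())
    cd = m2 - m1 * m1
    if cd <= 0:
        raise ValueError("degenerate histogram: zero variance")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        raise ValueError("degenerate histogram: complex moment roots")
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        raise ValueError("degenerate histogram: coincident moment roots")
    return float((z1 - m1) / (z1 - z0))


def moments_residual(hist: np.ndarray, p0: float) -> np.ndarray:
    """|cumulative fraction below t - p0| for every candidate t = 0..256."""
    p = np.asarray(hist, dtype=np.float64) / np.sum(hist)
    cum = np.concatenate([[0.0], np.cumsum(p)])  # cum[t] = fraction of bins < t
    return np.abs(cum - p0)


def threshold_moments(img: Image2D) -> tuple[float, VesselMask]:
    """Moment-preserving (Tsai) automatic threshold on a 256-bin quantization.

    The returned threshold minimizes the moment-preservation residual
    |P(t) - p0| over all candidates (smallest t on ties).
    """
    hist, _, vmin, width = _quantize_256(img.data)
    p0 = moments_background_fraction(hist)
    res = moments_residual(hist, p0)
    t = int(np.argmin(res))
    thr = vmin + t * width
    mask = VesselMask(data=img.data >= thr, method="AT", pixel_size=img.pixel_size, threshold_used=thr)
    return thr, mask


def segment_at(img: Image2D) -> VesselMask:
    """AT method: moment-preserving threshold of the projection."""
    _, mask = threshold_moments(img)
    return mask


def segment_vf(img: Image2D, params: FrangiParams | None = None) -> VesselMask:
    """VF method: Frangi vesselness followed by the minimum-error threshold."""
    vessels = frangi_vesselness(img, params)
    thr, mask = threshold_minimum_error(vessels)
    return VesselMask(data=mask.data, method="VF", pixel_size=img.pixel_size, threshold_used=thr)


# --- random-forest pixel classification -------------------------------------

_FEATURE_KINDS = (
    "gaussian",
    "log",
    "gradient_magnitude",
    "dog",
    "structure_tensor_eig",  # 2 planes
    "hessian_eig",  # 2 planes
)


@dataclass
class FeatureStack:
    """Per-pixel filter-bank features, shape (H, W, F), with plane names."""

    data: np.ndarray
    names: list[str]
    sigmas_px: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[2] != len(self.names):
            raise ValueError("feature plane count must match names")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite feature values")


def rf_features(img: Image2D, sigmas_px: tuple[float, ...] = (0.3, 0.7, 1.0, 1.6, 3.5, 5.0, 10.0)) -> FeatureStack:
    """Filter-bank feature stack (8 planes per sigma, documented order).

    Per sigma: Gaussian smoothing, Laplacian of Gaussian, Gaussian
    gradient magnitude, difference of Gaussians (σ vs 1.6σ), the two
    structure-tensor eigenvalues and the two Hessian eigenvalues, each
    eigenvalue pair sorted by descending magnitude.
    """
    if not sigmas_px:
        raise ValueError("empty sigma list")
    if max(sigmas_px) > 10.0:
        raise ValueError("sigma above the 10 px limit")
    f = img.data.astype(np.float64)
    planes: list[np.ndarray] = []
    names: list[str] = []
    for s in sigmas_px:
        g = ndimage.gaussian_filter(f, s, mode="reflect")
        planes.append(g)
        names.append(f"gaussian_s{s}")
        planes.append(ndimage.gaussian_laplace(f, s, mode="reflect"))
        names.append(f"log_s{s}")
        planes.append(ndimage.gaussian_gradient_magnitude(f, s, mode="reflect"))
        names.append(f"gradient_magnitude_s{s}")
        planes.append(g - ndimage.gaussian_filter(f, 1.6 * s, mode="reflect"))
        names.append(f"dog_s{s}")
        A = structure_tensor(f, sigma=s, mode="reflect")
        st_ev = structure_tensor_eigenvalues(A)
        order = np.argsort(-np.abs(st_ev), axis=0)
        st_sorted = np.take_along_axis(st_ev, order, axis=0)
        planes.extend([st_sorted[0], st_sorted[1]])
        names.extend([f"structure_tensor_eig{i}_s{s}" for i in (0, 1)])
        H = hessian_matrix(f, sigma=max(s, 0.3), mode="reflect", use_gaussian_derivatives=True)
        h_ev = hessian_matrix_eigvals(H)
        order = np.argsort(-np.abs(h_ev), axis=0)
        h_sorted = np.take_along_axis(h_ev, order, axis=0)
        planes.extend([h_sorted[0], h_sorted[1]])
        names.extend([f"hessian_eig{i}_s{s}" for i in (0, 1)])
    data = np.stack(planes, axis=-1).astype(np.float32)
    return FeatureStack(data=data, names=names, sigmas_px=tuple(sigmas_px))


LABEL_UNLABELED, LABEL_BACKGROUND, LABEL_VESSEL = 0, 1, 2

_MODEL_FORMAT_VERSION = 1


class RandomForestVesselModel:
    """Seeded random-forest pixel classifier over :func:`rf_features`."""

    def __init__(
        self,
        sigmas_px: tuple[float, ...] = (0.3, 0.7, 1.0, 1.6, 3.5, 5.0, 10.0),
        n_trees: int = 100,
        seed: int = 0,
    ) -> None:
        from sklearn.ensemble import RandomForestClassifier

        self.sigmas_px = tuple(sigmas_px)
        self.feature_names: list[str] | None = None
        self.classifier = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
        )

    def fit(self, pairs: list[tuple[Image2D, np.ndarray]]) -> "RandomForestVesselModel":
        """Train on (image, label-image) pairs; labels are 0 unlabeled,
        1 background, 2 vessel.  Unlabeled pixels are ignored."""
        X_parts, y_parts = [], []
        for img, labels in pairs:
            labels = np.asarray(labels)
            if labels.shape != img.data.shape:
                raise ValueError("label image shape mismatch")
            stack = rf_features(img, self.sigmas_px)
            if self.feature_names is None:
                self.feature_names = stack.names
            sel = labels != LABEL_UNLABELED
            X_parts.append(stack.data[sel])
            y_parts.append(labels[sel])
        X = np.concatenate(X_parts)
        y = np.concatenate(y_parts)
        if X.shape[0] == 0:
            raise ValueError("no labeled pixels provided")
        self.classifier.fit(X, y)
        return self

    def probability_map(self, img: Image2D) -> np.ndarray:
        """8-bit vessel probability map (0–255)."""
        stack = rf_features(img, self.sigmas_px)
        if self.feature_names is not None and stack.names != self.feature_names:
            raise ValueError("feature layout mismatch between training and inference")
        classes = list(self.classifier.classes_)
        if LABEL_VESSEL not in classes:
            raise ValueError("classifier was not trained with vessel labels")
        proba = self.classifier.predict_proba(stack.data.reshape(-1, stack.data.shape[2]))
        p_vessel = proba[:, classes.index(LABEL_VESSEL)].reshape(img.data.shape)
        return np.round(p_vessel * 255.0).astype(np.uint8)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": _MODEL_FORMAT_VERSION,
                "sigmas_px": self.sigmas_px,
                "feature_names": self.feature_names,
                "classifier": self.classifier,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "RandomForestVesselModel":
        blob = joblib.load(path)
        if blob.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model file version")
        model = cls(sigmas_px=tuple(blob["sigmas_px"]))
        model.feature_names = blob["feature_names"]
        model.classifier = blob["classifier"]
        return model


def rf_segment(img: Image2D, model: RandomForestVesselModel, prob_threshold: int = 128) -> VesselMask:
    """RF method: binarize the 8-bit probability map at ``prob_threshold``.

    A pixel exactly at the threshold is foreground (>= convention).
    """
    if not 0 <= prob_threshold <= 255:
        raise ValueError("prob_threshold must be in 0..255")
    pmap = model.probability_map(img)
    return VesselMask(
        data=pmap >= prob_threshold,
        method="RF",
        pixel_size=img.pixel_size,
        threshold_used=float(prob_threshold),
    )
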