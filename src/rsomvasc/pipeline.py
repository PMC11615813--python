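"""End-to-end orchestration: volume -> descriptors, plus method comparison.

``run_pipeline`` executes preprocess -> wall extraction -> segmentation ->
network quantification and optionally writes every intermediate artifact
together with a run manifest (inputs, config hash, seed, versions,
per-stage timings) sufficient to reproduce the run.  Rule-based methods
(AT, VF) are fully deterministic; RF is deterministic given a model file.

Cohort statistics are out of scope by design: the output is a tidy
per-sample descriptor table any statistics environment can consume.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import Image2D, LandmarkSet, PipelineConfig, Volume3D, write_image
from .network import (
    DescriptorSet,
    analyze_skeleton,
    compute_descriptors,
    local_diameters,
    median_denoise,
    skeletonize,
)
from .preprocess import gaussian3d, rolling_ball_subtract, sliding_paraboloid_subtract
from .segment import (
    FrangiParams,
    RandomForestVesselModel,
    VesselMask,
    rf_segment,
    segment_at,
    segment_vf,
)
from .wall import analysis_region, interpolate_wall_geometry, mask_colon_wall, project_wall

__all__ = ["PipelineStageError", "run_pipeline", "quantify_mask", "compare_methods", "segment_projection"]

logger = logging.getLogger("rsomvasc")

METHODS = ("at", "rf", "vf")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and partial outputs so far."""

    def __init__(self, stage: str, cause: Exception, partial: dict):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.partial = partial


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def segment_projection(
    img: Image2D,
    method: str,
    config: PipelineConfig,
    rf_model: RandomForestVesselModel | None = None,
) -> VesselMask:
    """Apply one of the three segmentation methods to a projected wall image."""
    method = method.lower()
    if method == "at":
        return segment_at(img)
    if method == "vf":
        params = FrangiParams(
            scales_um=config.frangi_scales_um, beta=config.frangi_beta, c=config.frangi_c
        )
        return segment_vf(img, params)
    if method == "rf":
        if rf_model is None:
            raise ValueError("RF segmentation requires a trained model")
        return rf_segment(img, rf_model, config.rf_prob_threshold)
    raise ValueError(f"unknown segmentation method {method!r} (expected one of {METHODS})")


def quantify_mask(
    mask: VesselMask, region, config: PipelineConfig
) -> tuple[DescriptorSet, dict]:
    """Median-filter, clip to the region, skeletonize and compute descriptors."""
    mask = median_denoise(mask, config.median_kernel_px)
    clipped = VesselMask(
        data=mask.data & region.mask,
        method=mask.method,
        pixel_size=mask.pixel_size,
        threshold_used=mask.threshold_used,
    )
    skel = skeletonize(clipped)
    graph = analyze_skeleton(skel, pixel_size=clipped.pixel_size)
    diam = local_diameters(clipped, skel)
    desc = compute_descriptors(clipped, graph, diam, region, box_sizes=config.box_sizes)
    return desc, {"mask": clipped, "skeleton": skel, "graph": graph, "diameters": diam}


def run_pipeline(
    volume: Volume3D,
    landmarks: LandmarkSet,
    config: PipelineConfig,
    method: str = "vf",
    rf_model: RandomForestVesselModel | None = None,
    outdir: str | Path | None = None,
    input_paths: dict | None = None,
) -> tuple[DescriptorSet, dict]:
    """Run the full pipeline on one volume; returns (descriptors, artifacts).

    Artifacts include the wall projection, the segmentation mask, the
    skeleton graph and the analysis region.  With ``outdir`` set, all of
    them plus a descriptor CSV and the run manifest are written to disk.
    """
    artifacts: dict = {}
    timings: dict[str, float] = {}

    class _Stage:
        """Timing + error annotation; big intermediates stay local."""

        def __init__(self, name: str):
            self.name = name

        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineStageError(self.name, exc, artifacts) from exc
            timings[self.name] = time.perf_counter() - self.t0
            logger.info("stage %-12s %.2f s", self.name, timings[self.name])
            return False

    with _Stage("preprocess"):
        # the smoothed copy is reused in place by the later stages
        vol_pp = gaussian3d(volume, config.gaussian_sigma_um)
        vol_pp = rolling_ball_subtract(vol_pp, config.ball_radius_um, in_place=True)

    with _Stage("wall_extract"):
        if landmarks is None:
            raise ValueError("missing landmark annotations")
        geom = interpolate_wall_geometry(
            landmarks,
            vol_pp,
            radius_policy=config.radius_policy,
            standard_radius_um=config.standard_radius_um,
            wall_offset_um=config.wall_offset_um,
            segment_length_um=config.segment_length_um,
        )
        masked, _ = mask_colon_wall(vol_pp, geom, config.wall_band_fraction, in_place=True)
        proj = project_wall(masked, geom, config.wall_band_fraction)
        del vol_pp, masked  # drop the working volume before segmentation
        proj = sliding_paraboloid_subtract(proj, config.paraboloid_radius_um)
        region = analysis_region(geom, proj, config.half_angle_deg, config.erosion_um)
    artifacts.update({"geometry": geom, "projection": proj, "region": region})

    with _Stage("segmentation"):
        mask = segment_projection(proj, method, config, rf_model)
    artifacts["raw_mask"] = mask

    with _Stage("network"):
        desc, net = quantify_mask(mask, region, config)
    artifacts.update(net)
    artifacts["descriptors"] = desc

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_image(proj, outdir / "projection.tif")
        write_image(net["mask"], outdir / f"mask_{method.lower()}.tif")
        write_image(
            Image2D(net["skeleton"].astype(np.float32), pixel_size=mask.pixel_size),
            outdir / "skeleton.tif",
        )
        row = {"method": method.upper(), **desc.to_dict(), "config_hash": config_hash(config)}
        pd.DataFrame([row]).to_csv(outdir / "descriptors.csv", index=False)
        manifest = {
            "inputs": input_paths or {},
            "config": config.to_dict(),
            "config_hash": config_hash(config),
            "seed": config.seed,
            "method": method.upper(),
            "software_version": __version__,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "outputs": sorted(p.name for p in outdir.iterdir()),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return desc, artifacts


def compare_methods(
    samples: list[tuple[str, Volume3D, LandmarkSet]],
    config: PipelineConfig,
    rf_model: RandomForestVesselModel | None = None,
) -> pd.DataFrame:
    """Run AT, RF and VF on every sample; long-format descriptor table.

    Without an RF model the table covers AT and VF only (with a warning).
    """
    if not samples:
        raise ValueError("empty sample list")
    methods = list(METHODS)
    if rf_model is None:
        logger.warning("no RF model available; comparing AT and VF only")
        methods = [m for m in methods if m != "rf"]
    rows = []
    for name, volume, landmarks in samples:
        for method in methods:
            desc, _ = run_pipeline(volume, landmarks, config, method=method, rf_model=rf_model)
            for key, value in desc.to_dict().items():
                if key == "analysis_area_um2":
                    continue
                rows.append(
                    {"sample": name, "method": method.upper(), "descriptor": key, "value": value}
                )
    return pd.DataFrame(rows, columns=["sample", "method", "descriptor", "value"])
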