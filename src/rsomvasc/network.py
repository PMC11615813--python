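"""Skeleton-based quantification of the segmented vessel network.

The binary vessel mask is median-filtered, skeletonized to a one-pixel
centerline, and organized into a graph of endpoints, junctions and
branches.  A *branch* is a connection between two junctions, two
endpoints, or a junction and an endpoint; adjacent junction pixels are
merged into a single junction node so thick crossings do not inflate the
branch count.  Branch lengths are Euclidean path lengths (orthogonal step
= pixel size, diagonal step = sqrt(2) x pixel size).

Seven descriptors summarize the network over the analysis region:
normalized network length (µm⁻¹), vessel coverage (%), average vessel
diameter (µm), normalized blood volume (µm³ µm⁻²), largest connected
component length (mm), normalized branch count (cm⁻²) and the box-counting
fractal dimension of the skeleton.  By construction
``avg_vessel_diameter x normalized_network_length == vessel_coverage/100``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .segment import VesselMask
from .wall import AnalysisRegion

__all__ = [
    "Branch",
    "SkeletonGraph",
    "DescriptorSet",
    "median_denoise",
    "skeletonize",
    "analyze_skeleton",
    "local_diameters",
    "fractal_dimension",
    "compute_descriptors",
]

_EIGHT = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def median_denoise(mask: VesselMask, kernel_px: int = 3) -> VesselMask:
    """Binary median filter; removes isolated foreground pixels.

    Note that a 3x3 median also shaves single-pixel convex corners (a
    corner pixel of a solid rectangle has only 4 of 9 foreground
    neighbors).
    """
    if kernel_px % 2 == 0 or kernel_px < 1:
        raise ValueError("median kernel must be odd")
    data = ndimage.median_filter(mask.data.astype(np.uint8), size=kernel_px, mode="reflect")
    return VesselMask(
        data=data > 0, method=mask.method, pixel_size=mask.pixel_size, threshold_used=mask.threshold_used
    )


def skeletonize(mask: VesselMask | np.ndarray) -> np.ndarray:
    """One-pixel-wide, 8-connected, topology-preserving thinning."""
    data = mask.data if isinstance(mask, VesselMask) else np.asarray(mask)
    return _sk_skeletonize(data.astype(bool))


@dataclass
class Branch:
    node_a: int
    node_b: int
    pixels: np.ndarray  # (k, 2) row/col path including node pixels
    length_um: float
    component: int = -1


@dataclass
class SkeletonGraph:
    """Centerline pixels organized into nodes, branches and components."""

    skeleton: np.ndarray
    pixel_size: tuple[float, float]
    branches: list[Branch]
    n_endpoints: int
    n_junctions: int
    component_lengths_um: np.ndarray
    pixel_coords: np.ndarray  # (N, 2) skeleton pixels carrying step length
    pixel_step_um: np.ndarray  # (N,) per-pixel Euclidean step length

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def total_length_um(self) -> float:
        return float(sum(b.length_um for b in self.branches))

    @property
    def largest_component_length_um(self) -> float:
        if self.component_lengths_um.size == 0:
            return 0.0
        return float(self.component_lengths_um.max())


def _step_um(p, q, px: float, py: float) -> float:
    return math.hypot((p[0] - q[0]) * px, (p[1] - q[1]) * py)


def analyze_skeleton(skel: np.ndarray, pixel_size: tuple[float, float] = (20.0, 20.0)) -> SkeletonGraph:
    """Classify skeleton pixels and trace branches.

    Endpoints have one 8-neighbor, junction pixels three or more; adjacent
    junction pixels are merged into one junction node.  Directly adjacent
    nodes contribute one branch per node pair.  Slab-only cycles count as
    one closed branch.  Isolated single pixels count as one zero-length
    branch so every connected component carries at least one branch.
    """
    skel = np.asarray(skel).astype(bool)
    px, py = float(pixel_size[0]), float(pixel_size[1])
    H, W = skel.shape
    deg = ndimage.convolve(skel.astype(np.uint8), np.ones((3, 3), np.uint8), mode="constant") - skel
    deg = np.where(skel, deg, 0)

    comp_labels, n_comp = ndimage.label(skel, structure=np.ones((3, 3), np.uint8))

    # node ids: junction clusters first, then endpoints / isolated pixels
    junction_pixels = skel & (deg >= 3)
    jlab, n_junctions = ndimage.label(junction_pixels, structure=np.ones((3, 3), np.uint8))
    node_id = np.full((H, W), -1, dtype=np.int64)
    node_id[junction_pixels] = jlab[junction_pixels] - 1
    next_id = n_junctions
    ep_coords = np.argwhere(skel & (deg == 1))
    for r, c in ep_coords:
        node_id[r, c] = next_id
        next_id += 1
    iso_coords = np.argwhere(skel & (deg == 0))
    for r, c in iso_coords:
        node_id[r, c] = next_id
        next_id += 1
    n_endpoints = len(ep_coords)

    def neighbors(r: int, c: int):
        for dr, dc in _EIGHT:
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and skel[rr, cc]:
                yield rr, cc

    visited = np.zeros((H, W), dtype=bool)  # slab pixels consumed by a walk
    branches: list[Branch] = []

    def trace_from(start: tuple[int, int], first: tuple[int, int]) -> None:
        path = [start, first]
        length = _step_um(start, first, px, py)
        visited[first] = True
        prev, cur = start, first
        while node_id[cur] < 0:
            nxt = None
            for q in neighbors(*cur):
                if q != prev:
                    nxt = q
                    break
            if nxt is None:  # dead end without an endpoint label (cannot occur on clean skeletons)
                break
            length += _step_um(cur, nxt, px, py)
            path.append(nxt)
            prev, cur = cur, nxt
            if node_id[cur] < 0:
                if visited[cur]:
                    break
                visited[cur] = True
        end_node = node_id[cur] if node_id[cur] >= 0 else -1
        branches.append(
            Branch(
                node_a=int(node_id[start]),
                node_b=int(end_node),
                pixels=np.asarray(path, dtype=np.int64),
                length_um=length,
                component=int(comp_labels[start] - 1),
            )
        )

    node_coords = np.argwhere(node_id >= 0)
    # branches with interior slab pixels
    for r, c in node_coords:
        for q in neighbors(r, c):
            if node_id[q] < 0 and not visited[q]:
                trace_from((r, c), q)
    # directly adjacent distinct nodes: one branch per node pair
    seen_pairs: set[tuple[int, int]] = set()
    for r, c in node_coords:
        a = node_id[r, c]
        for q in neighbors(r, c):
            b = node_id[q]
            if b >= 0 and b != a:
                key = (min(a, b), max(a, b))
                if key not in seen_pairs:
                    seen_pairs.add(key)
                    branches.append(
                        Branch(
                            node_a=int(key[0]),
                            node_b=int(key[1]),
                            pixels=np.asarray([(r, c), q], dtype=np.int64),
                            length_um=_step_um((r, c), q, px, py),
                            component=int(comp_labels[r, c] - 1),
                        )
                    )
    # node-free cycles
    slab_left = np.argwhere(skel & (deg == 2) & ~visited)
    for r, c in slab_left:
        if visited[r, c]:
            continue
        start = (r, c)
        visited[start] = True
        path = [start]
        length = 0.0
        prev: tuple[int, int] | None = None
        cur = start
        while True:
            nxt = None
            for q in neighbors(*cur):
                if q != prev and (not visited[q] or (q == start and len(path) > 2)):
                    nxt = q
                    break
            if nxt is None:
                break
            length += _step_um(cur, nxt, px, py)
            path.append(nxt)
            prev, cur = cur, nxt
            if cur == start:
                break
            visited[cur] = True
        branches.append(
            Branch(
                node_a=-1,
                node_b=-1,
                pixels=np.asarray(path, dtype=np.int64),
                length_um=length,
                component=int(comp_labels[start] - 1),
            )
        )
    # isolated single pixels: zero-length branch
    for r, c in iso_coords:
        branches.append(
            Branch(
                node_a=int(node_id[r, c]),
                node_b=int(node_id[r, c]),
                pixels=np.asarray([(r, c)], dtype=np.int64),
                length_um=0.0,
                component=int(comp_labels[r, c] - 1),
            )
        )

    comp_len = np.zeros(n_comp, dtype=np.float64)
    for b in branches:
        comp_len[b.component] += b.length_um

    # per-pixel Euclidean step length: half of each incident step
    step_map: dict[tuple[int, int], float] = {}
    for b in branches:
        pts = b.pixels
        for i in range(len(pts) - 1):
            s = _step_um(pts[i], pts[i + 1], px, py)
            for p in (tuple(pts[i]), tuple(pts[i + 1])):
                step_map[p] = step_map.get(p, 0.0) + s / 2.0
    if step_map:
        coords = np.asarray(list(step_map.keys()), dtype=np.int64)
        steps = np.asarray(list(step_map.values()), dtype=np.float64)
    else:
        coords = np.zeros((0, 2), dtype=np.int64)
        steps = np.zeros(0, dtype=np.float64)

    return SkeletonGraph(
        skeleton=skel,
        pixel_size=(px, py),
        branches=branches,
        n_endpoints=n_endpoints,
        n_junctions=int(n_junctions),
        component_lengths_um=comp_len,
        pixel_coords=coords,
        pixel_step_um=steps,
    )


def local_diameters(mask: VesselMask, skel: np.ndarray) -> np.ndarray:
    """Local vessel diameter (µm) at every skeleton pixel.

    Diameter = 2 x Euclidean distance transform of the mask, i.e. twice
    the distance to the nearest background pixel.  A one-pixel-wide line
    therefore reports a floor of two pixel widths.  Returns an image that
    is zero off the skeleton.
    """
    skel = np.asarray(skel).astype(bool)
    if np.any(skel & ~mask.data):
        raise ValueError("skeleton pixel outside mask")
    edt = ndimage.distance_transform_edt(mask.data, sampling=mask.pixel_size)
    out = np.zeros_like(edt)
    out[skel] = 2.0 * edt[skel]
    return out


def fractal_dimension(
    skel: np.ndarray,
    box_sizes: tuple[int, ...] = (2, 4, 8, 16, 32, 64),
    origin: tuple[int, int] | None = None,
) -> float:
    """Box-counting fractal dimension of the skeleton.

    For each box size the grid is anchored at ``origin`` (default: the
    skeleton's bounding-box corner) and occupied boxes are counted; the
    dimension is the negative slope of the least-squares fit of
    ln(count) against ln(size).
    """
    if len(box_sizes) < 3:
        raise ValueError("need at least 3 box sizes")
    coords = np.argwhere(np.asarray(skel).astype(bool))
    if coords.shape[0] == 0:
        raise ValueError("empty skeleton")
    if origin is None:
        origin = (int(coords[:, 0].min()), int(coords[:, 1].min()))
    rel = coords - np.asarray(origin, dtype=np.int64)
    counts = []
    for s in box_sizes:
        boxes = rel // s
        counts.append(len(np.unique(boxes[:, 0] * (2**31) + boxes[:, 1])))
    slope = np.polyfit(np.log(np.asarray(box_sizes, float)), np.log(np.asarray(counts, float)), 1)[0]
    return float(-slope)


@dataclass
class DescriptorSet:
    """The seven network descriptors plus the analysis area they refer to."""

    normalized_network_length: float  # µm⁻¹
    vessel_coverage: float  # %
    avg_vessel_diameter: float  # µm (NaN for an empty network)
    normalized_blood_volume: float  # µm³ µm⁻²
    largest_component_length: float  # mm
    normalized_branches: float  # cm⁻²
    fractal_dimension: float  # unitless (NaN for an empty skeleton)
    analysis_area_um2: float

    def to_dict(self) -> dict[str, float]:
        return {
            "normalized_network_length_per_um": self.normalized_network_length,
            "vessel_coverage_pct": self.vessel_coverage,
            "avg_vessel_diameter_um": self.avg_vessel_diameter,
            "normalized_blood_volume_um3_per_um2": self.normalized_blood_volume,
            "largest_component_length_mm": self.largest_component_length,
            "normalized_branches_per_cm2": self.normalized_branches,
            "fractal_dimension": self.fractal_dimension,
            "analysis_area_um2": self.analysis_area_um2,
        }


def compute_descriptors(
    mask: VesselMask,
    graph: SkeletonGraph,
    diameters: np.ndarray,
    region: AnalysisRegion,
    box_sizes: tuple[int, ...] = (2, 4, 8, 16, 32, 64),
) -> DescriptorSet:
    """Compute the seven descriptors over the analysis region.

    The caller must have clipped the mask to the region before
    skeletonizing (as :func:`rsomvasc.pipeline.run_pipeline` does), so the
    graph measures only in-region network.  Coverage is defensively
    computed on ``mask & region``.
    """
    if mask.data.shape != region.mask.shape or graph.skeleton.shape != region.mask.shape:
        raise ValueError("mask, skeleton and region must share one shape")
    area = region.area_um2
    if area <= 0:
        raise ValueError("empty analysis region")
    pixel_area = mask.pixel_area_um2
    mask_area_um2 = float((mask.data & region.mask).sum()) * pixel_area
    total_len = graph.total_length_um

    coverage = 100.0 * mask_area_um2 / area
    nnl = total_len / area
    avg_diam = mask_area_um2 / total_len if total_len > 0 else float("nan")

    if graph.pixel_coords.shape[0] > 0:
        d = diameters[graph.pixel_coords[:, 0], graph.pixel_coords[:, 1]]
        volume = float(np.sum(np.pi * (d / 2.0) ** 2 * graph.pixel_step_um))
    else:
        volume = 0.0

    try:
        fd = fractal_dimension(graph.skeleton, box_sizes, origin=region.bbox_origin())
    except ValueError:
        fd = float("nan")

    return DescriptorSet(
        normalized_network_length=nnl,
        vessel_coverage=coverage,
        avg_vessel_diameter=avg_diam,
        normalized_blood_volume=volume / area,
        largest_component_length=graph.largest_component_length_um / 1000.0,
        normalized_branches=graph.n_branches / area * 1e8,
        fractal_dimension=fd,
        analysis_area_um2=area,
    )
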