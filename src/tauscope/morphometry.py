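"""Nucleus morphometry and astrocyte branching.

Covers DAPI nucleus segmentation, live/condensed classification, the
condensed-nuclei accumulation score (dead neurons stored per living
astrocyte, binned 0 / 1-2 / 3-4 / 5+), cell counting and area, and the
skeletonization branching macro (8-bit convert, threshold, find edge,
Gaussian blur, mask, refine, skeletonize, branch points = skeleton pixels
touching >= 3 other skeleton pixels, merged per junction).

The condensed-nucleus criterion — small AND bright — is a necessary
operational choice (the classification is done by eye in practice); its
defaults are tied to the synthetic generator's rendering factors and must be
recalibrated for real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from . import defaults
from .primitives import (
    BinaryMask,
    apply_threshold,
    convert_to_8bit,
    count_branch_points,
    gaussian_blur,
    label_particles,
    refine_mask,
    skeletonize_mask,
    sobel_edges,
    subtract_background,
)

ACCUMULATION_BINS = ("0", "1-2", "3-4", "5+")


@dataclass
class NucleusRecord:
    label: int
    centroid: tuple[float, float]
    area_px: int
    mean_intensity: float
    state: str | None = None           # "live" | "condensed"
    host_cell_id: int | None = None


@dataclass
class AccumulationSummary:
    n_condensed_total: int
    n_live_astrocytes: int
    condensed_per_live: float
    bin_fractions: dict[str, float]
    n_unassigned_condensed: int = 0
    flags: list[str] = field(default_factory=list)


@dataclass
class BranchingResult:
    n_cells: int
    mean_cell_area_um2: float
    branch_points_per_cell: float
    total_branch_points: int
    per_cell_branch_counts: list[int]
    flags: list[str] = field(default_factory=list)


def segment_nuclei(dapi_plane: np.ndarray,
                   *,
                   threshold: float = defaults.NUCLEUS_THRESHOLD,
                   ball_radius_px: int = defaults.BALL_RADIUS_PX,
                   closing_cycles: int = 1,
                   min_area_px: int = defaults.NUCLEUS_MIN_AREA_PX,
                   max_area_px: int = defaults.NUCLEUS_MAX_AREA_PX,
                   split_touching: bool = False,
                   split_min_distance_px: int = 5,
                   ) -> list[NucleusRecord]:
    """Segment DAPI nuclei: background subtract, threshold, close, label.

    ``split_touching`` applies a distance-transform watershed to separate
    fused nuclei. Mean intensity is measured on the background-subtracted
    plane.
    """
    sub = subtract_background(np.asarray(dapi_plane, float), ball_radius_px)
    mask = refine_mask(apply_threshold(sub, threshold), closing_cycles)
    if split_touching:
        dist = ndimage.distance_transform_edt(mask.data)
        peaks = peak_local_max(dist, min_distance=split_min_distance_px,
                               labels=mask.data)
        markers = np.zeros(mask.data.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-dist, markers, mask=mask.data)
        n = labels.max()
        areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    else:
        labeled, areas = label_particles(mask, connectivity=8,
                                         min_area_px=1, max_area_px=None)
        labels, n = labeled.labels, labeled.count
    records: list[NucleusRecord] = []
    out_label = 0
    for k in range(1, n + 1):
        area = int(areas[k - 1])
        if area < min_area_px or area > max_area_px:
            continue
        sel = labels == k
        rows, cols = np.nonzero(sel)
        out_label += 1
        records.append(NucleusRecord(
            label=out_label,
            centroid=(float(rows.mean()), float(cols.mean())),
            area_px=area,
            mean_intensity=float(sub[sel].mean()),
        ))
    return records


def classify_nucleus_state(records: list[NucleusRecord],
                           area_max_condensed_px: int = defaults.CONDENSED_MAX_AREA_PX,
                           intensity_min_condensed: float = defaults.CONDENSED_MIN_INTENSITY,
                           ) -> list[NucleusRecord]:
    """Condensed iff area <= area threshold AND mean intensity >= intensity
    threshold (both inclusive); otherwise live."""
    for rec in records:
        condensed = (rec.area_px <= area_max_condensed_px
                     and rec.mean_intensity >= intensity_min_condensed)
        rec.state = "condensed" if condensed else "live"
    return records


def astro_territories(marker_mask: np.ndarray,
                      live_centroids: list[tuple[float, float]]) -> np.ndarray:
    """Partition a cell mask into astrocyte territories by nearest live
    nucleus (confluent cultures merge into one marker component, so
    territories cannot come from component labeling)."""
    marker_mask = np.asarray(marker_mask, bool)
    out = np.zeros(marker_mask.shape, dtype=np.int32)
    if not live_centroids:
        return out
    tree = cKDTree(np.asarray(live_centroids, float))
    rows, cols = np.nonzero(marker_mask)
    _, nearest = tree.query(np.column_stack([rows, cols]))
    out[rows, cols] = nearest + 1
    return out


def score_accumulation(nuclei: list[NucleusRecord],
                       astro_labels: np.ndarray) -> AccumulationSummary:
    """Condensed-nuclei accumulation per living astrocyte.

    ``astro_labels`` is an integer raster of astrocyte territories (0 =
    outside). An astrocyte counts as live when it contains at least one
    live-nucleus centroid. Each condensed nucleus is assigned to the
    astrocyte whose territory contains its centroid; condensed nuclei outside
    every territory enter the total but no bin. Bin fractions
    {0, 1-2, 3-4, 5+} are computed over live astrocytes.
    """
    astro_labels = np.asarray(astro_labels)
    live_ids: set[int] = set()
    for rec in nuclei:
        if rec.state == "live":
            r, c = int(round(rec.centroid[0])), int(round(rec.centroid[1]))
            lab = int(astro_labels[r, c]) if _inside(astro_labels.shape, r, c) else 0
            if lab > 0:
                live_ids.add(lab)
    counts = {lab: 0 for lab in live_ids}
    n_condensed = 0
    n_unassigned = 0
    for rec in nuclei:
        if rec.state != "condensed":
            continue
        n_condensed += 1
        r, c = int(round(rec.centroid[0])), int(round(rec.centroid[1]))
        lab = int(astro_labels[r, c]) if _inside(astro_labels.shape, r, c) else 0
        if lab in counts:
            counts[lab] += 1
            rec.host_cell_id = lab
        else:
            n_unassigned += 1

    flags: list[str] = []
    n_live = len(live_ids)
    if n_live == 0:
        flags.append("zero live astrocytes: ratio undefined")
        ratio = math.nan
        fractions = {b: math.nan for b in ACCUMULATION_BINS}
    else:
        ratio = n_condensed / n_live
        tallies = {b: 0 for b in ACCUMULATION_BINS}
        for v in counts.values():
            tallies[_bin_name(v)] += 1
        fractions = {b: tallies[b] / n_live for b in ACCUMULATION_BINS}
    return AccumulationSummary(
        n_condensed_total=n_condensed,
        n_live_astrocytes=n_live,
        condensed_per_live=ratio,
        bin_fractions=fractions,
        n_unassigned_condensed=n_unassigned,
        flags=flags,
    )


def _bin_name(count: int) -> str:
    if count == 0:
        return "0"
    if count <= 2:
        return "1-2"
    if count <= 4:
        return "3-4"
    return "5+"


def _inside(shape: tuple[int, int], r: int, c: int) -> bool:
    return 0 <= r < shape[0] and 0 <= c < shape[1]


def measure_cell_area(mask: BinaryMask | np.ndarray, pixel_size_um: float) -> float:
    """Foreground pixel count times the pixel area, in um^2."""
    arr = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    return float(arr.sum()) * pixel_size_um ** 2


def branching_mask(gfap_plane: np.ndarray,
                   *,
                   threshold_8bit: float = 128.0,
                   blur_sigma_px: float = defaults.GAUSSIAN_SIGMA_PX,
                   mask_threshold_frac: float = 0.10,
                   closing_cycles: int = defaults.CLOSING_CYCLES,
                   edge_before_threshold: bool = False,
                   ) -> BinaryMask:
    """The branching chain up to the refined binary mask.

    Default order follows the macro literally: 8-bit convert, fixed
    threshold, Sobel edges of the (0/255) thresholded image, Gaussian blur,
    convert to mask at ``mask_threshold_frac`` of the blurred maximum, then
    dilation/erosion refinement. ``edge_before_threshold`` swaps the first
    two analysis steps (edges on the grayscale image).
    """
    plane8 = convert_to_8bit(np.asarray(gfap_plane, float))
    if edge_before_threshold:
        edges = sobel_edges(plane8)
    else:
        thresholded = apply_threshold(plane8, threshold_8bit)
        edges = sobel_edges(thresholded.data.astype(np.float64) * 255.0)
    blurred = gaussian_blur(edges, blur_sigma_px)
    peak = blurred.max()
    mask = apply_threshold(blurred, mask_threshold_frac * peak if peak > 0 else np.inf)
    return refine_mask(mask, closing_cycles)


def measure_branching(gfap_plane: np.ndarray,
                      dapi_plane: np.ndarray,
                      *,
                      pixel_size_um: float = defaults.PIXEL_SIZE_UM,
                      nucleus_threshold: float = defaults.NUCLEUS_THRESHOLD,
                      ball_radius_px: int = defaults.BALL_RADIUS_PX,
                      **chain_kwargs,
                      ) -> BranchingResult:
    """Branch points per cell, cell count and mean cell area for one field.

    The cell count is the number of live nuclei whose centroid falls inside
    the GFAP mask (confluent astrocytes merge into one component, so the
    component count undercounts cells). Junctions are assigned to cells via
    the mask component that contains the nucleus; junctions in components
    without a nucleus are included in the total but no per-cell count.
    """
    mask = branching_mask(gfap_plane, **chain_kwargs)
    skeleton = skeletonize_mask(mask)
    total, coords = count_branch_points(skeleton)

    nuclei = classify_nucleus_state(
        segment_nuclei(dapi_plane, threshold=nucleus_threshold,
                       ball_radius_px=ball_radius_px))
    live_in_mask = []
    for rec in nuclei:
        r, c = int(round(rec.centroid[0])), int(round(rec.centroid[1]))
        if rec.state == "live" and _inside(mask.data.shape, r, c) and mask.data[r, c]:
            live_in_mask.append(rec)
    n_cells = len(live_in_mask)

    flags: list[str] = []
    if n_cells == 0:
        return BranchingResult(0, math.nan, math.nan, total, [],
                               flags=["zero cells: per-cell metrics undefined"])

    labeled, _ = label_particles(mask, connectivity=8)
    comp_of_cell = {}
    for rec in live_in_mask:
        r, c = int(round(rec.centroid[0])), int(round(rec.centroid[1]))
        comp_of_cell[rec.label] = int(labeled.labels[r, c])
    junctions_per_comp: dict[int, int] = {}
    for (r, c) in coords:
        comp = int(labeled.labels[int(round(r)), int(round(c))])
        junctions_per_comp[comp] = junctions_per_comp.get(comp, 0) + 1
    per_cell = [junctions_per_comp.get(comp, 0) for comp in comp_of_cell.values()]

    area_um2 = measure_cell_area(mask, pixel_size_um)
    return BranchingResult(
        n_cells=n_cells,
        mean_cell_area_um2=area_um2 / n_cells,
        branch_points_per_cell=total / n_cells,
        total_branch_points=total,
        per_cell_branch_counts=per_cell,
        flags=flags,
    )
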