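"""Tau-inclusion particle quantification.

Implements the particle-analysis chain used for Cy3-labeled tau deposits —
set scale, convert to 16-bit, subtract background, fixed threshold, clear
outside the cellular-marker ROI, analyze particles — with per-particle
integrated density (IntDen = area x mean intensity, equivalently the pixel
sum), size-class assignment at the 5-200 / 201-2000 / 2001+ pixel cut-offs,
and per-living-cell normalization of the field summary. The same chain with
puncta-scale area bounds serves generic puncta counting (synaptophysin,
TUNEL) normalized to total nuclei.

The fixed threshold is mandatory configuration: it is never derived from the
image being measured. :func:`calibrate_threshold` freezes one from a
designated reference image so a whole batch/time-course shares it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_triangle

from . import defaults, morphometry
from .primitives import (
    BinaryMask,
    ImageStack,
    apply_threshold,
    clear_outside,
    convert_to_16bit,
    label_particles,
    max_project,
    refine_mask,
    subtract_background,
)


class ConfigError(ValueError):
    pass


@dataclass
class SizeClassCutoffs:
    """Contiguous pixel-area classes; areas below ``small[0]`` are discarded."""

    small: tuple[int, int] = defaults.SMALL_BOUNDS_PX
    medium: tuple[int, int] = defaults.MEDIUM_BOUNDS_PX
    large_min: int = defaults.LARGE_MIN_PX

    def __post_init__(self) -> None:
        if not (0 < self.small[0] <= self.small[1]):
            raise ConfigError("small bounds must be a positive interval")
        if self.medium[0] != self.small[1] + 1 or self.medium[1] < self.medium[0]:
            raise ConfigError("medium class must start right after small and be non-empty")
        if self.large_min != self.medium[1] + 1:
            raise ConfigError("large class must start right after medium")

    def classify(self, area_px: int) -> str | None:
        """Class name for a pixel area, or None below the detection floor."""
        if area_px < self.small[0]:
            return None
        if area_px <= self.small[1]:
            return "small"
        if area_px <= self.medium[1]:
            return "medium"
        return "large"


@dataclass
class ParticleRecord:
    """One detected deposit/punctum."""

    label: int
    area_px: int
    area_um2: float
    mean_intensity: float
    int_den: float
    centroid: tuple[float, float]
    size_class: str | None = None


@dataclass
class InclusionSummary:
    """Per-field aggregate of the particle analysis."""

    n_particles: int
    total_area_px: int
    total_area_um2: float
    sum_int_den: float
    class_counts: dict[str, int]
    n_discarded_small: int
    n_live_nuclei: int | None = None
    particles_per_live: float = math.nan
    int_den_per_live: float = math.nan
    area_px_per_live: float = math.nan
    flags: list[str] = field(default_factory=list)


def calibrate_threshold(reference_plane: np.ndarray,
                        ball_radius_px: int = defaults.BALL_RADIUS_PX) -> float:
    """Freeze a fixed threshold from a reference image; reuse the value for
    the whole batch. Triangle thresholding on the background-subtracted
    plane: deposits cover a tiny area fraction at heterogeneous intensities,
    the regime the triangle method is built for."""
    sub = subtract_background(np.asarray(reference_plane, float), ball_radius_px)
    return float(threshold_triangle(sub))


def build_roi(marker_plane: np.ndarray,
              threshold: float = defaults.MARKER_THRESHOLD,
              closing_cycles: int = defaults.CLOSING_CYCLES) -> BinaryMask:
    """Cellular-marker ROI: fixed threshold on the raw marker plane, refined
    by dilation/erosion cycles. Covers the union of cell bodies."""
    mask = apply_threshold(np.asarray(marker_plane, float), threshold)
    out = refine_mask(mask, closing_cycles)
    out.provenance = f"roi:{mask.provenance}|close x{closing_cycles}"
    return out


def _measure_components(labeled, areas, measure_plane: np.ndarray,
                        pixel_size_um: float,
                        cutoffs: SizeClassCutoffs) -> list[ParticleRecord]:
    records = []
    lbl = labeled.labels
    for k in range(1, labeled.count + 1):
        sel = lbl == k
        area = int(areas[k - 1])
        vals = measure_plane[sel]
        rows, cols = np.nonzero(sel)
        mean_int = float(vals.mean())
        records.append(ParticleRecord(
            label=k,
            area_px=area,
            area_um2=area * pixel_size_um ** 2,
            mean_intensity=mean_int,
            int_den=float(vals.sum()),
            centroid=(float(rows.mean()), float(cols.mean())),
            size_class=cutoffs.classify(area),
        ))
    return records


def classify_sizes(records: list[ParticleRecord],
                   cutoffs: SizeClassCutoffs | None = None,
                   ) -> tuple[list[ParticleRecord], dict[str, int], int]:
    """Assign size classes; drop records below the small-class floor.

    Returns (retained records, per-class counts, number discarded).
    """
    cutoffs = cutoffs or SizeClassCutoffs()
    counts = {"small": 0, "medium": 0, "large": 0}
    retained = []
    discarded = 0
    for rec in records:
        cls = cutoffs.classify(rec.area_px)
        rec.size_class = cls
        if cls is None:
            discarded += 1
            continue
        counts[cls] += 1
        retained.append(rec)
    return retained, counts, discarded


def quantify_inclusions(stack: ImageStack,
                        threshold: float,
                        *,
                        deposit_channel: str = "deposit",
                        marker_channel: str = "marker",
                        nuclei_channel: str = "nuclei",
                        ball_radius_px: int = defaults.BALL_RADIUS_PX,
                        connectivity: int = defaults.CONNECTIVITY,
                        cutoffs: SizeClassCutoffs | None = None,
                        roi: BinaryMask | None = None,
                        marker_threshold: float = defaults.MARKER_THRESHOLD,
                        closing_cycles: int = defaults.CLOSING_CYCLES,
                        intden_on_raw: bool = False,
                        n_live_nuclei: int | None = None,
                        ) -> tuple[list[ParticleRecord], InclusionSummary]:
    """Run the inclusion macro chain on the deposit channel of a field.

    ``threshold`` is the fixed deposit threshold applied to the
    background-subtracted 16-bit plane (the same value must be reused across
    the time points of an experiment). The summary is normalized to the
    number of living nuclei segmented from the DAPI channel (pass
    ``n_live_nuclei`` to override, e.g. from a manual count).
    """
    cutoffs = cutoffs or SizeClassCutoffs()
    for ch in (deposit_channel, marker_channel, nuclei_channel):
        if ch not in stack.channels:
            raise ConfigError(f"channel role {ch!r} missing from stack")

    # macro chain, in order
    plane = max_project(stack.channel_stack(deposit_channel))
    plane16 = convert_to_16bit(plane)
    sub = subtract_background(plane16, ball_radius_px)
    mask = apply_threshold(sub, threshold)
    if roi is None:
        marker = max_project(stack.channel_stack(marker_channel))
        roi = build_roi(marker, marker_threshold, closing_cycles)
    flags: list[str] = []
    if roi.area_px() == 0:
        flags.append("empty ROI")
    mask = clear_outside(mask, roi)
    labeled, areas = label_particles(mask, connectivity=connectivity,
                                     min_area_px=1, max_area_px=None)
    measure_plane = plane16 if intden_on_raw else sub
    records = _measure_components(labeled, areas, measure_plane,
                                  stack.pixel_size_um, cutoffs)
    retained, counts, discarded = classify_sizes(records, cutoffs)

    if n_live_nuclei is None:
        dapi = max_project(stack.channel_stack(nuclei_channel))
        nuclei = morphometry.segment_nuclei(dapi, ball_radius_px=ball_radius_px)
        nuclei = morphometry.classify_nucleus_state(nuclei)
        n_live_nuclei = sum(1 for n in nuclei if n.state == "live")

    summary = InclusionSummary(
        n_particles=len(retained),
        total_area_px=int(sum(r.area_px for r in retained)),
        total_area_um2=float(sum(r.area_um2 for r in retained)),
        sum_int_den=float(sum(r.int_den for r in retained)),
        class_counts=counts,
        n_discarded_small=discarded,
        n_live_nuclei=n_live_nuclei,
        flags=flags,
    )
    if n_live_nuclei and n_live_nuclei > 0:
        summary.particles_per_live = summary.n_particles / n_live_nuclei
        summary.int_den_per_live = summary.sum_int_den / n_live_nuclei
        summary.area_px_per_live = summary.total_area_px / n_live_nuclei
    else:
        summary.flags.append("zero live nuclei: normalized metrics undefined")
    return retained, summary


def count_puncta(stack: ImageStack,
                 channel_role: str,
                 threshold: float,
                 *,
                 min_area_px: int = 2,
                 max_area_px: int = 50,
                 ball_radius_px: int = defaults.BALL_RADIUS_PX,
                 connectivity: int = defaults.CONNECTIVITY,
                 nuclei_channel: str = "nuclei",
                 n_total_nuclei: int | None = None,
                 ) -> tuple[int, float]:
    """Puncta count in a channel, normalized to the total number of nuclei.

    Same chain as the inclusion macro with puncta-scale area bounds; the
    normalizer counts all nuclei (live and condensed). Returns
    (count, count / total nuclei).
    """
    if channel_role not in stack.channels:
        raise ConfigError(f"channel role {channel_role!r} missing from stack")
    plane = max_project(stack.channel_stack(channel_role))
    sub = subtract_background(convert_to_16bit(plane), ball_radius_px)
    mask = apply_threshold(sub, threshold)
    labeled, _ = label_particles(mask, connectivity=connectivity,
                                 min_area_px=min_area_px, max_area_px=max_area_px)
    if n_total_nuclei is None:
        dapi = max_project(stack.channel_stack(nuclei_channel))
        n_total_nuclei = len(morphometry.segment_nuclei(dapi,
                                                        ball_radius_px=ball_radius_px))
    per_cell = labeled.count / n_total_nuclei if n_total_nuclei else math.nan
    return labeled.count, per_cell
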