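"""Synthetic microscopy fields and current traces with exact ground truth.

The generator emulates the data the quantification stages consume:

* **inclusion fields** — a confluent astrocyte sheet (cellular-marker
  channel), live and condensed DAPI nuclei, and fluorescent tau deposits in
  three pixel-area size classes, rendered as filled ellipses of uniform
  intensity so the true area and integrated density of every deposit are
  exactly bookkeepable;
* **branch fields** — astrocytes drawn as thick-stroked trees with a known
  number of topological branch points, one nucleus per cell;
* **current traces** — a baseline with difference-of-exponential EPSC events
  (inward, i.e. downward deflections) plus Gaussian noise.

Every field/trace comes with a :class:`GroundTruth` ledger holding the true
pixel sets, nucleus states, branch-point coordinates and event times against
which the analysis stages are scored. Identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from . import defaults
from .primitives import ImageStack

# internal rendering constants (amplitudes above background; integers so the
# value-preserving 16-bit step of the macro chain is exact on clean renders)
_DEPOSIT_CLASS_AREAS = {"small": (10, 80), "medium": (250, 900), "large": (2100, 3200)}
_CLASS_BOUNDS = {
    "small": defaults.SMALL_BOUNDS_PX,
    "medium": defaults.MEDIUM_BOUNDS_PX,
    "large": (defaults.LARGE_MIN_PX, np.inf),
}
# nucleus spacing: boundary gaps must survive one 3x3 closing cycle of the
# segmenter (>= 4 px), and a condensed nucleus must stay nearer its host than
# any other live nucleus (host dist + margin < live spacing - host dist)
_LIVE_MIN_SEP_PX = 34          # live-nucleus center spacing in inclusion fields
_CONDENSED_HOST_DIST = (15.0, 16.0)  # condensed nucleus distance from host center
_GFAP_INTENSITY = 250.0
_MAX_ATTEMPTS = 5000


class FieldTooCrowdedError(RuntimeError):
    """Rejection sampling could not place the requested objects."""


class SpecError(ValueError):
    """A generator spec violates its invariants."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class FieldSpec:
    """Acquisition geometry shared by all synthetic fields."""

    width_px: int = 256
    height_px: int = 256
    pixel_size_um: float = defaults.PIXEL_SIZE_UM
    n_z: int = 1
    seed: int = 0
    background_level: float = 100.0
    noise_sd: float = 10.0

    def validate(self) -> None:
        if self.width_px < 32 or self.height_px < 32:
            raise SpecError("field must be at least 32x32 px")
        if self.n_z < 1:
            raise SpecError("n_z must be >= 1")
        if self.noise_sd < 0 or self.background_level < 0:
            raise SpecError("noise_sd and background_level must be >= 0")
        if self.pixel_size_um <= 0:
            raise SpecError("pixel_size_um must be positive")


@dataclass
class InclusionFieldSpec(FieldSpec):
    """A deposit/nuclei/marker field emulating tau-inclusion micrographs."""

    n_particles_per_class: tuple[int, int, int] = (8, 4, 1)
    intensity_range: tuple[int, int] = (300, 800)
    min_separation_px: int = 3
    n_live_nuclei: int = 12
    n_condensed_nuclei: int = 4
    roi_fraction: float = 0.5
    n_particles_outside_roi: int = 0
    n_fused_nucleus_pairs: int = 0

    def validate(self) -> None:
        super().validate()
        if any(n < 0 for n in self.n_particles_per_class):
            raise SpecError("particle counts must be >= 0")
        if self.min_separation_px < 2:
            raise SpecError("min_separation_px must be >= 2")
        if not (0 < self.roi_fraction <= 1):
            raise SpecError("roi_fraction must be in (0, 1]")
        if not (0 < self.intensity_range[0] <= self.intensity_range[1]):
            raise SpecError("intensity_range must be a positive interval")


@dataclass
class BranchFieldSpec(FieldSpec):
    """GFAP-like field of tree-shaped cells with known branch counts."""

    n_cells: int = 2
    branch_points_per_cell: tuple[int, ...] = (2, 3)
    stroke_width_px: int = 3
    cell_area_um2: tuple[float, ...] | None = None

    def validate(self) -> None:
        super().validate()
        if self.n_cells < 1:
            raise SpecError("n_cells must be >= 1")
        if len(self.branch_points_per_cell) != self.n_cells:
            raise SpecError("branch_points_per_cell length must equal n_cells")
        if any(b < 0 for b in self.branch_points_per_cell):
            raise SpecError("branch counts must be >= 0")
        if self.stroke_width_px < 1:
            raise SpecError("stroke_width_px must be >= 1")


@dataclass
class TraceSpec:
    """A whole-cell current trace bearing EPSC-shaped events.

    Events are placed either at explicit ``event_times_s`` or by a Poisson
    process at ``rate_hz``; amplitudes come from ``amplitudes_pa`` (matched to
    explicit times) or are drawn uniformly from ``amplitude_range_pa``.
    """

    duration_s: float = 62.0
    sample_rate_hz: float = 5000.0
    event_times_s: tuple[float, ...] | None = None
    rate_hz: float | None = None
    amplitudes_pa: tuple[float, ...] | None = None
    amplitude_range_pa: tuple[float, float] = (12.0, 40.0)
    rise_tau_ms: float = 1.0
    decay_tau_ms: float = 6.0
    noise_sd_pa: float = 2.0
    baseline_pa: float = 0.0
    min_separation_s: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise SpecError("duration and sample rate must be positive")
        if self.decay_tau_ms <= self.rise_tau_ms:
            raise SpecError("decay_tau_ms must exceed rise_tau_ms")
        if self.noise_sd_pa < 0:
            raise SpecError("noise_sd_pa must be >= 0")
        if self.event_times_s is not None:
            if any(not (0 <= t < self.duration_s) for t in self.event_times_s):
                raise SpecError("event times must lie in [0, duration_s)")
            if self.amplitudes_pa is not None and \
                    len(self.amplitudes_pa) != len(self.event_times_s):
                raise SpecError("amplitudes_pa must match event_times_s in length")
        if self.amplitudes_pa is not None and any(a <= 0 for a in self.amplitudes_pa):
            raise SpecError("amplitudes must be positive")


@dataclass
class ScenarioSpec:
    """Labeled groups of inclusion fields with per-group spec overrides."""

    groups: dict[str, dict] = field(default_factory=dict)
    n_fields_per_group: int = 12
    base: InclusionFieldSpec = field(default_factory=InclusionFieldSpec)
    seed: int = 0


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class ParticleTruth:
    label: int
    rows: np.ndarray
    cols: np.ndarray
    size_class: str
    amplitude: float
    in_roi: bool = True

    @property
    def area_px(self) -> int:
        return len(self.rows)

    @property
    def total_intensity(self) -> float:
        """Sum of rendered above-background pixel values."""
        return float(self.amplitude * self.area_px)

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.rows.mean()), float(self.cols.mean())


@dataclass
class NucleusTruth:
    centroid: tuple[float, float]
    state: str                      # "live" | "condensed"
    rows: np.ndarray
    cols: np.ndarray
    intensity: float
    host_cell_id: int | None = None  # live-nucleus index for condensed nuclei


@dataclass
class CellTruth:
    cell_id: int
    branch_points: list[tuple[int, int]]
    nucleus_centroid: tuple[float, float]
    area_px: int

    @property
    def branch_count(self) -> int:
        return len(self.branch_points)


@dataclass
class EventTruth:
    time_s: float
    amplitude_pa: float
    rise_tau_ms: float
    decay_tau_ms: float


@dataclass
class GroundTruth:
    """The generator's ledger, consistent with the noise-free render."""

    particles: list[ParticleTruth] = field(default_factory=list)
    nuclei: list[NucleusTruth] = field(default_factory=list)
    cells: list[CellTruth] = field(default_factory=list)
    events: list[EventTruth] = field(default_factory=list)
    astro_labels: np.ndarray | None = None   # Voronoi astrocyte territories
    roi_mask: np.ndarray | None = None       # cellular-marker sheet
    params: dict = field(default_factory=dict)

    def particle_label_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=np.int32)
        for p in self.particles:
            out[p.rows, p.cols] = p.label
        return out

    def n_live(self) -> int:
        return sum(1 for n in self.nuclei if n.state == "live")

    def n_condensed(self) -> int:
        return sum(1 for n in self.nuclei if n.state == "condensed")

    def expected_component_count(self, connectivity: int = 8) -> int:
        """Components of the union of true pixel sets (adjacency analysis)."""
        shape = self.params.get("shape")
        mask = self.particle_label_mask(shape) > 0
        structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
        _, n = ndimage.label(mask, structure=structure)
        return n

    def expected_nucleus_components(self, connectivity: int = 8) -> int:
        shape = self.params.get("shape")
        mask = np.zeros(shape, dtype=bool)
        for nuc in self.nuclei:
            mask[nuc.rows, nuc.cols] = True
        structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
        _, n = ndimage.label(mask, structure=structure)
        return n

    def summary_dict(self) -> dict:
        """JSON-serializable summary (pixel sets reduced to areas/centroids)."""
        return {
            "particles": [
                {"label": p.label, "area_px": p.area_px, "size_class": p.size_class,
                 "total_intensity": p.total_intensity, "centroid": list(p.centroid),
                 "in_roi": p.in_roi}
                for p in self.particles
            ],
            "nuclei": [
                {"centroid": list(n.centroid), "state": n.state,
                 "host_cell_id": n.host_cell_id, "area_px": len(n.rows)}
                for n in self.nuclei
            ],
            "cells": [
                {"cell_id": c.cell_id, "branch_count": c.branch_count,
                 "branch_points": [list(b) for b in c.branch_points],
                 "area_px": c.area_px}
                for c in self.cells
            ],
            "events": [dataclasses.asdict(e) for e in self.events],
            "params": {k: v for k, v in self.params.items() if k != "shape"},
        }


# ---------------------------------------------------------------------------
# inclusion fields
# ---------------------------------------------------------------------------

def _sheet_mask(h: int, w: int, roi_fraction: float) -> np.ndarray:
    """Centered ellipse (or rectangle for high coverage) of ~roi_fraction area."""
    mask = np.zeros((h, w), dtype=bool)
    if roi_fraction >= 0.999:
        mask[:] = True
        return mask
    s = np.sqrt(roi_fraction * 4.0 / np.pi)
    if s <= 0.98:
        rr, cc = draw_ellipse(h / 2 - 0.5, w / 2 - 0.5, s * h / 2, s * w / 2, shape=(h, w))
        mask[rr, cc] = True
    else:
        t = np.sqrt(roi_fraction)
        mh, mw = int(round(h * (1 - t) / 2)), int(round(w * (1 - t) / 2))
        mask[mh:h - mh, mw:w - mw] = True
    return mask


def _place_live_nuclei(rng, sheet: np.ndarray, n: int, radius: int) -> list[tuple[int, int]]:
    eroded = ndimage.binary_erosion(sheet, iterations=radius + 1)
    rows, cols = np.nonzero(eroded)
    if len(rows) == 0 and n > 0:
        raise FieldTooCrowdedError("ROI too small for nuclei")
    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < n:
        if attempts > _MAX_ATTEMPTS:
            raise FieldTooCrowdedError("could not place live nuclei: field too crowded")
        attempts += 1
        i = rng.integers(len(rows))
        cand = (int(rows[i]), int(cols[i]))
        if all((cand[0] - r) ** 2 + (cand[1] - c) ** 2 >= _LIVE_MIN_SEP_PX ** 2
               for r, c in centers):
            centers.append(cand)
    return centers


def _render_disk(plane: np.ndarray, center: tuple[float, float], radius: int,
                 amplitude: float) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = draw_disk(center, radius, shape=plane.shape)
    plane[rr, cc] += amplitude
    return rr, cc


def _sample_ellipse_pixels(rng, target_area: float, bounds: tuple[float, float],
                           shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Pixel offsets (around origin) of a filled ellipse with area inside bounds."""
    for _ in range(200):
        q = rng.uniform(0.55, 0.95)           # axis ratio
        b = np.sqrt(target_area * q / np.pi)
        a = target_area / (np.pi * b)
        theta = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(0, 0, a, b, rotation=theta)
        if bounds[0] <= len(rr) <= bounds[1]:
            return rr, cc
        target_area = float(np.clip(target_area, bounds[0] + 1, min(bounds[1], 1e9) - 1))
    raise FieldTooCrowdedError("could not rasterize an ellipse inside its class bounds")


def generate_inclusion_field(spec: InclusionFieldSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a nuclei/marker/deposit field and its ground-truth ledger.

    Deposits are filled ellipses of uniform integer intensity placed fully
    inside the marker sheet (except the optional out-of-ROI extras), pairwise
    separated by at least ``min_separation_px`` in Chebyshev distance.
    Condensed nuclei are rendered smaller and brighter than live nuclei by
    the shared factors in :mod:`tauscope.defaults` and are always closest to
    their designated host live nucleus.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    truth = GroundTruth(params={
        "shape": (h, w), "spec": dataclasses.asdict(spec), "kind": "inclusion",
    })

    sheet = _sheet_mask(h, w, spec.roi_fraction)

    # --- nuclei ---------------------------------------------------------
    nuclei_plane = np.zeros((h, w))
    live_centers = _place_live_nuclei(rng, sheet, spec.n_live_nuclei,
                                      defaults.LIVE_NUCLEUS_RADIUS_PX)
    all_centers: list[tuple[float, float, float]] = []  # (row, col, radius)
    for r, c in live_centers:
        rr, cc = _render_disk(nuclei_plane, (r, c), defaults.LIVE_NUCLEUS_RADIUS_PX,
                              defaults.LIVE_NUCLEUS_INTENSITY)
        truth.nuclei.append(NucleusTruth((float(r), float(c)), "live", rr, cc,
                                         defaults.LIVE_NUCLEUS_INTENSITY))
        all_centers.append((r, c, defaults.LIVE_NUCLEUS_RADIUS_PX))

    # deliberately fused pairs (for merge-analysis tests): a second live
    # nucleus overlapping an existing one
    for k in range(spec.n_fused_nucleus_pairs):
        if k >= len(live_centers):
            break
        r0, c0 = live_centers[k]
        ang = rng.uniform(0, 2 * np.pi)
        d = defaults.LIVE_NUCLEUS_RADIUS_PX + 1  # overlap: < 2r
        r1, c1 = r0 + d * np.sin(ang), c0 + d * np.cos(ang)
        r1 = float(np.clip(r1, defaults.LIVE_NUCLEUS_RADIUS_PX + 1,
                           h - defaults.LIVE_NUCLEUS_RADIUS_PX - 2))
        c1 = float(np.clip(c1, defaults.LIVE_NUCLEUS_RADIUS_PX + 1,
                           w - defaults.LIVE_NUCLEUS_RADIUS_PX - 2))
        rr, cc = _render_disk(nuclei_plane, (r1, c1), defaults.LIVE_NUCLEUS_RADIUS_PX,
                              defaults.LIVE_NUCLEUS_INTENSITY)
        truth.nuclei.append(NucleusTruth((r1, c1), "live", rr, cc,
                                         defaults.LIVE_NUCLEUS_INTENSITY))
        all_centers.append((r1, c1, defaults.LIVE_NUCLEUS_RADIUS_PX))

    cond_eroded = ndimage.binary_erosion(
        sheet, iterations=defaults.CONDENSED_NUCLEUS_RADIUS_PX + 1)
    n_placed = 0
    attempts = 0
    while n_placed < spec.n_condensed_nuclei:
        if not live_centers:
            raise SpecError("condensed nuclei need at least one live host nucleus")
        if attempts > _MAX_ATTEMPTS:
            raise FieldTooCrowdedError("could not place condensed nuclei")
        attempts += 1
        host = int(rng.integers(len(live_centers)))
        hr, hc = live_centers[host]
        ang = rng.uniform(0, 2 * np.pi)
        d = rng.uniform(*_CONDENSED_HOST_DIST)
        r, c = hr + d * np.sin(ang), hc + d * np.cos(ang)
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < h and 0 <= ci < w and cond_eroded[ri, ci]):
            continue
        # must not touch other nuclei, and host must stay the nearest live nucleus
        ok = True
        for (orr, occ, orad) in all_centers:
            dist = np.hypot(ri - orr, ci - occ)
            if (orr, occ) == (float(hr), float(hc)):
                continue
            if dist < orad + defaults.CONDENSED_NUCLEUS_RADIUS_PX + 4:
                ok = False
                break
        if not ok:
            continue
        rr, cc = _render_disk(nuclei_plane, (ri, ci),
                              defaults.CONDENSED_NUCLEUS_RADIUS_PX,
                              defaults.CONDENSED_NUCLEUS_INTENSITY)
        truth.nuclei.append(NucleusTruth((float(ri), float(ci)), "condensed", rr, cc,
                                         defaults.CONDENSED_NUCLEUS_INTENSITY,
                                         host_cell_id=host))
        all_centers.append((float(ri), float(ci), defaults.CONDENSED_NUCLEUS_RADIUS_PX))
        n_placed += 1

    # --- deposits --------------------------------------------------------
    deposit_plane = np.zeros((h, w))
    occupied = np.zeros((h, w), dtype=bool)
    blocked = np.zeros((h, w), dtype=bool)
    outside = ~ndimage.binary_dilation(sheet, iterations=2)
    label = 0

    def _place_particle(size_class: str, in_roi: bool) -> None:
        nonlocal label, blocked
        lo, hi = _DEPOSIT_CLASS_AREAS[size_class]
        bounds = _CLASS_BOUNDS[size_class]
        for _ in range(_MAX_ATTEMPTS):
            target = rng.uniform(lo, hi)
            drr, dcc = _sample_ellipse_pixels(rng, target, bounds, (h, w))
            r0 = int(rng.integers(0, h))
            c0 = int(rng.integers(0, w))
            rr, cc = drr + r0, dcc + c0
            if rr.min() < 1 or cc.min() < 1 or rr.max() >= h - 1 or cc.max() >= w - 1:
                continue
            region = sheet if in_roi else outside
            if not region[rr, cc].all() or blocked[rr, cc].any():
                continue
            amp = float(rng.integers(spec.intensity_range[0], spec.intensity_range[1] + 1))
            deposit_plane[rr, cc] += amp
            occupied[rr, cc] = True
            blocked = ndimage.maximum_filter(occupied, size=2 * spec.min_separation_px + 1)
            label += 1
            truth.particles.append(ParticleTruth(label, rr, cc, size_class, amp, in_roi))
            return
        raise FieldTooCrowdedError(f"could not place a {size_class} deposit: field too crowded")

    # place large first: a big ellipse rarely fits once small deposits have
    # fragmented the sheet
    n_by_class = dict(zip(("small", "medium", "large"), spec.n_particles_per_class))
    for size_class in ("large", "medium", "small"):
        for _ in range(n_by_class[size_class]):
            _place_particle(size_class, in_roi=True)
    for _ in range(spec.n_particles_outside_roi):
        _place_particle("small", in_roi=False)

    # --- astrocyte territories (Voronoi of live nuclei within the sheet) --
    if live_centers:
        tree = cKDTree(np.asarray(live_centers, dtype=float))
        srows, scols = np.nonzero(sheet)
        _, nearest = tree.query(np.column_stack([srows, scols]))
        astro = np.zeros((h, w), dtype=np.int32)
        astro[srows, scols] = nearest + 1
        truth.astro_labels = astro
    truth.roi_mask = sheet

    # --- assemble stack ---------------------------------------------------
    marker_plane = np.where(sheet, defaults.MARKER_INTENSITY, 0.0)
    focal = spec.n_z // 2
    data = np.full((3, spec.n_z, h, w), float(spec.background_level))
    data[0, focal] += nuclei_plane
    data[1, focal] += marker_plane
    data[2, focal] += deposit_plane
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
        np.clip(data, 0.0, None, out=data)
    stack = ImageStack(data, spec.pixel_size_um,
                       {"nuclei": 0, "marker": 1, "deposit": 2})
    return stack, truth


# ---------------------------------------------------------------------------
# branch fields
# ---------------------------------------------------------------------------

_CELL_BOX_PX = 120      # grid cell allocated to one tree
_BOX_MARGIN_PX = 14


def _draw_tree(rng, box: tuple[int, int, int, int], n_branches: int,
               width_px: int, target_area_px: float | None,
               mask: np.ndarray) -> CellTruth:
    """One caterpillar tree: horizontal backbone + alternating vertical branches."""
    r0, c0, r1, c1 = box
    rows_mid = (r0 + r1) // 2 + int(rng.integers(-6, 7))
    x_start = c0 + _BOX_MARGIN_PX
    x_end = c1 - _BOX_MARGIN_PX
    backbone_len = x_end - x_start
    branch_len = 24
    if target_area_px is not None and width_px > 0:
        # total stroke length ~ target area / width; shrink/grow branch length
        total_len = target_area_px / width_px
        branch_len = int(np.clip((total_len - backbone_len) / max(n_branches, 1), 12, 34)) \
            if n_branches else branch_len

    segments = [((rows_mid, x_start), (rows_mid, x_end))]
    branch_points: list[tuple[int, int]] = []
    if n_branches > 0:
        usable = backbone_len - 24
        xs = np.linspace(x_start + 12, x_end - 12, n_branches)
        spacing = usable / (n_branches - 1) if n_branches > 1 else usable
        if spacing < 11:
            raise FieldTooCrowdedError("too many branch points for the cell box")
        jitter = int(np.clip((spacing - 11) // 2, 0, 3))
        for i, x in enumerate(xs):
            x = int(round(x + rng.integers(-jitter, jitter + 1)))
            side = -1 if i % 2 == 0 else 1
            length = branch_len + int(rng.integers(-3, 4))
            y_end = int(np.clip(rows_mid + side * length, r0 + 2, r1 - 2))
            segments.append(((rows_mid, x), (y_end, x)))
            branch_points.append((rows_mid, x))

    cell_mask = np.zeros_like(mask)
    for (ra, ca), (rb, cb) in segments:
        rr, cc = draw_line(ra, ca, rb, cb)
        cell_mask[rr, cc] = True
    if width_px > 1:
        cell_mask = ndimage.binary_dilation(cell_mask, structure=np.ones((width_px, width_px)))
    mask |= cell_mask
    nucleus = (float(rows_mid), float((x_start + x_end) / 2))
    return CellTruth(cell_id=0, branch_points=branch_points,
                     nucleus_centroid=nucleus, area_px=int(cell_mask.sum()))


def generate_branch_field(spec: BranchFieldSpec) -> tuple[ImageStack, GroundTruth]:
    """Render tree-shaped cells whose true branch counts are known exactly.

    Cells are laid out on a grid of non-overlapping boxes; each cell is a
    horizontal backbone stroke with perpendicular side branches attached at
    well-separated points on alternating sides, so each attachment is a
    single degree-3 junction of the cell's skeleton.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    cols = max(1, w // _CELL_BOX_PX)
    rows = max(1, h // _CELL_BOX_PX)
    if spec.n_cells > cols * rows:
        raise FieldTooCrowdedError(
            f"{spec.n_cells} cells do not fit: capacity {cols * rows} at {w}x{h}")

    gfap_mask = np.zeros((h, w), dtype=bool)
    nuclei_plane = np.zeros((h, w))
    truth = GroundTruth(params={"shape": (h, w), "spec": dataclasses.asdict(spec),
                                "kind": "branch"})
    for i in range(spec.n_cells):
        gr, gc = divmod(i, cols)
        box = (gr * _CELL_BOX_PX, gc * _CELL_BOX_PX,
               min((gr + 1) * _CELL_BOX_PX, h) - 1, min((gc + 1) * _CELL_BOX_PX, w) - 1)
        target = None
        if spec.cell_area_um2 is not None:
            target = spec.cell_area_um2[i] / spec.pixel_size_um ** 2
        cell = _draw_tree(rng, box, spec.branch_points_per_cell[i],
                          spec.stroke_width_px, target, gfap_mask)
        cell.cell_id = i + 1
        truth.cells.append(cell)
        rr, cc = _render_disk(nuclei_plane, cell.nucleus_centroid,
                              defaults.LIVE_NUCLEUS_RADIUS_PX,
                              defaults.LIVE_NUCLEUS_INTENSITY)
        truth.nuclei.append(NucleusTruth(cell.nucleus_centroid, "live", rr, cc,
                                         defaults.LIVE_NUCLEUS_INTENSITY,
                                         host_cell_id=i + 1))

    data = np.full((2, spec.n_z, h, w), float(spec.background_level))
    focal = spec.n_z // 2
    data[0, focal] += nuclei_plane
    data[1, focal] += np.where(gfap_mask, _GFAP_INTENSITY, 0.0)
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
        np.clip(data, 0.0, None, out=data)
    stack = ImageStack(data, spec.pixel_size_um, {"nuclei": 0, "gfap": 1})
    truth.roi_mask = gfap_mask
    return stack, truth


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def epsc_kernel(rise_tau_ms: float, decay_tau_ms: float,
                sample_rate_hz: float) -> np.ndarray:
    """Unit-amplitude difference-of-exponentials, positive-up, peak = 1.

    g(t) = exp(-t/tau_d) - exp(-t/tau_r), rescaled by its closed-form peak at
    t* = tau_r*tau_d/(tau_d-tau_r) * ln(tau_d/tau_r); truncated at 8 decay
    constants.
    """
    tr, td = rise_tau_ms / 1000.0, decay_tau_ms / 1000.0
    dt = 1.0 / sample_rate_hz
    t = np.arange(0.0, 8.0 * td, dt)
    g = np.exp(-t / td) - np.exp(-t / tr)
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    return g / peak


def generate_trace(spec: TraceSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a current trace (pA) with EPSC events as downward deflections.

    Returns the sample array (length ``duration_s * sample_rate_hz``) and a
    ledger whose event times are aligned to the sample grid. Overlapping
    events superpose linearly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    trace = np.full(n, float(spec.baseline_pa))
    kernel = epsc_kernel(spec.rise_tau_ms, spec.decay_tau_ms, spec.sample_rate_hz)
    truth = GroundTruth(params={"kind": "trace", "spec": dataclasses.asdict(spec)})

    if spec.event_times_s is not None:
        times = list(spec.event_times_s)
    elif spec.rate_hz is not None:
        times = []
        t = 0.0
        while True:
            gap = rng.exponential(1.0 / spec.rate_hz)
            if spec.min_separation_s is not None:
                gap = max(gap, spec.min_separation_s)
            t += gap
            if t >= spec.duration_s:
                break
            times.append(t)
    else:
        times = []

    if spec.amplitudes_pa is not None and spec.event_times_s is not None:
        amps = list(spec.amplitudes_pa)
    else:
        amps = [float(rng.uniform(*spec.amplitude_range_pa)) for _ in times]

    for t0, amp in zip(times, amps):
        i0 = int(round(t0 * spec.sample_rate_hz))
        if i0 >= n:
            continue
        seg = kernel[: n - i0]
        trace[i0:i0 + len(seg)] -= amp * seg
        truth.events.append(EventTruth(i0 / spec.sample_rate_hz, float(amp),
                                       spec.rise_tau_ms, spec.decay_tau_ms))

    if spec.noise_sd_pa > 0:
        trace = trace + rng.normal(0.0, spec.noise_sd_pa, size=n)
    return trace, truth


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    """A scenario configuration names unknown keys."""


def generate_scenario(spec: ScenarioSpec) -> dict[str, list[tuple[ImageStack, GroundTruth]]]:
    """Generate labeled groups of inclusion fields from per-group overrides.

    ``spec.groups`` maps a group name to a dict of :class:`InclusionFieldSpec`
    field overrides (e.g. ``{"treated": {"n_live_nuclei": 4}}``). Each field
    gets a deterministic child seed derived from the scenario seed and its
    (group, field) position.
    """
    if len(spec.groups) < 2:
        raise ConfigError("a scenario needs at least 2 groups")
    valid = {f.name for f in dataclasses.fields(InclusionFieldSpec)}
    out: dict[str, list[tuple[ImageStack, GroundTruth]]] = {}
    for gi, (name, overrides) in enumerate(sorted(spec.groups.items())):
        unknown = set(overrides) - valid
        if unknown:
            raise ConfigError(f"unknown spec keys for group {name!r}: {sorted(unknown)}")
        # per-field seeds derive from the group's own seed when one is pinned
        # (so identically-configured groups yield identical fields), else from
        # the scenario seed and the group's position
        entropy = overrides.get("seed", None)
        plain = {k: v for k, v in overrides.items() if k != "seed"}
        fields = []
        for fi in range(spec.n_fields_per_group):
            key = [entropy, fi] if entropy is not None else [spec.seed, gi, fi]
            child = np.random.SeedSequence(key).generate_state(1)[0]
            fspec = dataclasses.replace(spec.base, seed=int(child) % (2 ** 31),
                                        **plain)
            fields.append(generate_inclusion_field(fspec))
        out[name] = fields
    return out
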