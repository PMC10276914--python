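"""Raster operators underlying the quantification macros.

These are the individual steps that the particle-analysis and branching
chains compose: background subtraction, fixed thresholding, ROI clearing,
connected-component labeling, z projection, Sobel edges, Gaussian blur,
skeletonization, morphological refinement and branch-point counting.

Conventions (recorded because tool dialects differ):

* thresholding is strict (``pixel > t``), and the threshold value is kept in
  the mask's provenance string;
* particle labeling defaults to 8-connectivity;
* "subtract background" is a rolling-ball style morphological background
  (grayscale opening with a flat disk element, default radius 50 px);
* "find edge" is the 3x3 Sobel gradient magnitude;
* coordinates are 0-based (row, col), origin top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, opening, skeletonize

from . import defaults


class GeometryError(ValueError):
    """Raster shapes do not match."""


class ParameterError(ValueError):
    """An operator parameter is out of its documented range."""


@dataclass
class ImageStack:
    """Multi-channel, optionally z-stacked raster with a physical pixel scale.

    ``data`` has shape ``(n_channels, n_z, height, width)`` and is held as
    float64 in arbitrary fluorescence units. ``channels`` maps a role name
    (``nuclei``, ``marker``, ``deposit``, ``yfp``, ``membrane``...) to its
    channel index.
    """

    data: np.ndarray
    pixel_size_um: float
    channels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise GeometryError(
                f"ImageStack data must be (channels, z, height, width), got shape {self.data.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageStack intensities must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def plane(self, role: str | int, z: int = 0) -> np.ndarray:
        """A single (height, width) plane for a channel role at a z slice."""
        idx = self.channels[role] if isinstance(role, str) else int(role)
        return self.data[idx, z]

    def channel_stack(self, role: str | int) -> np.ndarray:
        """All z slices of one channel, shape (n_z, height, width)."""
        idx = self.channels[role] if isinstance(role, str) else int(role)
        return self.data[idx]


@dataclass
class BinaryMask:
    """Boolean raster with a provenance note (how it was made)."""

    data: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise GeometryError("BinaryMask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def area_px(self) -> int:
        return int(self.data.sum())


@dataclass
class LabeledComponents:
    """Integer component raster: 0 = background, k = component k (1..count)."""

    labels: np.ndarray
    count: int
    connectivity: int

    def areas(self) -> np.ndarray:
        """Pixel area of each component, index k-1 for label k."""
        if self.count == 0:
            return np.zeros(0, dtype=np.int64)
        return np.bincount(self.labels.ravel(), minlength=self.count + 1)[1:]


# ---------------------------------------------------------------------------
# intensity-plane operators
# ---------------------------------------------------------------------------

def rolling_ball_background(plane: np.ndarray, ball_radius_px: int) -> np.ndarray:
    """Morphological background estimate: grayscale opening with a disk.

    The decomposed disk footprint realises the large convex element as a
    chain of small erosions/dilations, keeping the cost linear in radius.
    """
    footprint = disk(ball_radius_px, decomposition="sequence")
    return opening(np.asarray(plane, dtype=np.float64), footprint=footprint)


def subtract_background(plane: np.ndarray,
                        ball_radius_px: int = defaults.BALL_RADIUS_PX,
                        presmooth_sigma_px: float = 2.0) -> np.ndarray:
    """Subtract a rolling-ball style background; result clipped at 0.

    The background is estimated on a Gaussian pre-smoothed copy of the plane
    (as the classic rolling-ball implementations do): a bare min/max opening
    of a noisy image tracks the noise minima and biases the background low by
    several noise SDs. Pre-smoothing leaves clean renders untouched — on any
    constant plane the result is identically 0, and adding a constant offset
    to the input does not change the output. Set ``presmooth_sigma_px=0`` to
    disable.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if ball_radius_px < 1:
        raise ParameterError("ball_radius_px must be >= 1")
    if ball_radius_px > min(plane.shape):
        raise ParameterError(
            f"ball_radius_px={ball_radius_px} exceeds the smaller image dimension {min(plane.shape)}"
        )
    est_src = plane
    if presmooth_sigma_px > 0:
        est_src = ndimage.gaussian_filter(plane, presmooth_sigma_px, mode="reflect")
    background = rolling_ball_background(est_src, ball_radius_px)
    return np.clip(plane - background, 0.0, None)


def apply_threshold(plane: np.ndarray, t: float) -> BinaryMask:
    """Fixed threshold, strict: mask = (pixel > t)."""
    if not np.isfinite(t):
        raise ParameterError("threshold must be finite")
    plane = np.asarray(plane)
    return BinaryMask(plane > t, provenance=f"threshold>{t!r}")


def clear_outside(plane_or_mask, roi: BinaryMask):
    """Zero (or falsify) everything outside the ROI; inside is unchanged."""
    roi_arr = roi.data if isinstance(roi, BinaryMask) else np.asarray(roi, bool)
    if isinstance(plane_or_mask, BinaryMask):
        if plane_or_mask.shape != roi_arr.shape:
            raise GeometryError("mask/ROI shape mismatch")
        return BinaryMask(plane_or_mask.data & roi_arr,
                          provenance=plane_or_mask.provenance + "|clear_outside")
    plane = np.asarray(plane_or_mask, dtype=np.float64)
    if plane.shape != roi_arr.shape:
        raise GeometryError("plane/ROI shape mismatch")
    return np.where(roi_arr, plane, 0.0)


def convert_to_16bit(plane: np.ndarray) -> np.ndarray:
    """Value-preserving 16-bit conversion: round and clip to [0, 65535]."""
    return np.clip(np.rint(np.asarray(plane, dtype=np.float64)), 0, 65535)


def convert_to_8bit(plane: np.ndarray) -> np.ndarray:
    """Min-max linear rescale to [0, 255] (display-range downcast)."""
    plane = np.asarray(plane, dtype=np.float64)
    lo, hi = plane.min(), plane.max()
    if hi == lo:
        return np.zeros_like(plane)
    return np.rint((plane - lo) / (hi - lo) * 255.0)


def max_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum across z. Input shape (n_z, h, w); n_z=1 is identity."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack.copy()
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise GeometryError("max_project expects a (n_z, h, w) stack")
    return stack.max(axis=0)


_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)


def sobel_edges(plane: np.ndarray) -> np.ndarray:
    """3x3 Sobel gradient magnitude, sqrt(gx^2 + gy^2), reflective boundary."""
    plane = np.asarray(plane, dtype=np.float64)
    gx = ndimage.convolve(plane, _SOBEL_X, mode="reflect")
    gy = ndimage.convolve(plane, _SOBEL_X.T, mode="reflect")
    return np.hypot(gx, gy)


def gaussian_blur(plane: np.ndarray, sigma_px: float = defaults.GAUSSIAN_SIGMA_PX) -> np.ndarray:
    """Separable Gaussian convolution with reflective boundary."""
    if sigma_px <= 0:
        raise ParameterError("sigma_px must be positive")
    return ndimage.gaussian_filter(np.asarray(plane, dtype=np.float64), sigma_px, mode="reflect")


# ---------------------------------------------------------------------------
# mask operators
# ---------------------------------------------------------------------------

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def label_particles(mask: BinaryMask | np.ndarray,
                    connectivity: int = defaults.CONNECTIVITY,
                    min_area_px: int = 1,
                    max_area_px: int | None = None) -> tuple[LabeledComponents, np.ndarray]:
    """Connected components of a mask with an area gate.

    Components with pixel area outside ``[min_area_px, max_area_px]`` are
    dropped; survivors are relabeled consecutively 1..K. Returns the labeled
    raster and the per-component pixel areas.
    """
    if connectivity not in (4, 8):
        raise ParameterError("connectivity must be 4 or 8")
    if min_area_px < 1 or (max_area_px is not None and max_area_px < min_area_px):
        raise ParameterError("require 0 < min_area_px <= max_area_px")
    arr = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    raw, n = ndimage.label(arr, structure=_STRUCTURES[connectivity])
    if n == 0:
        return LabeledComponents(raw, 0, connectivity), np.zeros(0, dtype=np.int64)
    areas = np.bincount(raw.ravel(), minlength=n + 1)[1:]
    keep = areas >= min_area_px
    if max_area_px is not None:
        keep &= areas <= max_area_px
    remap = np.zeros(n + 1, dtype=np.int64)
    remap[1:][keep] = np.arange(1, keep.sum() + 1)
    labels = remap[raw]
    return LabeledComponents(labels, int(keep.sum()), connectivity), areas[keep].astype(np.int64)


def skeletonize_mask(mask: BinaryMask | np.ndarray) -> BinaryMask:
    """1-px-wide 8-connected skeleton preserving component count."""
    arr = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    return BinaryMask(skeletonize(arr), provenance="skeletonize")


def refine_mask(mask: BinaryMask | np.ndarray, n_cycles: int = defaults.CLOSING_CYCLES) -> BinaryMask:
    """``n_cycles`` of (3x3 dilation then 3x3 erosion); n_cycles=0 is identity."""
    if n_cycles < 0:
        raise ParameterError("n_cycles must be >= 0")
    arr = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    out = arr.copy()
    s = _STRUCTURES[8]
    for _ in range(n_cycles):
        out = ndimage.binary_dilation(out, structure=s)
        # border_value=1 so closing never erodes at the image boundary
        out = ndimage.binary_erosion(out, structure=s, border_value=1)
    return BinaryMask(out, provenance=f"refine x{n_cycles}")


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.int64)


def count_branch_points(skeleton: BinaryMask | np.ndarray) -> tuple[int, list[tuple[float, float]]]:
    """Merged branch points of a 1-px skeleton.

    A skeleton pixel qualifies when its 8-neighborhood contains >= 3 other
    skeleton pixels. Qualifying pixels that are themselves 8-adjacent belong
    to the same physical junction (thinning can emit 2-3 of them at a thick
    crossing), so they are clustered and each cluster counts once. Returns
    the merged count and the cluster centroids as (row, col).
    """
    arr = skeleton.data if isinstance(skeleton, BinaryMask) else np.asarray(skeleton, bool)
    neighbor_counts = ndimage.convolve(arr.astype(np.int64), _NEIGHBOR_KERNEL,
                                       mode="constant", cval=0)
    qualifying = arr & (neighbor_counts >= 3)
    clusters, n = ndimage.label(qualifying, structure=_STRUCTURES[8])
    if n == 0:
        return 0, []
    centroids = ndimage.center_of_mass(qualifying, clusters, index=range(1, n + 1))
    return n, [(float(r), float(c)) for r, c in centroids]
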