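"""FRET-biosensor seeding readout.

The biosensor reports tau seeding as aggregated-reporter YFP signal. The
readout is the summed YFP integrated density of a field, obtained with the
same particle-analysis chain as the tau-inclusion macro applied to the
max-intensity z projection, normalized to the area covered by cells in the
field (a hand-drawn or marker-derived mask) rather than to a DAPI count,
because DAPI excitation interferes with the CFP/YFP emission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import defaults
from .inclusions import SizeClassCutoffs, _measure_components, classify_sizes
from .primitives import (
    BinaryMask,
    ImageStack,
    apply_threshold,
    clear_outside,
    convert_to_16bit,
    label_particles,
    max_project,
    subtract_background,
)


@dataclass
class SeedingResult:
    yfp_int_den: float
    cell_area_um2: float
    normalized_int_den: float
    n_inclusions: int
    n_z_used: int
    flags: list[str] = field(default_factory=list)


def quantify_seeding(stack: ImageStack,
                     cell_area_mask: BinaryMask | np.ndarray,
                     threshold: float,
                     *,
                     yfp_channel: str = "yfp",
                     ball_radius_px: int = defaults.BALL_RADIUS_PX,
                     connectivity: int = defaults.CONNECTIVITY,
                     cutoffs: SizeClassCutoffs | None = None,
                     restrict_to_mask: bool = False,
                     ) -> SeedingResult:
    """Summed YFP IntDen per field, normalized to cell-covered area.

    ``cell_area_mask`` is the cell-coverage mask (hand-drawn on phase
    contrast, ingested from file, or marker-derived); its area in um^2 is the
    normalizer. By default the whole projection is measured (the mask only
    normalizes); ``restrict_to_mask`` additionally clears signal outside it.
    """
    mask_arr = cell_area_mask.data if isinstance(cell_area_mask, BinaryMask) \
        else np.asarray(cell_area_mask, bool)
    cutoffs = cutoffs or SizeClassCutoffs()

    projection = max_project(stack.channel_stack(yfp_channel))
    sub = subtract_background(convert_to_16bit(projection), ball_radius_px)
    sig = apply_threshold(sub, threshold)
    if restrict_to_mask:
        sig = clear_outside(sig, BinaryMask(mask_arr))
    labeled, areas = label_particles(sig, connectivity=connectivity)
    records = _measure_components(labeled, areas, sub, stack.pixel_size_um, cutoffs)
    retained, _, _ = classify_sizes(records, cutoffs)
    int_den = float(sum(r.int_den for r in retained))

    area_um2 = float(mask_arr.sum()) * stack.pixel_size_um ** 2
    flags: list[str] = []
    if area_um2 > 0:
        normalized = int_den / area_um2
    else:
        normalized = math.nan
        flags.append("empty cell-area mask: normalized value undefined")
    return SeedingResult(
        yfp_int_den=int_den,
        cell_area_um2=area_um2,
        normalized_int_den=normalized,
        n_inclusions=len(retained),
        n_z_used=stack.n_z,
        flags=flags,
    )
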