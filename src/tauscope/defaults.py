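"""Shared default parameters.

The live/condensed DAPI rendering factors and the classifier thresholds live
in one place so that the synthetic generator and the morphometry classifier
are guaranteed to agree. On real data the condensed-nucleus criterion must be
re-calibrated explicitly; these numbers describe the generator's conventions,
not a biological constant.
"""

# -- pixel geometry -----------------------------------------------------------
PIXEL_SIZE_UM = 0.3          # um per pixel side; always explicit config downstream

# -- DAPI nuclei (arbitrary fluorescence units, above background) -------------
LIVE_NUCLEUS_RADIUS_PX = 7          # disk radius -> area ~149 px
CONDENSED_NUCLEUS_RADIUS_PX = 4     # <=50% of live area (49 px vs 149 px)
LIVE_NUCLEUS_INTENSITY = 150.0
CONDENSED_NUCLEUS_INTENSITY = 320.0  # >=2x live mean intensity

# classifier thresholds, midway between the live and condensed renderings
CONDENSED_MAX_AREA_PX = 80
CONDENSED_MIN_INTENSITY = 230.0
NUCLEUS_THRESHOLD = 75.0            # segmentation threshold on DAPI (above background)
NUCLEUS_MIN_AREA_PX = 10
NUCLEUS_MAX_AREA_PX = 2000

# -- cellular marker / deposits ----------------------------------------------
MARKER_INTENSITY = 200.0
MARKER_THRESHOLD = 200.0            # on the raw marker plane (background ~100)
DEPOSIT_THRESHOLD = 100.0           # on the background-subtracted deposit plane

# -- macro chain parameters ---------------------------------------------------
BALL_RADIUS_PX = 50                 # rolling-ball background radius
GAUSSIAN_SIGMA_PX = 2.0             # blur step of the branching chain
CLOSING_CYCLES = 3                  # "several" dilation/erosion iterations
CONNECTIVITY = 8                    # particle labeling connectivity

# -- size classes (pixel areas, inclusive bounds) -----------------------------
SMALL_BOUNDS_PX = (5, 200)
MEDIUM_BOUNDS_PX = (201, 2000)
LARGE_MIN_PX = 2001

# -- EPSC analysis ------------------------------------------------------------
CRITERION_THRESHOLD = 3.0           # template-fit detection criterion
AMP_MIN_PA = 10.0                   # events with amplitude <= 10 pA are discarded
WINDOW_S = 60.0                     # analysis window per recording
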