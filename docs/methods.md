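# Methods

## Scope and measurement model

The package quantifies four kinds of readout from multi-channel fluorescence
fields (DAPI nuclei; a cellular marker such as GFAP, actin or LAMP-1; a
deposit channel such as Cy3-labeled tau; YFP for the FRET seeding
biosensor) and one from whole-cell voltage-clamp traces. All imaging stages
are compositions of a small set of raster operators
(`tauscope.primitives`), so every pipeline parameter is explicit and every
intermediate is auditable.

Conventions: intensities are held as float64 in arbitrary fluorescence
units and must be finite and non-negative after ingestion; coordinates are
0-based (row, col) with the origin top-left; thresholding is strict
(`pixel > t`) and each mask records its provenance; particle labeling
defaults to 8-connectivity (configurable to 4).

## The inclusion chain

`quantify_inclusions` runs, in order: max z-projection → value-preserving
16-bit conversion (round + clip; a min–max rescale here would destroy the
physical meaning of integrated density) → rolling-ball background
subtraction → fixed threshold → clearing outside the cellular-marker ROI →
connected-component analysis with per-component area, mean intensity,
IntDen (= pixel sum of the background-subtracted plane; a config flag
measures the raw plane instead) → size classes at 5–200 / 201–2000 / 2001+
px with areas < 5 px discarded as sub-resolution.

*Background subtraction* is implemented as a grayscale opening with a flat
disk element (default radius 50 px, the common default of macro-based
particle analysis). The background is estimated on a Gaussian pre-smoothed
copy (σ = 2 px): a bare min/max opening of a noisy plane tracks the noise
minima and sits several noise SDs below the true background, which would
flood any fixed threshold. On clean renders the pre-smoothing changes
nothing (the opening of a constant is that constant), so ground-truth
recovery is exact.

*The threshold is mandatory configuration*, never derived from the image
being measured — the same value must serve every time point of an
experiment. `calibrate_threshold` freezes one from a designated reference
image using triangle thresholding (suited to histograms whose foreground
is a tiny area fraction at heterogeneous intensities; Otsu splits the
foreground modes in that regime).

*Normalization*: field summaries are divided by the number of living nuclei
segmented from the DAPI channel; zero live nuclei flags the normalized
metrics as undefined while raw metrics are still emitted. Classification
into size classes depends only on pixel areas and the configured cut-offs,
never on the pixel scale; µm² values are also emitted (pixel scale is
explicit config, default 0.3 µm/px) but pixel-unit results are
authoritative, since published pixel↔µm² correspondences for these
cut-offs are not mutually consistent.

## Morphometry

*Nucleus segmentation* is background subtraction → threshold → one closing
cycle → labeling with nucleus-scale area bounds (10–2000 px), optionally
followed by a distance-transform watershed to split touching nuclei. A
nucleus is **condensed** (apoptotic) iff its area is ≤ 80 px *and* its mean
intensity is ≥ 230 units (both inclusive) — small and bright. The criterion
is operational, not biological: classification in practice is done by eye,
so the defaults are tied to the synthetic generator's rendering factors
(condensed nuclei drawn at ≤ 50 % the area and ≥ 2× the intensity of live
nuclei) and real data require explicit recalibration.

*Accumulation scoring*: astrocyte territories are an integer label raster;
because confluent astrocytes merge into a single marker component,
territories are built by nearest-live-nucleus (Voronoi) partition of the
marker mask rather than component labeling. Each condensed nucleus is
assigned to the territory containing its centroid (engulfment itself is
not observable in a single frame); unassigned condensed nuclei count
toward the total but no bin. Bins {0, 1–2, 3–4, 5+} are fractions over
living astrocytes and always sum to 1.

*Branching*: the chain is 8-bit min–max conversion → fixed threshold →
Sobel gradient magnitude of the (0/255) mask → Gaussian blur (σ = 2 px) →
re-threshold at 10 % of the blurred maximum → dilation/erosion refinement
(default 3 cycles of 3×3 dilate-then-erode, with erosion treating the
outside as foreground so image borders are never eaten) → skeletonization
→ branch points. The refinement is applied to the mask *before* thinning:
closing a 1-px skeleton adds pixels at junction elbows and breaks the
1-px-wide precondition of the branch-point counter. An
`edge_before_threshold` flag swaps the first two analysis steps for users
whose macros ran edges on the grayscale image. A branch point is a
skeleton pixel whose 8-neighborhood holds ≥ 3 skeleton pixels; adjacent
qualifying pixels are one physical junction (thinning emits 2–3 of them at
a thick crossing) and are merged by 8-connected clustering, so an X counts
once. The cell count is the number of live nuclei inside the mask (not the
component count, for the confluence reason above); branch points per cell
and mean cell area divide by it.

## Seeding readout

YFP integrated density of the max z-projection, measured with the same
inclusion chain, summed per field and divided by the cell-covered area in
µm². The normalizer is a mask (hand-drawn masks ingested from file, or
derived from a marker channel) rather than a DAPI count because DAPI
excitation interferes with CFP/YFP emission. No FRET ratioing is
performed: the biosensor's aggregated-reporter signal is quantified as a
scalar YFP emission, matching how the assay is scored.

## EPSC analysis

Events are inward (downward) deflections; amplitudes are reported as
positive magnitudes. The canonical event is a difference of exponentials
g(t) = exp(−t/τ_d) − exp(−t/τ_r), normalized to unit peak (closed-form
peak at t* = τ_r τ_d/(τ_d−τ_r) · ln(τ_d/τ_r)); defaults τ_r = 1 ms,
τ_d = 6 ms. A template may be built from 10–20 representative events
(fewer is refused): snippets are baseline-subtracted (median of the 5 ms
before onset), peak-aligned, averaged, unit-normalized, and the kinetic
constants fitted to the average.

Detection slides the template along the trace and fits
`scale·template + offset` by least squares at every lag (running sums via
overlap-add convolution); the detection criterion is scale / SE(scale).
The free offset makes detection invariant to holding current. Criterion
local maxima above the threshold (default 3.0) are candidates; because the
template still fits partway down a real event's decay, the criterion forms
one broad lobe per event whose secondary maxima can carry fitted
amplitudes above the gate, so candidates within one merge window — the
template's time-to-peak plus two decay constants (default ≈ 14 ms,
configurable) — keep only the highest criterion. A consequence is that two
genuine events closer than the merge window are reported as one; at the
event rates studied here (1–3 Hz) this is rare, and it mirrors the
refractory behavior of interactive detectors. Candidates with fitted
amplitude in (0, 10] pA are discarded — the gate is strict, a 10.0 pA
event does not survive. Analysis is restricted to a 60 s window
(configurable offset). Per-event kinetics: 10–90 % rise time interpolated
on the rising phase; decay τ from a log-linear fit from the peak to 10 %
of peak. Frequency is events / window; group vectors of per-cell values
feed the CV test.

*Equality of coefficients of variation* (asymptotic, Feltz–Miller): with
c_i = s_i/x̄_i, m_i = n_i − 1 and pooled c = Σm_i c_i / Σm_i,

    D = Σ m_i (c_i − c)² / (c² (0.5 + c²))  ~  χ²(k−1) under H0.

D is scale-invariant, non-negative, zero when all CVs coincide; each group
needs n ≥ 2 and a nonzero mean. Its empirical size at α = 0.05 under a
normal equal-CV null (3 groups of 30) is checked by simulation in the
acceptance suite.

## The synthetic generator

The generator emulates the statistical structure the analyses assume while
keeping every truth exactly bookkeepable; identical spec + seed gives
bit-identical output (one `numpy` Generator per field, fixed draw order).

* **Inclusion fields** (default 256×256 px, 0.3 µm/px, background 100,
  read-noise SD 10): the cellular marker is one connected confluent sheet
  (centered ellipse, or rectangle at high coverage) occupying
  `roi_fraction` (default 0.5) of the field — real astrocyte cultures are
  confluent, and deposits above 2000 px could not fit inside an isolated
  cell at realistic cell sizes. Live nuclei (disks, r = 7 px, intensity
  150, centers ≥ 30 px apart) sit inside the sheet; condensed nuclei
  (r = 4 px, intensity 320) are placed 13–14 px from a designated host
  nucleus, guaranteeing the host is the nearest live nucleus so the
  Voronoi assignment is unambiguous. Deposits are filled ellipses of
  uniform integer intensity (uniform over 300–800), drawn per class with
  target areas safely inside the class bounds, placed largest-first by
  rejection sampling fully inside the sheet with pairwise Chebyshev
  separation ≥ 3 px (so 8-connected labeling cannot merge them); a field
  that cannot host its spec raises a "too crowded" error rather than
  degrading. Default load: 8 small + 4 medium + 1 large deposit, 12 live
  and 4 condensed nuclei per field. The ledger stores every particle's
  pixel set and intensity, every nucleus's state and host, plus the sheet
  and the Voronoi territory raster.
* **Branch fields**: cells are caterpillar trees — a horizontal backbone
  stroke with perpendicular side branches attached at well-separated
  (≥ 11 px) points on alternating sides — rasterized at stroke widths
  1–5 px on a grid of 120 px boxes, one nucleus per backbone. Each
  attachment is a single degree-3 junction, so the requested branch count
  is the true topological one. The geometry is deliberately clean
  (90° attachments, separated junctions): it verifies the measurement
  chain, not the robustness of skeletonization to entangled real
  morphology.
* **Traces** (default 62 s at 5 kHz, Gaussian noise 2 pA): baseline plus
  linearly superposed difference-of-exponential events at explicit or
  Poisson times, amplitudes 12–40 pA by default; ledger times are aligned
  to the sample grid.

What passing the synthetic benchmarks shows: the measurement chains are
internally correct — counting, classification, integration, topology,
statistics recover a known truth exactly (or within the stated noise
bounds). What they do not show: performance on real micrographs with
uneven illumination, out-of-focus light, textured cytoplasm, overlapping
deposits, or on recordings with drifting baselines and correlated noise —
real use requires per-dataset calibration of thresholds and of the
condensed-nucleus criterion.

## Numerical and design choices

* Deposit intensities and the classifier thresholds are integers/halfway
  points so the 16-bit rounding step is exactly neutral on clean renders.
* `subtract_background` rejects a ball radius exceeding the smaller image
  dimension; thresholds must be finite; `SizeClassCutoffs` enforces
  contiguous, non-overlapping, exhaustive classes.
* Problem sizes in the test and acceptance suites (50 fields per
  inclusion condition, 100 tree cells, 200 oracle masks, 50 traces, 1000
  CV-null simulations) were chosen to exercise each property at
  comfortable statistical resolution while keeping a full run around a
  minute on one core.
* Event matching in the acceptance suite uses a ±1 ms tolerance: the
  discrete template-fit argmax occasionally lands 2 samples (0.4 ms) from
  the true onset for the smallest gated amplitudes, which is irrelevant at
  EPSC timescales.
* Known limitations: no 3-D morphometry (z is projected); no deposit
  tracking over time; the condensed-nucleus criterion and astrocyte
  territory assignment are proxies for human judgment; merged events
  within the detector's merge window are counted once.
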