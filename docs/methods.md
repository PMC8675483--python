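# Methods

## Problem and model

Differentiating myoblasts fuse into multinucleated myotubes. Two scalar
readouts summarise a culture imaged with a nuclear stain (DAPI) and a
differentiation marker (myosin heavy chain, MYH):

- **nuclei density** — total nuclei divided by the imaged area in mm²; a
  proxy for viability/growth;
- **fusion index** — the percentage of nuclei residing in MYH-positive cells
  with at least three nuclei. MYH-positive cells with one or two nuclei are
  *not* myotubes under the strict differentiation criterion, so their nuclei
  are subtracted alongside the nuclei outside MYH-positive cells:
  `(total − outside − small) / total × 100`.

Counting is the hard part: nuclei touch and clump as fusion proceeds. Two
mechanisms resolve this. Touching nuclei with distinguishable bodies are
separated by a distance-transform watershed. Merged blobs beyond the
singleton size range (> 250 µm²) are treated as clumps and assigned
`area / modal singleton area` nuclei each — under the assumption that the
area of a k-nucleus clump is close to k times the typical nucleus area.

## Pipelines

Nuclei counting on the DAPI channel, in order: saturating multiplication →
automatic threshold → radius-1 binary median filter → hole filling →
watershed split → particle measurement → size binning → modal area → clump
division → total and density. The fusion pipeline additionally builds the
myotube mask on the MYH channel (multiplication → Gaussian blur σ = 2 px →
threshold on the *blurred* image's own histogram → median filter → hole
fill), removes masked pixels from the watershed label map, re-labels the
remainder (watershed divisions are preserved: adjacent pixels from different
parent labels stay separate), and counts the outside nuclei with the same
two-bin scheme.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `multiply_dapi`, `multiply_myh` | 1 | saturating brightness factor (≥ 1); raise for dim acquisitions |
| `median_radius_px` | 1 | binary median (majority) window radius; radius 1 = full 3×3 |
| `gaussian_sigma_px` | 2 | MYH smoothing before thresholding |
| `singles_min_um2` | 50 | below: debris, ignored |
| `singles_max_um2` | 250 | above: nuclear clump |
| `clump_rounding` | nearest | per-clump `max(1, round(q))`; `floor` and `fractional` (round the summed quotients once) are available |

The MYH channel should be at least as bright as the DAPI channel after
multiplication, or nuclei at myotube borders may survive subtraction; the
library logs a warning (not an error) when the multiplied channel means
violate this.

## Numerical choices

- **Threshold.** The automatic threshold is the iterative-intermeans
  (IsoData-variant) fixed point `t = (mean(≤t) + mean(>t)) / 2` computed on a
  256-bin histogram spanning the image's own intensity range, starting from
  the mid-range bin; the mask is strictly `img > t` so background exactly at
  the threshold stays out. A constant image raises a degenerate-histogram
  error; the top-level counters catch it and report an empty field with a
  warning.
- **Connectivity.** Foreground components are 8-connected; background (and
  hence holes) 4-connected — the standard complementary pairing.
- **Median filter.** Boolean median = majority vote; the odd window size
  makes ties impossible. Borders are edge-replicated.
- **Watershed.** Euclidean distance transform, smoothed with a σ = 1 px
  Gaussian; maxima suppressed at h = 1 px of distance seed a marker-based
  watershed restricted to the mask. Divide pixels join an adjacent region
  (no pixel is dropped), and components too thin to seed a maximum are kept
  as their own labels, so the label count never falls below the
  connected-component count.
- **Multiplication** rounds half away from zero before clipping, matching
  integer-image semantics.
- **Size bins.** The conventional bin labels leave a nominal gap between
  250 µm² and 251 µm²; areas are continuous here, so the partition is at
  `area > 250` — no particle can vanish between bins.
- **Mode.** The modal area of continuous measurements is ill-defined, so
  areas are binned at 1 µm² (bin k covers [k−0.5, k+0.5)) and ties break
  toward the smallest bin.
- **Clump quotient.** Round-half-up with a floor of one nucleus per clump;
  exposed as a parameter because the division can also be left fractional.
- **Outside-image mode.** The outside count uses the outside image's own
  modal singleton area. If the outside image has clumps but no singletons,
  the whole-image mode is used with a warning; if there are no singletons
  anywhere, the clump count is undefined and an error is raised.
- **Calibration.** Areas are `pixel count × (µm/px)²`; pixel sizes are taken
  from TIFF resolution metadata or given explicitly, never assumed;
  anisotropic calibrations are rejected because the area formula assumes
  isotropy.
- **Small-cell nuclei.** The count of nuclei in 1–2-nucleus MYH-positive
  cells is a user input by default. The optional estimator assigns each
  nucleus to the 8-connected MYH component containing its centroid and sums
  the nuclei of components holding one or two — adequate on well-separated
  scenes, but a centroid-in-mask rule, so nuclei straddling a component
  border may be misattributed on crowded real images.

## Synthetic scenes

The generator renders calibrated uint8 scenes (default 1024×1024 px at
0.8 µm/px, background 20, nuclei 200, MYH 230 — nucleus signal ~10× the
background, and MYH at least as bright as DAPI so the default multiplication
of 1 applies) with exact ground truth:

- **single nuclei**: ellipses with areas uniform in 50–250 µm² (default
  120–200), aspect ratio 1–1.8, random orientation, placed by rejection
  sampling with a ≥ 3 px background gap between structures;
- **clumps**: rosettes of k mutually-overlapping disks whose union area is
  iteratively tuned to k × the modal singleton area, so modal-area division
  is a sharp test (the estimate must hit k exactly on clean scenes);
- **myotubes**: capsules (segments with rounded caps) enclosing m ≥ 3 nuclei
  in single file with a ≥ 4 px interior margin; 1–2-nucleus MYH-positive
  cells use the same geometry;
- optional additive Gaussian noise, clipped to [0, 255].

Identical spec + seed reproduce scenes bit-for-bit. Not emulated: the
optical point-spread function, uneven illumination, intensity gradients,
stitching seams, chromatic offsets, and out-of-focus nuclei of real confocal
montages. Passing recovery tests on these scenes therefore demonstrates the
correctness of the segmentation/counting logic under the model's own
assumptions, not performance on arbitrary real micrographs — on real data
the brightness standardisation and multiplication factors remain the
researcher's responsibility.

## Verification sizes

The test suite and acceptance script run entirely on generated scenes:
100 random 64×64 label maps against a per-pixel measurement oracle; a
200-nucleus recovery scene (clean and with noise at 5% of nucleus
intensity); a clump scene with 100 modal singles plus 20 four-nucleus
clumps; 100 random mask pairs against the AND-NOT subtraction oracle; nine
1024×1024 fusion scenes with true indices spaced 10–90% (totals 80–160)
for the computed-vs-truth Pearson correlations; 50 random bimodal images
for the threshold fixed point; and two repeated seeded runs for byte-level
CSV determinism. These sizes keep a full verification run around ten
seconds while leaving each check sharp (exact recovery is required on the
clean scenes).

## Known limitations

- Clump resolution assumes clump area ≈ k × modal area; densely packed or
  unusually large/small nuclei bias the division.
- The watershed uses h = 1 px maxima suppression on the smoothed distance
  map; elongated nuclei beyond ~2:1 aspect or deeply overlapped pairs can
  over- or under-split.
- Nuclei straddling a myotube border are cut by the subtraction; fragments
  below 50 µm² fall into debris and are counted neither outside nor inside.
  This is a deliberate consequence of the two-bin rule, slightly favouring
  the inside (fused) interpretation for borderline nuclei.
- Only the first plane per channel of a TIFF is used; z-stacks and time
  series are out of scope, as is vendor-specific (e.g. LSM) metadata beyond
  what generic TIFF readers expose.
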