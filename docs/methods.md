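# Methods

This note documents the models and procedures behind each pipeline, the
parameters that matter, what the synthetic fixtures do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Raster primitives (`motilityq.imcore`)

All pipelines are assembled from a small set of primitives that mirror the
behaviour of the interactive tools this workflow historically used. Fixing
their conventions is essential: several downstream numbers depend on them.

* **8-bit conversion** is a linear min–max rescale to integer levels
  0–255 with half-up rounding; a constant image maps to all zeros. The
  operation is idempotent (its output always spans the full range), which
  is what makes "threshold the 8-bit image" well defined.
* **Edge magnitude** is the unnormalised 3×3 Sobel magnitude
  √(Gx²+Gy²) with replicated borders. This is the documented behaviour of
  the classic "find edges" command, and the wound segmentation depends on
  it, so it is fixed rather than configurable.
* **Gaussian blur** uses the separable truncated (4σ) discrete Gaussian
  with replicated borders. The wound pipeline's default σ = 5 px follows
  the interactive tool's labelling of σ as "radius".
* **Automatic thresholds** always operate on the 256-bin histogram of the
  min–max-rescaled image. Three methods are implemented from their
  published criteria: *Minimum* (iterated 3-bin moving-average smoothing
  until exactly two local maxima remain — capped at 10 000 passes, after
  which a no-threshold error is raised rather than a guess — returning the
  minimum between the two modes), *Yen* (maximum entropic-correlation
  criterion, computed with direct per-candidate class sums because a
  reversed cumulative sum cancels catastrophically in near-degenerate
  tails), and *Triangle* (the bin maximising perpendicular distance to the
  chord from the histogram peak to the end of its longer tail). Otsu,
  isodata, Li and mean are available through scikit-image for the
  choose-your-threshold workflow. Returned levels are clamped so both
  classes are non-empty for any non-constant image.
* **Disk opening** is exact Euclidean-disk morphology computed via
  distance transforms (erode: keep pixels with no background within radius
  r; dilate: the dual). Pixels outside the image count as foreground
  (replicate convention), so a full mask is a fixed point. This removes
  every component that cannot contain a disk of radius r, and is provably
  identical to brute-force disk opening — the test suite asserts this.
* **Binary polish** steps (erode/dilate/fill-holes) use a 3×3 square
  element per application; hole filling treats the background as
  4-connected. Component labeling is 8-connected throughout.
* **Rolling-ball background subtraction** estimates the background as the
  grayscale opening of the image with a non-flat ball-shaped structuring
  element (height √(r²−d²) over a disk footprint) and subtracts it,
  clipping at zero. Bright features narrower than the ball survive with
  their amplitude; a constant image maps to zeros.
* **Maxima detection** returns every local maximum whose *prominence* —
  the drop from its height to the highest saddle connecting it to higher
  (or dominating equal-height) terrain — reaches the noise tolerance. The
  implementation floods intensity levels in descending order with a
  union-find over per-level connected components; a plateau reports one
  peak at its centroid, ties between equal-height peaks resolve toward the
  smaller (row, col) centroid, and the dominant maximum takes its height
  above the image minimum. The test suite checks exact agreement (count,
  coordinates, prominences) with an independent level-set enumeration on
  random rasters. Edge-touching maxima are kept by default, matching the
  interactive tool's default.
* **Watershed splitting** floods the negated Euclidean distance map from
  markers at its prominence maxima. The distance map is quantised to
  half-pixel levels and maxima shallower than 0.5 px are merged into their
  neighbours, which suppresses splits caused by boundary raggedness while
  still separating genuinely overlapping blobs (two radius-10 disks with
  centres 15 px apart have a saddle prominence of ≈3.4 px and split
  correctly). Disconnected input components are never merged.
* **Particle analysis** reports exact pixel areas (and μm² through the
  pixel size) and coordinate-mean centroids per label, with a minimum-area
  filter.

Coordinates are 0-based (row, col) with row increasing downward, in every
public output.

## Wound healing (`motilityq.wound`)

The wound is segmented as the *low-gradient* class of each frame: a
confluent monolayer is texture-rich while the cell-free gap is smooth, so
the chain edge-magnitude → Gaussian blur (σ = 5 px) → 8-bit → Minimum
threshold → keep-below → disk opening (radius 20 px) isolates the gap. The
opening radius is the macro-argument default and configurable; gaps
narrower than twice the radius are below the method's resolution and
vanish. Two guards reject degenerate segmentations of frames without a
detectable gap (e.g. after full closure): the kept class must average
below a quarter of the rescaled gradient scale (a real gap sits near
zero; on an all-texture frame the Minimum method's bimodality is a noise
fluke inside the texture mode), and it must cover at most 90% of the frame
(a gap cannot fill the whole field). Frames failing segmentation are
recorded as missing with a warning, never as silent zeros, and slope
computations bridge them using actual elapsed time.

Healing speed negates the per-interval slopes so a closing wound reads
positive; a widening wound yields a negative average rather than an error.
When the frame interval is constant, the average equals
(A_first − A_last)/elapsed exactly (telescoping). Wound width at a sampled
row is the longest contiguous run of wound pixels crossing it — robust to
stray holes — measured by default at 3 evenly spaced rows for a vertical
wound (orientation is a flag; auto-detection is out of scope), with the
sample (n−1) SD in the CV. Front distances for the front-velocity formula
are user-measured inputs; deriving them as half the mean wound width is
offered as a clearly flagged convenience for symmetric wounds.

## Tracking (`motilityq.tracks`)

Track tables in the manual-tracking export dialect (track number, slice,
x, y; whitespace- or tab-separated) are parsed into pixel-unit track sets
and calibrated once — a second calibration raises, because silently
re-scaling distances is the classic error in this workflow. Velocity is
accumulated distance over elapsed time, which equals the mean of per-step
velocities at constant sampling. The FMI is computed per track as net
axis displacement over accumulated path length and then averaged across
the cohort; whether tools of this family average per track or pool
displacements cohort-wide is not universally documented, so users
comparing against other software should check this convention. Gaps in a
track contribute one straight step over the actual elapsed frames — no
interpolation. A stationary track (zero accumulated distance) takes
directionality and FMI 0 and is flagged. Rose-diagram angles flip the
screen y-axis so diagrams read in standard mathematical orientation, with
half-open bins (a boundary angle belongs to the higher bin); raw metrics
are orientation-agnostic.

## Transwell counting (`motilityq.transwell`)

Nuclei are maxima with prominence at or above the noise tolerance. The
default tolerance is 5× a robust noise SD estimated from the image's
median absolute deviation (1.4826·MAD), always overridable — there is no
universal default because it depends on camera gain and staining. The
migrated/invaded percentage pools counts across an insert's fields
(Σ migrated / Σ total), appropriate when the fields tile the membrane; a
per-field averaging mode covers the random-fields sampling design. A
migrated count exceeding the total is flagged inconsistent, never clipped.
Invasion versus migration (Matrigel or not) is metadata only. Manual
click-coordinate tables can be imported in place of automatic counts.

## Spreading classification (`motilityq.spreading`)

Both branches start from the same 8-bit, rolling-ball
(radius 10 px) background-subtracted image. The unspread branch keeps the
brightest class of the Yen threshold (round refringent cells are the
brightest structures after background subtraction), polishes with erode →
dilate → fill-holes, splits touching cells by watershed and counts
particles of at least 100 px² — the floor that discards thresholding
debris. The total branch highlights all cell outlines with the edge
magnitude, keeps the high-gradient class of the less restrictive Triangle
threshold, fills outlines into solid cells (fill-holes first), then
polishes, splits and counts identically. The interactive workflow's
display-polarity inversions are absorbed into these explicit keep-class
choices. One erode and one dilate per branch is the default (exact counts
are configurable), cells touching the border are counted, and the printed
order — watershed, then the size filter — is followed (the order matters
for merged pairs).

## Synthetic fixtures (`motilityq.synth`)

All generators are pure functions of (parameters, seed); ground truth
depends only on geometry parameters, never on the noise realisation — with
one deliberate exception, the track ledger, which is realisation-exact.

* **Wound stacks** (default 512×512 px at 1 μm/px, 10 frames every 2 h,
  300 μm initial gap closing at 8 μm/h — i.e. 4 096 μm²/h over the field,
  a desk-scale stand-in for a 20 h acquisition) render the monolayer as
  clipped Gaussian speckle (mean 100, SD 40, smoothed at 1 px) and the gap
  as the same mean with SD 1, so the two regions differ in gradient by far
  more than the 5× the segmentation tolerance assumes, while presenting no
  mean-intensity step at the boundary. Per-row integer gap widths are
  jittered (zero-mean, ~8-row correlation) and adjusted so their sum equals
  round(H·width) exactly — the analytic truth is therefore seed-free. The
  insert preset uses 3 μm edge jitter, the scratch preset 12 μm, encoding
  the straight-versus-ragged difference between the two wounding methods;
  the measured width CVs (≈1.3% vs ≈5%) are within-image raggedness, not
  the between-replicate variation a bench comparison reports, so only the
  ordering is meaningful.
* **Nuclei fields** (default 200 spots of amplitude 100 and σ 3 px on
  background 20 with noise SD 10 — SNR 10 — at pairwise separation
  ≥ 20 px ≈ 6σ in 512×512) are placed by rejection sampling with an
  attempt cap and rounded to integer intensity levels.
* **Spreading scenes** (default 30 unspread + 50 spread in 768×768, i.e.
  ≥ 600 cells over ten seeds) draw unspread cells as uniform bright disks
  (radius 9 px, level 235) and spread cells as larger dark textured disks
  (radius 18 px, mean 75, texture SD 15) with a thin bright rim (2 px,
  level 150) on background 120 — the rim thin enough that a single erosion
  destroys its thresholded ring, as the polish step is meant to.
* **Tracks** (default 300 walks of 60 steps every 20 min, drift 1 μm/step
  along x, step SD 4 μm — giving cohort velocities around 15 μm/h and
  accumulated distances around 300 μm, the scale of motile tumour cells)
  are biased random walks; the pilot-simulation truth for the cohort mean
  FMI is estimated from 10⁵ vectorised walks.

What passing tests on these fixtures shows — and does not. They verify the
arithmetic, the segmentation logic, determinism, and parameter recovery
under the stated noise models. They do not model uneven illumination,
debris, cell division, focus drift, halo artefacts of phase contrast, or
persistent (autocorrelated) motility, so performance on real microscopy
still depends on acquisition quality and on choosing the threshold method
and noise tolerance per dataset — the reason those are exposed as
parameters.

## Numerical choices and degenerate inputs

* Sample (n−1) SD everywhere a spread across replicates is reported; an
  n = 1 cohort reports SD 0 with a flag rather than erroring.
* Constant images: no-threshold error (thresholds), empty peak list
  (maxima), all-zero output (8-bit conversion, rolling ball).
* Ties: equal-height maxima resolve toward the smaller (row, col)
  centroid; equal threshold criteria take the first (lowest) level;
  boundary rose angles go to the higher bin.
* All randomness flows from explicit integer seeds; result tables carry no
  timestamps, so identical inputs and configuration reproduce output files
  byte for byte.

## Known limitations

* No drift correction, illumination flattening, or fluorescence-specific
  wound segmentation; inputs are grayscale TIFF/PNG only (convert
  proprietary formats first).
* Wound orientation must be stated (vertical by default); gaps narrower
  than twice the opening radius are unresolvable by design.
* Tracking itself (detection and linking) stays manual or external; the
  package analyses exported track tables.
* The watershed merge tolerance trades under- for over-segmentation at
  0.5 px; heavily textured masks may still occasionally split.
* Sub-pixel area measurement is out of scope: areas are pixel counts
  scaled by the calibration.
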