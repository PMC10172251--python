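# Methods

This note documents the models, estimators and design choices behind
`ciliapol`, and what the synthetic-data tests do and do not demonstrate
about real microscopy data.

## Coordinate and angle conventions

All geometry lives in the image frame: origin top-left, x right, y down,
units of pixels.  Angles are `atan2(dy, dx)` in degrees, wrapped to
[−180, 180) with the boundary convention +180 → −180.  Whether an angle
reads clockwise or counterclockwise on screen is a display concern; every
statistic in the package is a *relative* angle (cell vs field mean, cell vs
cell), so the frame choice cancels.  Computations run in pixels; lengths
and areas convert to µm/µm² only at reporting time, via the field's
`pixel_size_um` (default 0.09 µm, i.e. a 90-nm acquisition pixel).

Polygon area and centroid are the shoelace (area-weighted) definitions,
computed through shapely.  The centroid choice matters for concave traced
contours, where the vertex average can fall well off the region's center of
mass.

## Per-cell polarity

For each cell: the displacement vector runs from the cell-contour centroid
to the patch-contour centroid.  A cell with no patch contour but exactly
one cilium is handled in *primary-cilium mode* (the basal-body point stands
in for the patch center; rotational metrics undefined) so neonate-stage
tissue with single primary cilia uses the same code path.

*Strength* is displacement length divided by the equivalent cell radius
√(area/π).  It is dimensionless and cell-size-normalized, so large cells do
not read as "more polarized" merely by being large.

Rotational metrics require at least `min_cilia = 3` usable cilia (a
circular SD of one or two angles is uninformative); below that the CSD is
*undefined*, never 0.  Cilia whose two marker points coincide are skipped
with a warning.  A cell whose cilium angles have zero resultant (perfectly
balanced directions) gets the `inf` CSD sentinel: it carries no directional
information, is excluded from every mean-orientation computation, and falls
into the overflow bin of the CSD histogram (ten bins of 10° from 0 to 100
plus overflow).

The validity rule for mean beating orientation is CSD ≤ 45° (configurable
`csd_threshold_deg`).  Cells failing it contribute no VpatchO and no
VpatchD&O — which is why the group comparisons report different n per
metric rather than a single sample size.

## Field-level angles and group inference

Field mean directions are *unit-weighted* circular means of per-cell
angles, not magnitude-weighted vector sums: polarity coordination is a
statement about directions, and magnitude weighting would let large
displacements or large cells dominate the reference direction.

VpatchD&O is computed per cell as displacement angle minus mean
orientation.  An alternative reading — difference of the two
field-referenced angles — differs from this by a common rotation of the
whole sample, which the Watson U² statistic ignores (property-tested), so
the choice does not affect inference.

Watson's two-sample U² is computed from the pooled ECDF difference
d_k = F₁ − F₂ evaluated *after consuming all observations tied at a
value*, each pooled observation contributing its shared d once:
U² = (n₁n₂/N²)·[Σd² − (Σd)²/N].  The tie rule makes identical samples give
exactly U² = 0, the only defensible degenerate behavior.  p-values come
from seeded permutation of the pooled sample,
p = (1 + #{U²* ≥ U²}) / (1 + B); this is exact-level at any sample size
and reproducible, at the cost of a discrete p-value lattice (granularity
1/(B+1)).  No asymptotic tables are used.  Linear quantities (CSD,
strength, areas, cilia counts) use the classical pooled-variance two-tailed
t test; CSD-infinite cells are excluded from the t test and their counts
reported.

## Ciliary beat frequency

Stack preprocessing, in fixed order: (1) background = per-pixel temporal
minimum, subtracted; (2) bleach correction = divide each frame by a
mono-exponential fit A·e^(−t/τ) + B to the frame-mean intensity,
renormalized to the first frame (the offset term is needed because the
minimum-projection subtraction leaves frame means as "exponential plus
constant"; the correction ratio is clamped at 0.05 so a fit decaying to
zero cannot blow up the tail); (3) 3×3 spatial mean smoothing.  Frame means
that do not decay (judged on first/last decile means, robust to
oscillation) skip the correction with a warning.

Kymograms sample the stack by bilinear interpolation at unit-spaced
positions along a polyline; the trace is the per-frame mean over positions
(a single-row option exists for lines that cross opposing-phase cilia,
where the mean cancels).

Bare traces that never went through stack preprocessing get
`preprocess_trace`: the same mono-exponential fit, but *subtracted* rather
than divided out.  Division would amplify late-trace noise by up to
e^(T/τ) (17× at τ = 10 s over 600 frames at 21 fps), inflating the robust
peak threshold; subtraction removes the trend — whose Lorentzian spectral
tail otherwise leaks past the low-frequency exclusion band — without
touching the noise floor.

The estimator mean-subtracts, applies no window (rectangular; at 600
samples with well-separated peaks, leakage is tolerable, and a Hann window
is available as an option), and searches the magnitude spectrum in
(0.5 Hz, fs/2].  The global in-band maximum is accepted as the beat
frequency iff its magnitude exceeds median + k·(1.4826·MAD) of the in-band
magnitudes, k = 6 by default.  Calibration of k: the in-band magnitudes of
white noise are Rayleigh; with the MAD scaled to a robust sigma, k = 6 puts
the threshold ≈ 5.2 Rayleigh scale units, so the probability that the
maximum of the ≈270 noise bins of a 600-frame band crosses it is below
0.1%, while a sinusoidal peak at SNR ≥ 1 clears it by an order of
magnitude.  Flat or noise-only traces therefore report `valid = False`
rather than a spurious frequency.  Frequencies above Nyquist fold back
(a 12-Hz beat sampled at 21 fps reports at 9 Hz); the estimator cannot
detect aliasing, it can only document it.

## Synthetic generators

The tissue generator emulates the *statistical* structure of a polarized
epithelium, not its optics.  Cell contours come from a bounded Voronoi
tessellation of Lloyd-relaxed (2 iterations) uniform seeds, clipped to the
field by mirror points.  Angular noise is von Mises throughout — the
maximum-entropy circular analogue of the Gaussian, with the closed form
CSD(κ) = (180/π)·√(−2 ln(I₁(κ)/I₀(κ))) that the tests use as an
independent oracle.  The hierarchy has two levels: per-cell displacement
and orientation directions are von Mises about the tissue direction μ with
concentrations κ_D and κ_O, and per-cilium angles are von Mises about the
cell's orientation with κ_cil, so translational and rotational polarity are
independently controllable.  Defaults per field: 50 cells, displacement
0.3 of the equivalent cell radius, patch radius 0.35 of it, 15–40 cilia
per cell, marker-pair separation 0.5 µm.  Presets: control
κ_D = κ_O = 6, κ_cil = 8 (per-cell CSD ≈ 21°, most cells under the 45°
threshold); mutant κ_D = κ_O = 1, κ_cil = 2 (CSD ≈ 49°, most cells over
it) — chosen to reproduce, at desk scale, the qualitative contrast between
a coordinated and a polarity-impaired tissue.  Study-level generation uses
5 fields per group by default with per-field seeds derived from the study
seed.

The video generator renders each cilium as a Gaussian spot (σ = 2 px)
whose center oscillates along a 3-px arc at its true frequency, plus
mono-exponential bleaching and Gaussian noise; the per-cilium polyline
crosses the *end* of the arc perpendicular to the motion, so the spot
sweeps past the line once per cycle and the line-averaged intensity
oscillates at the fundamental (a line through the arc center would see two
passes per cycle and emphasize the second harmonic).  Trace-level
generation uses (baseline + A·sin(2πft + φ))·e^(−t/τ) + noise with
baseline 100, A = 10, noise SD 2 (SNR 5), τ = 20 s, 600 frames at
21 frames/s — the acquisition geometry of the study design this package
serves.

What the generators do **not** emulate: realistic point-spread functions,
camera shot noise and gain, cilium-to-cilium optical overlap, motion of the
tissue, segmentation/tracing error in the contours, and any spatial
correlation of polarity beyond the shared tissue direction.  Passing
recovery tests therefore demonstrates correctness of the *estimators* under
the stated noise model, not robustness to every artifact of real imaging.

## Problem sizes in the test suite

The statistical tests run at sizes chosen to make their assertions sharp
but cheap: CSD oracle checks at n = 5000 angles; Watson type-I calibration
over 1000 null pairs (n = m = 50, 199 permutations); study contrasts at 5
fields × 50 cells per group, with the 100-replicate null calibration at 199
permutations; CBF recovery over 100–500 traces of 600 frames.  These are
the package's reference problem sizes; all are parameters.

## Known limitations

* Permutation p-values have granularity 1/(B+1); with B = 999 the smallest
  reportable p is 0.001.  "p < 0.001"-level claims need more permutations.
* The CSD estimator is biased low at small within-cell cilia counts
  (relative bias ≈ (1−R²)/(2nR²·ln(1/R)) at n cilia); the tests allow for
  this at n = 30.
* The strength metric assumes roughly isotropic cells; for very elongated
  cells the equivalent-radius normalization under-states displacement
  along the short axis.
* Beat frequencies above fs/2 alias; at 21 fps anything above 10.5 Hz is
  reported folded.
* The bounded-Voronoi mirror construction guarantees cells tile the field
  but makes boundary cells slightly more regular than interior ones.
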