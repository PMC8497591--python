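# Methods

This note records the models behind `episcan`, the defaults and why they
were chosen, and the numerical decisions taken where the design was
genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope and model of the instrument

The package reproduces the *computational* side of an adaptive scanning
fluorescence microscope: everything from the fractional pre-scan to the
converged propagative scan is implemented against a `VoxelOracle` that
serves one intensity per integer voxel request.  Optics (point-spread
function, targeted illumination hardware, virtual pinholing, multi-focus
batching) are out of scope; the only optical ingredients kept are an
isotropic Gaussian softening of the bright structure in the phantom and
the column-wise bleaching model below.  Light dose is identified with
the number of *uniquely* scanned voxels (`DoseLedger`); repeat queries
are counted separately and do not increase the dose fraction.

## Phantom

A phantom is `s = a(x,y,z) · (1 + cv·g + A·B)` with

- `a` a strictly positive low-order polynomial background (order ≤ 2 per
  axis) describing excitation/detection inhomogeneity;
- `g` i.i.d. standard normal noise, *multiplicative* relative to `a` so
  that the spread of `s/a − 1` is spatially constant — exactly the
  assumption under which a scalar σ̂ makes the normalized signal
  N(0, 1) on background;
- `B` the bright structure: a Voronoi-like cell mesh (cell centres from
  a maximal Poisson-disc sample of radius `cell_diameter/2`, boundaries
  thickened to `contour_width`) extruded ±`structure_thickness`/2 in z
  around the surface `Z(x,y)`, softened by a Gaussian of sigma
  `contour_width/2` but held at exactly 1 on true bright voxels, plus an
  optional fraction of scattered off-surface outlier voxels;
- `A = contour_amplitude`, the junction brightness as a multiple of the
  local background.

Surface kinds: `flat`, `quadratic` (paraboloid whose stated z-bounds are
reached at the tissue corner, clipped beyond), `sinusoidal`, `step`
(two plateaus joined by a linear ramp of stated width — the
non-polynomial robustness case), and `double-surface` (a decoy sheet a
few µm above the primary one, with its contour randomly thinned to
~25%, emulating a less populated facing epithelium).  The tissue
occupies a centred rectangle with `tissue_xy_coverage` of the lateral
area; the surface and mesh exist only there.

Defaults are the study conditions of the imaging scenario emulated:
915×915×50 voxels at 0.27×0.27×0.5 µm, 2.5 µm cells (wing-disc-like;
25 µm for epidermis-like phantoms), tissue coverage 0.3, `cv = 0.1`,
`A = 2` (junctions ≈ 3× local background — the real contrast is not
documented, so this is a fixed, swept-in-tests choice), `contour_width
= 0.4 µm` (a PSF-limited junction width), `structure_thickness = 3 µm`.
Tests and the acceptance script use proportionally reduced grids
(384–640 px laterally, 20–50 planes) so the whole suite runs on a
desktop; the reduced fields keep ≥ 25 cells for the small-cell phantoms
and ≥ 40 cells for the large-cell ones.

What the generator does **not** emulate: Poisson shot noise and camera
read noise (the noise is purely the stated multiplicative Gaussian),
diffraction of the excitation pattern, scattering, or axially varying
PSFs.  Passing tests therefore demonstrate the *algorithmic* properties
(robust estimation, dose accounting, propagation behaviour), not
photometric realism.

### Bleaching

Out-of-focus excitation irradiates a whole column, so each query of any
voxel in a column counts one exposure for that column, and a voxel's
value decays as `(1 − bleach_rate)^exposures`.  Exposures accrue
batch-wise (one `read` call = one frame): all values within a frame see
the exposure counts at frame start.  In the hybrid half-full-scan /
half-shell-scan experiment this yields a per-frame decay ratio of
`(1 − b)^(nz − n_layers)` between the two halves, which the test suite
verifies against the measured curves.

## Pre-scan and normalization

`draw_prescan` realizes the fractional scan as uniform sampling without
replacement (`round(η·N)` distinct voxels); the physical lattice-batch
structure of a real instrument is irrelevant to the algorithms.
Defaults: η = 0.1%, raised to 0.2% for large-cell phantoms where bright
voxels are scarce.

The background model is a full quadratic polynomial in normalized
coordinates (10 coefficients), fitted by iteratively trimmed least
squares: 3 iterations, each dropping samples whose |relative residual −
median| exceeds its 90th percentile.  The trimming is deliberately
*symmetric about the median* rather than one-sided: one-sided trimming
of a symmetric noise population biases the fit low (the mean of a
normal truncated at its 90th percentile is ≈ −0.19σ), which would shift
the normalized background off zero and break the false-alarm
calibration.  σ̂ is `1.4826 · MAD(s/â − 1)` over **all** samples: the
MAD is already robust to the bright minority, and computing it on the
untrimmed set keeps it a consistent Gaussian spread estimate (the MAD
of a trimmed set estimates a lower quantile, ≈ −11% at 27% trimming).
With a non-negligible bright fraction σ̂ is a few percent conservative,
which only makes detection slightly stricter.  This recipe is a
documented substitute for an unpublished estimation procedure; it uses
only Ω₀, survives a bright tail, and calibrates the test to its nominal
false-alarm rate (verified at 10⁶ samples).

Detection is the strict test r̂ > T with T the standard-normal
upper-tail quantile of the chosen pfa (1% throughout ⇒ T ≈ 2.33).

## Surface estimation

Windows: lateral squares of width ⅓ of the field with 50% overlap (a
5×5 grid on a square field), full coverage guaranteed.

**Robust local fits.**  Hypotheses are minimal 3-point *plane* samples;
the best few (5) by inlier count are refined into the full quadratic
`z = c0 + c1x + c2y + c3x² + c4xy + c5y²` by iterated least squares
with tolerance-annealed re-selection (schedule 1, 1, ½, ½, ¼ × the
1.5 µm inlier tolerance, floored at 2.5× the robust residual spread).
Two reasons for this departure from single-stage 6-point quadratic
sampling: (i) at the >⅔ outlier contamination the method must survive,
a clean 6-point sample has probability ~0.3⁶ ≈ 5·10⁻⁴ and no practical
trial count finds one reliably, while a clean 3-point sample is drawn
hundreds of times in 500 trials; (ii) the adaptive annealing floor lets
the final coefficients purge chance inliers when the true points are
tight, yet keeps the full (noisy) inlier population when residuals are
at the tolerance scale, so genuinely thick-structure points are
averaged, not subsampled.  The inlier tolerance defaults to ε/2 =
1.5 µm so that inliers are exactly shell-compatible points.  A window
returns no-fit below 6 points or when the consensus is under
6 + 10% of its points.

**Fusion.**  A bright point is retained iff it is an inlier of at least
one covering window fit; its denoised z is the tent-weighted (peak at
window centre, product over axes) average of the covering fits'
predictions — a smooth cross-window blend; the fusion rule itself is a
free design choice.  Retained points then pass a scatter filter (keep a
point iff ≥ 3 neighbours within 4× the median nearest-neighbour
distance): surviving false alarms are isolated on the field, genuine
surface points are dense, and without this step stray detections
balloon the interpolation support far beyond the tissue.

**Interpolation and support.**  A thin-plate (biharmonic Green's
function) spline interpolates the denoised points exactly; the surface
is evaluated only inside the convex hull of the points.  Outside the
hull the estimate is undefined and the shell empty — extrapolated
spline values are meaningless there and would only add dose over
tissue-free regions.

**Shell voxelization.**  The surface is snapped to its nearest plane
`z0 = rint(Ẑ/dz)`; the shell column is `|z − z0| ≤ floor(ε/(2dz))`,
clipped to the stack, i.e. `2·floor(ε/(2dz)) + 1` layers — 7 at the
ε = 3 µm, dz = 0.5 µm defaults.  In the degenerate ε = dz case this
convention yields a single layer (the nearest-plane layer); membership
is symmetric about the snapped surface by construction.  Columns whose
snapped surface falls outside the stack are dropped.

## Propagative scan

Iteration 0 is the pre-scan: its samples keep their normalized values,
but only those inside the shell ever serve as nearest-neighbour
candidates, and the per-column "best acquired" bookkeeping is likewise
shell-restricted.  Iteration 1 draws N₀ additional uniform in-shell
seeds (default: the pre-scan size — the value is free; seeding only
improves coverage of contours the pre-scan missed).  Normalization
parameters are frozen from the pre-scan and never refit.

Each later iteration: for every unexplored shell voxel, the prediction
is the normalized value of its nearest acquired neighbour *in the same
layer* by xy-Euclidean distance, ties resolved to the highest
normalized intensity, no prediction beyond β pixels.  Acquisitions are
the voxels with prediction > T, thinned to one per lateral column (the
highest prediction; ties to the lowest layer) and skipped entirely when
the column already holds an acquired shell voxel with normalized value
≥ that prediction (equality blocks: re-acquiring an equal value cannot
add information).  The scan stops at the first empty iteration (or a
safety cap of 100 iterations; convergence is the operative stop).

The grid implementation exploits the fact that within one layer each
lateral column holds exactly one voxel, so a layer is a 2D image and
the NN search is a fixed set of lattice shifts grouped by distance; it
is tested voxel-for-voxel against an exhaustive pairwise-distance
search.

## Evaluation

- *Bright-voxel capture*: % of ground-truth bright voxels inside the
  ground-truth shell that also fall in the estimated shell (per voxel).
- *Contour capture*: after maximum-intensity projection of normalized
  values over the shell, % of ground-truth-bright MIP pixels also
  bright in a strategy's MIP, both thresholded at the same T as
  detection (one threshold throughout).
- *Dose table*: per-strategy unique-voxel percentages, with the full
  scan (100%) and the tight bounding box (lateral tissue extents × the
  surface z-range padded by ε/2) as references.
- *Bleaching curves*: per-frame mean of the raw MIP over each half of
  the hybrid scan, relative to its first frame (initial-value-relative
  normalization).

Monotonicity suites (capture vs η, acquisitions and capture vs
β ∈ {1, 3, 5, 10}, per-iteration counts reaching zero) are asserted on
means over several seeded pre-scans; the test suite uses 4–6 seeds per
condition to stay fast, accepting that single-seed comparisons are
noisy.

## Known limitations

- Height-field surfaces only: closed or multi-valued surfaces cannot be
  represented as z = Ẑ(x, y).
- The scatter filter assumes the tissue projects to one dense region;
  pathological cases (many small islands) could lose support.
- The thin-plate solve is dense: ~10⁴ or more bright points per field
  would need a compactly supported kernel or subsampling.
- The false-alarm calibration assumes the background noise family of
  the generator (multiplicative Gaussian); heavy-tailed camera noise
  would make σ̂ conservative and the realized pfa lower than nominal.
- Manual early stopping of the propagative scan and adaptive-η
  pre-scans are not implemented (convergence and the iteration cap are
  the only stops).
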