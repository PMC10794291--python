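# Methods

## The local connected fractal surface dimension

The estimator treats a nonnegative single-channel image as a surface:
the intensity f(x, y) is a height above the image plane, and zero marks
background. For a nonzero pixel r the analysis is strictly local:

1. **Window.** Take the h × h patch centered on r, h = 2w + 1 (default
   w = 8, h = 17). Pixels within w of an image edge are never analyzed.
2. **Connectivity.** Keep only the 8-connected component of nonzero
   pixels that contains r, computed inside the patch. A pixel belongs to
   the component if a chain of horizontally, vertically or diagonally
   adjacent nonzero pixels joins it to r. Before any window is taken,
   8-connected clusters with fewer than `min_cluster_size` pixels
   (default 6, i.e. clusters of five or fewer) are erased from the image.
3. **Binning.** Heights on the component are rescaled by a normalization
   maximum ℱ and binned upward: f* = ⌈h·f/ℱ⌉, clamped to {1,…,h}. A
   nonzero pixel always occupies at least one voxel; the pixel attaining
   ℱ occupies the full column of h. ℱ is shared across all images of an
   experiment (`global_max_F`), or taken from the supplied image(s) when
   "auto"; an ℱ smaller than the data maximum is an error rather than a
   silent clip.
4. **Occupancy.** The window is now an h × h × h cube of voxels. For
   each odd box side L in the scale set S_L = {3, 5, …, h} the occupied
   voxel count of the L × L × L cube centered on r in-plane and resting
   on the base plane is N(L) = Σ min(f*, L) over the L × L subwindow.
5. **Slope.** The dimension at r is the ordinary least-squares slope of
   log N(L) versus log L over S_L. All eight scales always contribute
   (the center voxel guarantees N ≥ 1); exactly flat profiles give
   slope 0.

The default scale set includes L = 9: the set is "every odd size from 3
to h". The positive-slope convention is used throughout — occupancy
grows with box size — so a filled block scores 3, a unit-height sheet 2,
an isolated column 1. With the default 0.369 µm pixels the 17-pixel
window spans 6.3 µm, the physical scale of the analysis.

Two implementations of the per-pixel loop exist: a readable numpy/scipy
reference (`engine="numpy"`) and a numba kernel (`engine="numba"`,
default when numba is importable). They are compared on random images in
the test suite and agree exactly.

### Range of the estimate, and its heavy upper tail

For exact power-law profiles N(L) ∝ L^D the slope lies in [0, 3], and on
typical dense surfaces virtually all pixels do. The bound is **not** a
theorem about the OLS slope, however: a window whose occupancy profile
is convex in log-log — a sparse immediate neighborhood of the center
joined by an 8-connected path to dense, tall structure further out —
can exceed 3 (we observe values up to ≈3.7 on adversarial random
images, affecting ≈1% of pixels at intermediate sparsity). Dimensions
are therefore reported unclipped, with a warning when any pixel falls
outside [0, 3], so that downstream analyses see the estimator's true
behaviour. Anyone comparing dimension distributions between groups
should treat values above 3 as "locally non-power-law", not as noise to
be discarded silently.

### Dimension distributions

Valid-pixel dimensions are summarized by a Gaussian kernel density
(Silverman bandwidth by default, overridable) and a mode count: strict
local maxima of the evaluated density with prominence at least 1% of the
density maximum. Mode counting on subsampled data is bandwidth
sensitive — Silverman's rule smooths a ~6k-pixel sample noticeably more
than a ~47k-pixel one — so analyses that compare rasters of different
sizes should fix the bandwidth explicitly (the shuffle-control tests use
0.05, the Silverman value of the full 1386² Julia analysis).

## Julia-set test surfaces

Pixel centers are mapped linearly onto a rectangle of the complex plane
(row 0 at the top of the imaginary axis); each pixel's coordinate seeds
z₀ of the iteration z_{n+1} = z_n² + c with |c| ≤ 2. Pixels whose
modulus stays ≤ 2 through n_iter iterations are members; their final
|z| is the height surface. Non-members record the last iteration index
on which they were still inside. Because modulus 2 is absorbing for
|c| ≤ 2, membership can only shrink as n_iter grows.

The published exemplars are provided as presets: c = −0.5285−0.5285i
(97 iterations), c = i (15 iterations; the dendrite), and
c = −1.15+0.215i (96 iterations), at 1386 × 1386 pixels by default. The
negative control `shuffle_magnitudes` permutes member heights under an
explicit seed — globally by default, which preserves the member support
and the exact magnitude histogram while destroying all spatial
correlation of the surface; a per-tile variant is available for
localized controls.

**Critical-orbit periods.** The cycle reached from z₀ = 0 is detected on
the double-precision orbit after a burn-in of half the iteration budget,
as the smallest lag p with |z_{n+p} − z_n| ≤ tol over 3p consecutive
steps. The default tol = 0.0 detects the exact repeat length of the
machine orbit — the quantity an escape-time implementation in double
precision actually observes. The two are not always the same cycle
length in exact arithmetic: for c = −1.15+0.215i the attracting cycle
has period 42 (verified in 60-digit arithmetic), but rounding splits it
into four nearly identical copies so the machine orbit repeats exactly
at lag 168, while any tol ≳ 1e−13 reports 42. Both behaviours are
available through the tol parameter; the exact-repeat default matches
how these fixtures are characterized in practice.

## Picrosirius-red hue pipeline

Polarized-light PSR micrographs (1600 × 1200, 24-bit, 0.369 µm pixels in
the intended acquisition) are decomposed with the hexagonal hue
transform into 8-bit hue/saturation/intensity channels (hue 0 at red,
wrapping at 255; achromatic pixels get hue 0). A pixel is retained iff
saturation ≥ 143, intensity ≥ 16, and hue outside 129–229 (that band is
neither background nor collagen). Retained hues map to fiber-thickness
classes — red 0–9 ∪ 230–255 (thickest), orange 10–38, yellow 39–51,
green 52–128 (thinnest) — which tile the hue circle together with the
disregarded band.

**Hue → height.** The red band wraps around 255, so hues 230–255 are
unwrapped to −26…−1; the rank 128 − h' then increases monotonically with
fiber thickness (green ≈ 0…76, yellow 77…89, orange 90…118, red
119…154). All retained ranks are offset by +1 — otherwise the greenest
retained hue would collide with the background level 0 — and divided by
the experiment-wide maximum offset rank, so heights lie in (0, 1] and
the strongest red observed in the experiment maps to exactly 1. The
exact shift used in the original acquisition software is not
documented; this mapping is one explicit, monotone realization,
centralized in `normalize_hue_to_height`.

Collagen content is the classified-pixel count over the tissue area;
the default denominator is every pixel of the image, with an optional
binary tissue mask. Per-animal aggregation reports the arithmetic mean
and the sample (n−1) standard deviation; a single image yields SD 0
with an explicit `sd_defined=False` flag.

**Synthetic micrographs.** The fixture generator paints curvilinear
fiber strokes (seeded random walks, 1–2 px wide) in mid-band hues of the
four classes at full saturation/intensity over a dark background that
fails the intensity cut, tracking the final class of every pixel while
painting. The sidecar class counts are therefore exact ground truth for
the threshold + classification pipeline. The generator emulates only
the pipeline's bookkeeping — hue bands, thresholds, wraparound — not
optics: no birefringence physics, no sensor noise, no partial-volume
hues, no real fiber morphology. Passing its tests validates the
arithmetic of the pipeline, not its biological calibration.

## Multifractal spectra

Binary masks are analyzed with the direct (Chhabra–Jensen) estimator:
for box sides ε (powers of 2 from 2 to a quarter of the short image
side by default) the foreground-mass fractions P_i(ε) are computed on a
grid anchored at the foreground bounding box and shifted by an offset
chosen to minimize the number of empty boxes (origin plus 15 seeded
random shifts by default). For each moment order q (−5…5, step 0.25)
the normalized weights μ_i = P_i^q / Σ P_j^q give α(q) and f(q) as OLS
slopes of Σμ log P and Σμ log μ against log ε. Weights are computed in
log space, so extreme q are numerically safe.

**Scaling-quality filter.** On binary digitized images the smallest box
masses are floored at one pixel at every scale (boxes that merely graze
the object), which destroys the scaling of negative-q moments and can
collapse α(q<0) toward 0. The estimator therefore enforces the direct
method's own linearity requirement: moment orders whose α-regression has
R² below `r2_min` (default 0.90) are excluded from α_min, α_max, Δα and
α₀. The full α(q), f(q) curves and per-q R² are always reported, so the
filter is transparent and reversible (`r2_min=0` disables it). An
exactly uniform measure has perfect fits at every q and is unaffected:
its Δα is zero to floating-point precision.

Δα = α_max − α_min measures the degree of multifractality (0 for a
monofractal); the skewness A_α = (Δα_L − Δα_R)/(Δα_L + Δα_R), with
Δα_L = α₀ − α_min and Δα_R = α_max − α₀ and α₀ the α at the maximum of
f, is +1/−1 when the spectrum is entirely left/right of its apex and
near 0 when multifractality is scale-balanced.

**Reference objects.** The Hénon attractor ((x,y) → (1 − 1.4x² + y,
0.3x), 2·10⁵ iterates after a 100-step burn-in) is the multifractal
reference; a filled disk is the nonfractal one. Both are digitized on a
matched 256 × 256 raster (disk radius 120, nearly inscribed; attractor
over [−1.5, 1.5] × [−0.45, 0.45]) so the two are compared at the same
pixel scales. At this raster the attractor's strands merge into bands
of genuinely varying thickness and its filtered width (≈0.5–0.7)
exceeds the disk's (≈0.3–0.45) across grid-offset seeds. At much finer
rasters the binary attractor thins toward a homogeneous curve and the
contrast shrinks — a known property of box-counting on binary sets, and
the reason the controls default to a common raster.

## Problem sizes and determinism

Defaults were chosen so the full validation (including the 1386²
Julia-set analyses) runs in minutes on one core: the numba kernel
processes ≈10⁶ windows/s after a one-time compile. Every stochastic
step — grid offsets, magnitude shuffles, synthetic fixtures — takes an
explicit integer seed; there is no global random state, and identical
configurations produce byte-identical CSV/JSON outputs.

## Known limitations

- The dimension estimate's upper tail exceeds 3 on non-power-law
  windows (see above); the [0, 3] range is exact only for power-law
  occupancy profiles.
- The hue→height shift is one consistent realization of an
  under-documented mapping; absolute height values (not their ordering)
  depend on it.
- Negative-q multifractal quantities on binary images are meaningful
  only through the scaling-quality filter; reported Δα depends on the
  raster resolution of the object.
- The synthetic histology generator does not model optics or noise;
  agreement on it demonstrates bookkeeping correctness only.
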