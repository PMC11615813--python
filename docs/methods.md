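# Methods

## Imaging model and coordinate conventions

Reconstructed RSOM volumes are scalar absorption maps on a
20 × 20 × 4 µm³ grid. The package fixes the axis order `(x, y, z)`:
`x` is the lateral scan axis, `y` runs along the transrectal absorber
guide (TAG) and hence along the colon, `z` is depth. On disk a volume is
a multi-page grayscale TIFF with one depth slice per page. All
intensities are processed in floating point; the two histogram
thresholds quantize to 256 bins internally, mirroring 8-bit practice.

## Preprocessing

* **3D Gaussian** (default σ = (20, 20, 8) µm, i.e. (1, 1, 2) voxels):
  suppresses voxel noise without erasing 40 µm vessels. No σ is
  prescribed by the workflow the package follows, so the value is a
  documented default and configurable.
* **Rolling ball**, applied slice-wise to x–y planes along depth
  (reflection artifacts are depth-periodic, so background varies chiefly
  with z). The background is the grayscale opening of each slice with a
  non-flat ball structuring element. Ball and paraboloid radii default
  to 1000 µm (50 px), the conventional default for this image size.
  Intensity-to-height scaling follows the 8-bit convention (image span
  mapped to 0–255; one intensity unit = one pixel of ball height);
  `intensity_scale` overrides it. For radii above 10 px the standard
  shrink speed-up is used: block-minimum downsampling (factor 2–8 chosen
  from the radius), opening with the scaled ball, bilinear upsampling,
  then clipping the background below the data. The exact opening is
  available with `downscale=1`.
* **Sliding paraboloid** for the 2D projection. The background is the
  fixpoint of 1-D parabolic openings (lower envelopes, computed with the
  linear-time envelope algorithm) along rows, columns and both diagonal
  families, iterated to convergence (tolerance 10⁻⁹ of the span, at most
  6 sweeps). The parabola's apex curvature matches a ball of the given
  radius; diagonal passes halve the curvature coefficient to account for
  the √2 step length. Each line is detrended by its secant and
  edge-extended with constant values before the envelope — this lets a
  tilted background pass through exactly and prevents the parabola from
  sinking over the image edge — and the resulting background is clamped
  to `[line minimum, data]`. A parabola slides under narrow bright
  ridges that a ball of equal nominal radius cannot enter, so vessels
  are preserved at least as well as under the rolling ball (asserted in
  the tests).

All filters use reflective boundaries so the edge erosion downstream is
not biased by darkened borders.

## Wall extraction

Operator landmarks (CSV, one row per 1-mm segment) mark the apex of the
colon wall and the TAG per segment; they are linearly interpolated to
every slice, with nearest-landmark extrapolation outside the annotated
range. The colon circle is "standardized": by default every slice gets
a fixed radius from the config (default 1800 µm) with the circle top
anchored at the apex. An alternative policy derives the radius from the
apex-to-far-guide-boundary distance. The "upper tenth of the colon
tube" is implemented as a depth band of thickness 2R/10 below the apex
(a depth band matches a substack projection workflow; an angular sector
was the alternative reading). The projection is the mean over the
retained band only, so its intensity is independent of the volume's
depth extent.

The analysis region is the ±18° sector around the apex mapped to a
lateral strip via the orthographic projection x = R·sin θ (at 18° the
chord/arc discrepancy is < 1.7 %), eroded by a 200 µm disk. All
normalized descriptors divide by this region's area; the same region
also implements the edge erosion of mask and skeleton (clipping before
measurement), so one object governs all normalizations.

## Segmentation

* **AT** — Tsai's moment-preserving threshold: the background fraction
  p₀ is solved from the first three histogram moments and the threshold
  minimizes |P(t) − p₀| over all 256 candidates (smallest on ties).
* **VF** — Frangi vesselness with scales interpreted as target vessel
  diameters (40, 60, 80, 100 µm); the Gaussian σ per scale is scale/2
  (the ridge response of a bar of width w peaks near σ ≈ w/2). Hessians
  are σ²-normalized; β = 0.5; c defaults to half the maximal Hessian
  norm per scale; responses combine by pixelwise maximum and are
  rescaled to [0, 1]. The mask comes from the Kittler–Illingworth
  minimum-error threshold. Class variances in the criterion are floored
  at 1/12 bin² (the within-bin quantization variance); without the floor
  a large population of exactly-zero background pixels forms a
  zero-variance class that drives the criterion to −∞ and collapses the
  threshold to the first bin.
* **RF** — a seeded random forest (100 trees, √-features per split) on
  8 feature planes per scale (Gaussian, Laplacian of Gaussian, gradient
  magnitude, difference of Gaussians, structure-tensor and Hessian
  eigenvalue pairs sorted by magnitude) at σ ∈ {0.3, 0.7, 1.0, 1.6,
  3.5, 5.0, 10.0} px. Training takes (image, label) pairs with labels
  {unlabeled, background, vessel}; the 8-bit vessel probability map is
  binarized at ≥ 128.

Foreground is `value ≥ threshold` everywhere, and both rule-based
thresholds are invariant to affine intensity rescaling by construction.

## Network quantification

Masks are median-filtered (3×3), clipped to the analysis region, and
thinned to an 8-connected one-pixel skeleton. Skeleton pixels with one
neighbour are endpoints, with ≥ 3 neighbours junction pixels; adjacent
junction pixels merge into a single junction node so thick crossings do
not inflate the branch count. A branch connects two nodes (or closes a
node-free cycle); isolated pixels count as one zero-length branch.
Branch length sums Euclidean steps (pixel size, √2 × pixel size for
diagonals). This step rule overestimates the length of lines at
intermediate angles by up to ~8 % while endpoint retraction of the
thinning shortens each free end by about one vessel radius; on networks
of mixed orientation the two biases largely cancel (the recovery
experiment bounds the residual below 5 %).

Local diameter at a skeleton pixel is 2 × the Euclidean distance
transform of the mask (distance to the nearest background pixel center),
in µm — a one-pixel line therefore reads two pixel widths, and an
axis-aligned odd-width bar reads one pixel wide of its nominal width.
Blood volume sums π (d/2)² ℓ per skeleton pixel, where ℓ is half the
pixel's incident step lengths, which converges to the tube integral
∫ π r(s)² ds. The box-counting dimension uses sizes {2, 4, 8, 16, 32,
64} anchored at the analysis region's bounding-box corner and is the
negative slope of ln N(s) vs ln s.

Degenerate inputs are defined: an empty mask yields zero-valued
descriptors with average diameter and fractal dimension reported as NaN
(missing), not zero.

## Phantom generator

The generator emulates the guide-distended colon: a cylindrical wall
shell (radius 1800 µm, thickness 60.9 µm, apex at 400 µm depth) around
the guide axis, vessels grown on the unwrapped wall plane and wrapped by
their projected abscissa u = R sin θ — so the depth projection of the
embedded volume aligns pixel-for-pixel with the 2D rasterization (the
≤1.7 % arc/chord error inside ±18° is absorbed by this choice).
Degradations: anisotropic Gaussian PSF (FWHM 40/40/10 µm),
depth-periodic attenuated echoes of the blurred signal (period 250 µm,
amplitude 0.2, two echoes), and additive Gaussian noise specified via
contrast-to-noise ratio (default CNR 10) with clipping at zero.

Vessel growth is a seeded branching process: trunks with uniform
position/orientation, branch lengths U(400, 900) µm in 40 µm steps with
9° heading jitter, bifurcation probability 0.8 into two children tapered
by 0.85, stopping at depth 3, a 40 µm diameter floor, or the domain
edge (trees terminate rather than fold back). The defaults are
calibrated so a healthy phantom lands in the healthy-colon descriptor
range (normalized network length ≈ 2.6 × 10⁻³ µm⁻¹, mean diameter
≈ 100–120 µm, blood volume ≈ 15–20 µm³ µm⁻²) and so the smallest branch
generation carries roughly a quarter of the blood volume — consistent
with vessel populations dominated by small calibres, as seen in colonic
histology. Truth descriptors (length, area, volume, branch and
component counts) are closed-form sums over the polylines. For
unconstrained growth (margin large enough that the edge is unreachable,
no diameter-floor truncation, no collision checking) the expected total
length has the closed form n_trunks · E[ℓ] · Σ (2p)^d, used as a
Monte-Carlo oracle.

Two optional growth constraints exist for measurement studies: an
interior start margin, and collision-aware growth (a branch stops before
touching another tree), used where rasterized geometry must match truth
exactly.

The colitis transform removes a fraction of branches — always the
smallest-diameter *terminal* branch next, so trees stay connected — and
multiplies surviving diameters by a dilation factor, emulating the loss
of small vessels and dilation of the remainder seen in inflamed colons.

## Validation experiments and problem sizes

* *Threshold oracles*: 50 seeded 64×64 two-Gaussian mixtures; both
  thresholds must equal exhaustive 256-candidate searches exactly.
* *Recovery*: 20 rasterized phantoms of sparse, collision-free, lightly
  branched vessels (diameters ≥ 3 px, the geometry of colonic vasa
  recta) on a 10.2 mm plane; length within 5 %, mean diameter within
  10 %, blood volume within 15 % of analytic truth, per phantom. The
  sparse fixture isolates measurement fidelity: dense networks lose
  apparent length where tubes overlap and merge, which is a property of
  union masks, not of the measurement chain.
* *3D consistency*: one full-size 600×600×750 phantom; noiseless
  projection NCC ≥ 0.95 against the rasterization, VF Dice ≥ 0.80 at
  CNR 5 with artifacts and full preprocessing.
* *Colitis directionality*: 20 seeds on a compact 3.8 × 6.4 mm grid
  (192×320×230 voxels) through the complete 3D VF pipeline; prune 0.4 /
  dilate 1.1 must decrease six descriptors and increase mean diameter in
  ≥ 90 % of seeds.
* *Method ranking*: five dense faint-vessel phantoms (brightness scaling
  with diameter, lateral PSF, background and noise); VF must recover
  more true network length than AT on every seed and mean normalized
  length must order AT < RF < VF.

The compact grids keep the full suite within routine runtimes on a
single CPU; the full-size consistency check confirms behaviour at the
native volume size.

## Known limitations

* The phantom is a geometric emulation, not an acoustic simulation:
  no frequency-dependent attenuation, no speed-of-sound errors, no
  reconstruction artifacts beyond periodic echoes. Passing tests show
  the analysis chain is self-consistent and recovers known geometry
  under realistic contrast and noise; they do not certify accuracy on
  in-vivo scans.
* Vessels are painted into the wall shell's radial band; very large
  vessels (> wall thickness) are flattened into the band.
* Diameters below ~2 px (40 µm) are unresolvable by construction; the
  2×EDT convention introduces a ±1 px quantization on widths.
* The skeleton length rule inherits the ±8 % orientation-dependent bias
  of 8-connected chain codes; descriptors are comparable across samples
  analyzed with this package but not directly against tools with other
  length calibrations.
* The RF method's quality depends entirely on its training pairs; the
  bundled experiments train on phantoms, not on annotated scans.
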