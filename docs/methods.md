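# Methods

This note records the models, algorithms, parameter choices, and known
limitations behind `rodmorph`, at the level of detail a user needs to judge
what the package's validated behaviour does and does not imply about real
data.

## Coordinate conventions

Images are 0-based row-major arrays; `x` is the column index, `y` the row,
pixel centers at integer coordinates (the simulator places them at
`(i + 0.5) · pixel_size` in physical units). All geometric outputs are in
micrometers via `pixel_size`; raw contour and mask files stay in pixels.
Closed contours are counterclockwise, so the interior lies left of the
direction of travel, the outward normal points right, and curvature is
positive where the outline is locally convex. `z = 0` is the focal plane;
a simulated cell's center defaults to `z = 0` (midplane focus).

## Segmentation

All three modalities are reduced to a *boundary-intensity map* that is
bright along the cell outline: PF images are used directly; PC and IF
images are converted via |∇I| (central differences, normalized to max 1).
Preprocessing stretches intensities linearly between the 0.1th and 99.9th
percentiles (robust to hot pixels) and can subtract a morphological-opening
background (`background_radius_px`, default off) for uneven illumination.

Objects are the filled connected regions above an Otsu threshold of the
boundary map, split by a watershed on the distance transform. Watershed
seeds are the connected high-distance cores (`dist > 0.6 ×` the component
maximum), merged within `seed_merge_px = 3`: a rod's axial ridge is one
plateau of near-equal distance maxima, so seeding from *all* regional
maxima would shatter it, while the relative-threshold core keeps one seed
per cell and still splits touching cells at their neck. Objects are
filtered on pixel area and mean interior intensity, and then on the ratio
of boundary-band to interior intensity on the boundary map: the band is an
annulus inset 1 px from the thresholded edge (≤ 4 px wide, adaptive for
small objects, 1-px guard ring), because the rim ridge of a real cell sits
a few pixels inside the threshold cut. Measured ratios under the default
optics: ~1.4 for 1–2-μm cells versus ~1.0 for uniform debris; the default
threshold is 1.2. Two caveats are inherent to the physics: sub-wavelength
cells (≲ 0.5 μm) lack rim/interior contrast entirely, and cells much wider
than ~3 μm fill with structured defocused light, so for controlled
single-cell simulations the validation scans disable the filter (threshold
0). The final object pixel set is the half-max core of the object's
boundary-map intensity, which tracks the rim rather than the defocus halo.

`link_frames` performs greedy nearest-centroid tracking with a maximum
displacement; objects that swap positions between frames are followed by
proximity, not identity — a documented limitation of greedy linking.

## Contour fitting

Each object's pixel boundary, resampled to `spacing_px = 1`, initializes a
closed polyline that descends the energy

E = Σᵢ [ −Î(vᵢ) + α|vᵢ₊₁ − vᵢ|² + β|vᵢ₊₁ − 2vᵢ + vᵢ₋₁|² ]

by explicit gradient descent with backtracking: a step that raises E or
self-intersects is rejected and the step halved; the polyline is
reparameterized to equal arclength every 10 accepted steps; convergence is
a maximum vertex displacement below `tol = 1e-3` px (cap `max_iter = 500`).
Î is a bicubic spline of the boundary map scaled to [0, 1]. The defaults
α = 0.05, β = 0.5, step = 0.2 keep the smoothness terms far below the
image term at realistic signal-to-noise, preserving the method's
essentially parameter-free character: on an analytic ring the equilibrium
displacement due to α is ~0.02 px.

Because the image force is local and the halo of defocused light outside a
cell is nearly flat, descent alone can stall several pixels out. The
initialization therefore snaps each seed vertex to the boundary-map
maximum along its inward normal (search bounded by the object's medial
axis so a vertex cannot jump across a thin cell; offsets smoothed along
the contour; a lightly blurred map is used for the search only). The
descent then refines on the raw map, so the converged position is the
interpolated ridge. On analytic Gaussian rings the fitted radius is within
0.05 px of truth and 0.25-px radius steps are resolved monotonically.

## Curvature and pole detection

Curvature at each vertex is 1/R of the algebraic (Kasa) least-squares
circle through all vertices within ±`window_arc_um` (default 0.25 μm) of
arclength, signed by the side the center falls on. Two guards map
degenerate windows to κ = 0: an eigenvalue-ratio collinearity test (the
rank-deficient system otherwise returns an arbitrary min-norm center), and
a chord/sagitta consistency bound (at inflection points the fit can return
a spuriously tiny radius). The 0.25-μm default resolves hemispherical caps
down to ~0.4-μm cells; sensitivity is quadratic in window size (noise
∝ window⁻²; cap smoothing extends ~one window into the flanks).

Pole detection — which doubles as the rod-shape/segmentation-error filter —
works on a detection profile computed at a coarser window
(min(perimeter/30, 0.5 μm), vertices pre-smoothed over 0.67 of that
window), because wide cells pair low cap curvature (2/w) with unchanged
contour noise. Candidate poles are prominence-filtered peaks above the
larger of (background + half the profile's dynamic range) and a
2-MAD outlier level, where background is the 10th percentile (flank level
even when caps dominate the perimeter). Peaks merge when the profile
between them never falls halfway back toward background relative to the
smaller peak (two noise maxima on one broad cap are one pole; the convex
outer flank of a bent cell does not merge its two real poles), surviving
peaks must be ≥ 25 % of the perimeter apart and integrate ≥ π/4 of
turning. A contour is accepted iff exactly two such maxima exist; accepted
poles are then localized as the mutually farthest vertex pair (the cap
apices), since curvature peaks localize poorly on flat plateaus. On the
analytic zoo this accepts rods (straight, bent, indented, 0.4–8 μm wide)
and rejects circles (0 maxima) and Y-shaped cells (3).

## Meshing and measurements

The contour is split at the poles into two arcs, each resampled to
M = max(50, perimeter_px/2) equal-arclength stations; meshline *i* joins
opposite stations, the midline is the meshline midpoints, widths are
meshline lengths (for symmetric pairings identical to twice the
midline-to-boundary distance). One re-pairing pass aligns meshlines with
the perpendicular of the local midline, but is kept only when it improves
mean perpendicularity: for straight rods the symmetric pairing is already
optimal and re-pairing against a noisy tangent field inflates midline
arclength. The midline is smoothed at a 0.1-μm scale (station-level jitter
otherwise accumulates into systematic length overestimates; genuine
bending at radii ≫ 0.1 μm is preserved, e.g. a 3-μm-radius banana's
midline length errs by < 0.3 %). Meshline crossings among substantive
meshlines (≥ 20 % of max width; the vanishing polar meshlines cross
benignly) trigger one local reorder, then a fall-back to the symmetric
pairing, then rejection.

Scalar measurements: length = midline arclength; mean width and its
intracellular CV are computed over the central region only (stations at
least max_width/2 of arclength from each pole, which exactly excludes the
hemispherical caps of an ideal rod); area is the shoelace area of the
contour. On analytic spherocylinders (w = 1, L = 4 μm) the errors are
< 0.03 % in all three, and a ±10 % sinusoidal width modulation yields
width_cv = 0.0717 against the analytic 0.0707.

The branching mesh (for non-rod shapes) is the Voronoi medial axis of the
densely resampled contour, restricted to interior edges, pruned of leaf
branches shorter than one local width, with each free end trimmed by one
local radius (Voronoi spurs inside caps can merge into the trunk) and
extended straight to the contour. For rods it agrees with the centerline
midline to < 0.05 μm Hausdorff; a Y-shaped cell yields three arms and one
branch point; a circle degenerates to radial spokes near the center.

## Fluorescence simulation

Fluorophore fields are sampled area-uniformly on the spherocylinder
surface (membrane labels) or volume-uniformly by rejection (cytoplasmic
labels), with Poisson-distributed molecule counts. Rendering bins
molecules into 0.05-μm z-slices, splats each slice onto the pixel grid
with bilinear weights, and convolves with that slice's PSF plane — exactly
photon-conserving (< 0.1 % truncation) and linear in intensities.

Two PSF models are provided. The parametric model is the Gaussian defocus
approximation σ(z) = σ₀√(1 + (z/z_R)²) with σ₀ = 0.21 λ/NA and the axial
scale set by geometric optics, z_R = 2σ₀/tan(asin(NA/n)) (the paraxial
Rayleigh range nλ/NA² badly understates defocus at high NA and would let
out-of-focus light corrupt boundary localization far more than a real
objective does). Plane energy is constant in z (widefield). The sampled
model wraps a measured 3D kernel (trilinear in z). For the validation
loop, a third option is computed internally: a scalar-diffraction
widefield stack (Fourier optics over a hard NA pupil with the
sine-condition detection apodization cos⁻¹ᐟ⁴θ). No Gaussian σ(z) law can
reproduce both experimental facts at once — a nearly unbiased rim for
≳ 2-μm cells *and* a boundary that remains localizable at ±500 nm
defocus — whereas the diffraction stack does, because a real defocused
PSF keeps a structured core while spreading its energy. Not modeled:
index-mismatch spherical aberration (which breaks ±z symmetry), vector
high-NA effects, spectral bandwidth (tested: < 0.2-point effect on the
bias curve), vignetting.

The noise model is counts = Poisson(gain·I + dark) + offset +
N(0, read σ²), clipped at zero, fully seeded. Thermal noise is represented
as Poisson dark counts.

## The validation loop

In-silico surface-labeled cells (default density 2000 fluorophores/μm²,
gain 200 photons/intensity — high-density, high-SNR conditions) are
rendered at 0.05 μm/pixel (NA 1.4, λ 0.61 μm, n 1.515), measured by the
full PF pipeline, and compared with the generating geometry; the scan uses
lengths L = w + 3 μm so every width keeps a true cylindrical flank, three
replicates per width, fields of view capped at 512². Under these
conditions the measured width is below the true width for all narrow
cells, the bias shrinks monotonically with width — −10 % at 1 μm, −2.8 %
at 2 μm, −1.1 % at 3 μm, −0.7 % at 4 μm, −0.2 % at 8 μm — and the length
error is width-independent (< 1.5 % for w ≥ 2 μm, constant across lengths
3–8 μm at fixed width). The residual ~3 % at exactly 2 μm is a property of
symmetric scalar widefield optics at these parameters (the ridge of the
noiseless image itself sits there), not of the contour machinery, which
tracks the rendered ridge to < 0.1 %. In the focal series of a 1-μm cell
the measured width peaks at the midplane, falls monotonically with
|offset|, remains measurable at ±500 nm, and spans ~0.36× the range of the
true cross-section width 2√(r² − z²).

What passing these simulations does *not* show: robustness to uneven
illumination beyond the background-removal step, dense colonies with
overlapping light fields, aberrated or mismatched-index optics, or
non-membrane label distributions — real-data performance on those axes is
untested here.

## Shape modes and screen statistics

Alignment maps each accepted contour to a 600-vector: subtract the vertex
centroid, rotate the major principal axis onto x, resolve the 180° and
mirror ambiguities by requiring non-negative third moments of x and y
(making alignment chirality-free and deterministic), re-orient
counterclockwise, and resample 300 equal-arclength points starting from
the point of maximal x (a pole). PCA of the covariance matrix (via SVD of
the centered data) gives modes ordered by eigenvalue; eigenvector signs
are fixed by pointing each mode "outward" along the mean shape, so a
positive amplitude of the elongation mode lengthens the cell. The
correlation basis standardizes columns first, dropping zero-variance
columns. A population varying only in length concentrates > 99.9 % of
variance in the elongation mode; a planted orthonormal two-mode population
with 4:1 variances is recovered to < 2° principal angles.

Screen correlations use the exact Pearson/Student-t machinery: R per
condition over strains present in both tables (pairwise deletion of
missing scores; zero-variance inputs yield NaN, never 0), two-sided
p = 2·T_{n−2}(|t|), Bonferroni-corrected over the tested conditions, with
the family size recorded in every result. The COG stratification defaults
to the stricter classes × conditions family (`family="conditions"`
restores per-class correction). The synthetic screen generator plants
exact population correlations on top of Normal(1.0, 0.08) μm strain widths
coupled to lengths 1.2 + 2.2·w + N(0, 0.3) μm. At the scale of a
genome-wide screen (ρ = −0.10, n = 2465, 324 conditions) the exact power
at the Bonferroni level is ~88 % (Fisher-z: r_crit = 0.076, sd(R̂) = 0.020)
— the calibration tests assert the empirical power matches this analytic
value, and null screens keep the family-wise error rate at the nominal
5 %.

## Determinism

Every stochastic step takes a seed; the CLI fans a single global seed out
to per-stage sub-seeds (CRC-based, < 2³¹), so stages can be re-run
independently and whole runs are byte-reproducible. The run log's timing
metadata is the one deliberately non-deterministic output.
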