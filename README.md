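# rodmorph

Sub-pixel measurement of bacterial cell shape from light micrographs, and
simulation of the fluorescence images such measurements are made from.

Bacterial morphology — width, length, curvature, and their variability —
carries biological signal that is subtle compared to the diffraction limit:
an *E. coli* cell is ~1 μm wide, the point-spread function (PSF) of a good
objective ~0.2 μm. `rodmorph` addresses both halves of that problem:

* **Measurement.** Cells are detected in phase-contrast (PC), interior-
  fluorescence (IF), or peripheral-fluorescence (PF) images; each detected
  object's boundary is refined into a smooth closed contour at sub-pixel
  resolution by minimizing a contour energy on the interpolated intensity
  landscape; the contour is meshed into a midline coordinate system whose
  perpendicular meshlines measure the local cell width; curvature profiles
  identify the two poles of rod-shaped cells (and reject segmentation
  errors that have ≠ 2 poles).
* **Simulation.** Explicit fluorophore positions in 3D are rendered through
  a PSF with camera, dark, and shot noise, including z-stacks, TIRF
  weighting, photobleaching (mean-field, stochastic, FRAP-style), and
  motion blur. Rendering in-silico cells of *known* geometry and measuring
  them with the pipeline closes the validation loop: it quantifies the
  systematic inward bias of extracted contours for cells narrower than
  ~2 μm and the behaviour of width measurements as the focal plane moves
  off the cell midplane.
* **Population statistics.** Aligned contours (300 equal-arclength points)
  are decomposed by PCA into shape modes (elongation, bending, widening,
  tapering); per-strain morphology statistics can be correlated with
  chemical-genomics S-scores condition-by-condition, with Student-t
  significance, Bonferroni correction, and COG-class stratification.

## The model in brief

A rod-shaped cell is idealized as a spherocylinder: a cylinder of width
*w* = 2*r* capped by hemispheres, with midplane area
*A* = *w*(*L* − *w*) + π(*w*/2)² and perimeter 2(*L* − *w*) + π*w* for
pole-to-pole length *L*. The fitted contour is a closed polyline
**v**₁…**v**ₙ minimizing

```
E = Σᵢ [ −Î(vᵢ) + α |vᵢ₊₁ − vᵢ|² + β |vᵢ₊₁ − 2vᵢ + vᵢ₋₁|² ]
```

where Î is the bicubic interpolation of the boundary-intensity map (the
image itself for PF; |∇I| for PC and IF), and α, β are small numerical
regularizers, not shape priors. Signed curvature κ(s) along the contour
comes from least-squares circle fits in a sliding arclength window
(positive = locally convex). Simulated images are linear superpositions
I(p) = Σᵢ cᵢ · PSF(p − xᵢ; z) of the PSF at each fluorophore, with Poisson
shot/dark noise and Gaussian read noise.

## Worked example

Render two surface-labeled in-silico cells and measure them back:

```
rodmorph simulate --out demo --seed 5 --n-cells 2 --fov-um 12.8
rodmorph measure --out demo_meas --seed 5 demo/image.tif
```

`demo/cells.csv` holds the ground truth that was rendered:

```
cell,width_um,length_um,center_x_um,center_y_um,axis_angle
1,1.04231,2.78116,9.30527,7.66412,1.15333
2,1.04715,3.36949,5.49819,3.60252,1.84982
```

and `demo_meas/measurements.csv` what the pipeline measured:

```
cell_id,length_um,mean_width_um,max_width_um,area_um2,width_cv
1,3.24782,0.950076,0.963149,2.87339,0.00646401
2,2.66015,0.944678,0.950415,2.29964,0.0047378
```

Both cells are recovered (the ids are detection order, not ground-truth
order). Lengths are ~3 % under the truth and widths ~9 % under — exactly
the systematic inward bias expected for ~1-μm cells, where out-of-focus
light from the curved surface pulls the extracted contour inside the true
midplane outline. The `validate-bias` subcommand maps this bias across
widths 0.4–8 μm and shows it vanishing for wide cells; `validate-focus`
maps the width measured at focal offsets up to ±500 nm. `width_cv` is the
intracellular fractional width variability (SD/mean of meshline widths in
the central region).

The other subcommands: `segment` (label mask + objects table),
`shapemodes` (contour alignment + PCA), `screen` (morphology vs S-score
correlations), `fixtures` (regenerate every synthetic input from a seed).
All accept an INI config (`--config`) and `--set key=value` overrides, and
write their resolved configuration next to their outputs.

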