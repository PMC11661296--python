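# Methods

## Scope and readout

The package quantifies membrane adsorption of fluorescent tension probes in
three geometries — GUV membranes at equilibrium, the nuclear membrane over
time, and ER morphology as the membrane-reservoir context — together with
the model fits and statistics applied to those measurements.  Tension is
never expressed in physical units (mN/m); the readout is always a
fluorescence ratio or a fitted binding parameter.  Wet-lab procedure,
microscope control, SIM reconstruction, commercial deconvolution/denoising
and biological interpretation are out of scope.

## Data model

Stacks are held in a single container with canonical `T, C, Z, Y, X` axis
order (missing axes padded to length 1) and an explicit
`PixelCalibration` (dx = dy = 0.16 µm/px, dz = 1.5 µm, dt = 1 min by
default, overridable; OME metadata wins over arguments when present).
Coordinates are 0-based and pixel-centred.  Parameters quoted in pixels
(blur radii, contour widths) and in µm (tracking bound) deliberately
coexist: the pixel quantities describe image-processing scales, the µm
quantities physical motion.  Axis order is never guessed: a file whose
metadata leaves the layout ambiguous requires an explicit `axes_hint`.

## GUV rim binding

A user line from the vesicle centre to its edge seeds the analysis.  The
crop is a square of half-width ceil(1.5 × line length) around the line
start, clipped to bounds.  The crop is percentile-normalised
(0.1–99.9% → [0, 1]) and blurred with a 3D Gaussian, sigma 3 px in-plane
and scaled by dx/dz axially; "3-pixel radius" is interpreted as sigma
(configurable), the common convention.  Each z-slice is segmented by a
marker-controlled watershed with the interior seeded at the line start and
the background at the crop corners; a basin that reaches the crop border,
or whose boundary carries no membrane signal (boundary median below 25% of
the volume's dynamic range), is rejected as containing no vesicle
cross-section.  The watershed line itself runs along the rim-intensity
crest and is counted as part of the vesicle, so the segmented disc extends
to the membrane centre.  The middle section is the slice of largest
segmented area (ties → lowest index).

Because the basin boundary bisects the rim, the 3-px measurement contour is
centred on the segmentation boundary (erosion-difference applied to the
slightly dilated mask) rather than strictly inside it; on phantoms this
makes the rim median equal the rendered rim amplitude exactly in the
noiseless case.  Medians are taken on **raw** intensities — the
normalisation exists only for segmentation — because the batch reference (a
1 µM protein solution from the same purification) is meaningful only on raw
counts.  `normalized_rim = rim_median / reference`.

## Nuclear-membrane binding

Preprocessing per frame: percentile normalisation, 3D Gaussian blur
(sigma 1 px, z-scaled), and slice-wise rolling-ball background subtraction
with non-negative clipping.  The rolling element is an *ellipsoid*: 50 px
lateral radius (config-exposed) but shallow on the intensity axis (10% of
the slice's dynamic range).  A sphere of 50 px radius applied to
normalised intensities (range ≈ 1) would hug the flat top of any nucleus
wider than the ball and subtract the nucleoplasm itself; the shallow
ellipsoid removes slowly varying shading while leaving genuine objects
intact.  For speed the background is estimated on a 4× downsampled image
and interpolated back (the classic ImageJ shrink trick); the background is
smooth at the ball scale so the approximation error is negligible.

Segmentation is masked-object thresholding followed by a marker-controlled
watershed: a global Otsu cut finds foreground; each connected component is
re-thresholded with the Otsu cut of its background-padded bounding box.
Two guards make this robust for rim-bright objects: the local threshold may
only *grow* a component (a shrink would hollow out a nucleus whose envelope
outshines its nucleoplasm), and masks are hole-filled slice-wise so a dim
nucleoplasm enclosed by a bright envelope ring is recovered.  Markers come
from in-plane erosion of the refined components (disk radius 5; erosion is
2D because the z-step is ~9 px); the watershed floods the inverted smoothed
intensity inside the mask.  Objects under 200 voxels are dropped.

Tracking is greedy nearest-neighbour linking of 3D centroids in physical
units: candidate links are consumed in order of increasing distance, links
beyond 50 µm are forbidden, unmatched objects open new tracks, and tracks
shorter than 3 frames are dropped.  Nuclear movement in these experiments
is bounded, so no motion model is needed.

Per frame of a track, the middle slice is the z-slice of largest labelled
area (ties → lowest index).  The membrane contour is a 3-px band at the
inward offset (0..3 px) whose median raw-probe intensity is maximal —
the segmentation boundary sits on the threshold crossing slightly outside
the membrane peak, and snapping the band onto the signal removes that
offset; ties resolve to offset 0, so a uniform nucleus measures ratio 1.
The background ("nucleoplasm") contour is a 3-px-wide ring at 50% of the
object's equivalent radius, intersected with the eroded interior: the
geometry is not specified by the readout definition beyond "inside the
nucleus", and half-radius avoids both the membrane and the centre, where
probe-rich droplet-like bodies can sit.  Frames whose ring is empty are
flagged NaN, never fabricated.  `ratio = membrane median / background
median` on raw intensities; `ratio_norm` divides by the first finite
frame, so ratio_norm(0) = 1 exactly.  With a lamin channel,
`ratiometric = probe membrane median / lamin membrane median` controls for
the known caveat that a dimming nucleoplasm can mimic increased membrane
binding.

Line profiles (for in-vivo stills) sample bilinearly at unit-pixel spacing
along a segment, endpoints inclusive, with distances converted to µm.

## ER morphology

With a luminal marker the ER is segmented by the same
masked-object-threshold + watershed chain as nuclei, with a 10-voxel size
filter and no hole-filling (a network loop is not a hole to be filled).
With a membrane marker a multiscale Hessian ridge ("filament") filter
(Sato tubularity, sigmas 1 and 2 px) is thresholded by Otsu on the
response; the filter favours elongated structures over equal-intensity
blobs.

Morphology is measured in 2D on the analysis plane (single-plane scenes, a
chosen slice, or a projection): the circularity formula mixes an area with
a perimeter, which is intrinsically two-dimensional, and the ~9:1 voxel
anisotropy makes 3D surface/perimeter estimates on these stacks
unreliable.  Area is pixel count × dx·dy; the perimeter uses the Crofton
multi-direction estimator, because naive pixel-edge counting biases disc
circularity to ≈ 0.78 whereas Crofton keeps discretised discs of radius
≥ 10 px within ~1% of circularity 1 (values are clamped to [0, 1]).
Medians are aggregated per field of view — neighbouring cells' ER cannot
be reliably separated — and time courses are normalised to t = 0
(`fold_area`, `fold_circularity`), which requires a non-empty first
timepoint.

## Binding models and statistics

**Hill–Langmuir isotherm.**  `B(c) = Bmax·c^H/(c^H + Kd'^H)` (evaluated in
the overflow-safe logistic form) is fitted by Levenberg–Marquardt least
squares on log-parameters, enforcing positivity, with multi-starts over
Kd' at the quartiles of the positive concentrations and H ∈ {0.5, 1, 2};
the lowest-RSS converged start wins, and total failure raises with
per-start diagnostics.  95% CIs come from the asymptotic covariance
s²(JᵀJ)⁻¹ with the analytic Jacobian and a t quantile on n − 3 df —
bootstrap was considered but the asymptotic interval calibrates well at
the n ≈ 8, 2%-noise regime these curves occupy (~95% empirical coverage in
the test suite).  At least four distinct concentrations are required.

**Binding rate.**  The "linear part" of a ratio time course is defined
operationally: slide a window of ceil(0.3·n) frames, keep windows with
r² ≥ 0.9, and among them choose the one maximising slope·sign(net change);
if none qualifies, fall back to the maximum-r² window.  The OLS slope,
intercept, standard error and the chosen window bounds are all reported,
so every rate is auditable.  The estimate is invariant to intensity
offsets and scales inversely with time rescaling.

**Welch test.**  Two-tailed t-test assuming unequal variances
(scipy's `ttest_ind(equal_var=False)`), with star categories at
p ≤ 0.05/0.01/0.001/0.0001 and "ns" above.  Both-samples-constant with
equal means returns t = 0, p = 1.  No multiple-testing correction is
applied, matching per-comparison reporting.

**FOV joins.**  ER metrics are per-FOV while binding is per-nucleus; for
correlation analyses every nucleus inherits its FOV's value via a
validated left join (duplicate FOV keys are an error; unmatched nuclei are
excluded and logged).

**Osmotic dilution.**  Δπ = start − (v₁·start + v₂·diluent)/(v₁+v₂), with
the water + 1.26 mM CaCl₂ diluent assigned 3 × 1.26 = 3.78 mOsm under
ideal full dissociation.  The function returns the unrounded value; the
published scheme's 80 + 320 µL and 40 + 360 µL rows evaluate to 269.78 and
303.50 mOsm, i.e. 270 and 303 to the nearest integer.

## Synthetic phantoms

The generator renders geometry in physical space and samples it on the
anisotropic voxel grid, then applies an acquisition model: Gaussian PSF
(sigma in px, z-scaled by dx/dz), optional multiplicative linear shading,
Poisson shot noise (photons per intensity unit) and additive Gaussian read
noise, with non-negative clipping.  Every generator is a pure function of
its seed.

* **GUV**: a spherical shell centred on the sphere surface (so the
  analytic per-slice rim circle runs through the middle of the rendered
  membrane), dim interior, odd slice count so the equator lies on a slice.
* **Nuclei**: ellipsoids with a rim band (~4 px in-plane) and interior,
  each with per-frame intensity courses; rim/interior is the ground-truth
  binding signal.  Optional constant-amplitude lamin channel.  Optional
  drift.  Overlap between phantoms is rejected frame-by-frame.
* **ER**: single-plane scenes.  Tubular mode draws a minimum-spanning-tree
  network over random nodes (guaranteed one connected, elongated
  component); vesiculated mode places disjoint discs by rejection
  sampling; mixed mode interpolates.  Ground-truth area/perimeter are
  analytic for parametric shapes (discs, rectangles) and Crofton-measured
  on the pre-noise label mask for network components.  Disc circularity 1
  versus network circularity ≪ 0.5 guarantees the vesiculated > tubular
  median-circularity ordering for any seed.
* **Model data**: Hill curves with additive Gaussian noise, and
  baseline/linear-rise/plateau rate series with the true slope stored.

Default study conditions used by the pipelines, tests and the acceptance
script: PSF sigma 0.6 px — the diffraction-limited lateral sigma
(≈ 0.21 λ/NA ≈ 90 nm for 620 nm emission through a 1.45 NA objective at
0.16 µm/px); Gaussian read noise at ~2% of the signal amplitude;
background offset ≈ 2 intensity units; nuclei of 5–5.5 µm in-plane
semi-axes imaged over 7 z-slices; binding curves with 8 concentrations
spanning 0–500 nM around Kd' = 100 nM, Hill coefficient 2, 2% noise —
sizes chosen so each full pipeline runs in seconds on one CPU while
objects remain tens of pixels across, the regime the estimators assume.

What the phantoms do **not** emulate: optical aberrations and
depth-dependent PSF variation, photobleaching, chromatic misregistration,
cytoplasmic autofluorescence, probe sequestration by curved vesicles, cell
crowding and true 3D ER architecture.  Passing tests therefore demonstrate
correctness of the measurement chain on idealised geometry — recovery of
known ratios, directions of effect, parameter round-trips — not robustness
to every real-microscopy artefact.

## Numerical choices and degenerate inputs

Ties in middle-slice selection go to the lowest z index; ties in the
contour-snap offset go to offset 0.  Constant images degenerate gracefully:
percentile normalisation returns zeros with a logged warning (not an
error), the Welch test returns t = 0, p = 1, and rolling-ball subtraction
returns exactly zero.  A contour erosion that empties a mask falls back to
the full mask with a warning; an empty background ring flags the frame NaN.
Circularity estimates are clamped to [0, 1]; the pre-clamp excess for
discs ≥ 10 px is ~1%.  Seeds for stochastic stages are explicit
everywhere; there is no hidden global randomness.

## Known limitations

* The background-ring placement (half the equivalent radius) is a
  documented choice, not a published geometry; strongly non-convex nuclei
  could put parts of the ring outside the nucleoplasm.
* Greedy nearest-neighbour tracking has no motion model and can swap
  identities if two nuclei approach within their per-frame displacement.
* 2D ER morphology on projections merges objects that overlap in z.
* The rate-window rule is an operational definition of "linear part";
  different window fractions give slightly different rates (the window is
  reported for exactly this reason).
* The asymptotic Hill CIs undercover for very small n or Hill coefficients
  far above the multi-start grid.
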