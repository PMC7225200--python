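# Methods

`depotscope` is a desk-scale re-creation of a synchrotron micro-CT
workflow for imaging subcutaneously injected PLG-microsphere suspension
formulations in *ex vivo* porcine tissue, together with the optical
macrotomy workflow used as its comparison method. Every stage operates
on simulated data whose ground truth is known, so the whole chain —
acquisition physics, reconstruction, particle detection, depot
quantification — is testable end to end.

## Imaging model

The beam is monochromatic and parallel (synchrotron geometry), default
70 keV (`lambda = hc/E ≈ 1.77e-5 um`). A phantom voxel grid (z, y, x)
holds material labels; each material carries the complex refractive
index `n = 1 - delta + i*beta` with the identity `mu = 4*pi*beta/lambda`
enforced at construction. For one tomographic slice the exit wave after
the sample is

    psi(s) = exp( -M(s)/2 - i (2*pi/lambda) D(s) ),

where `M` and `D` are line integrals of `mu` and `delta` computed by
rotate-and-sum projection with linear interpolation (the rotation axis
is the z axis at column `N//2`). Free-space propagation over the
sample-to-detector distance `d` (default 1 m — the edge-enhancement
regime) uses the angular-spectrum transfer function
`exp(-i*pi*lambda*d*f^2)` per sinogram row, which is exact for parallel
illumination with slice-independent propagation. At `d = 0` the code
returns the Beer–Lambert contact image exactly.

The detector model then applies, in order: per-column multiplicative
gain (with a small *drift* between flat-field acquisition and the scan
— without drift, flat-fielding would cancel the gain exactly and no
ring artifacts would survive to be filtered), radial lens distortion
`r_d = r_u (1 + k1 r_u^2 + k2 r_u^4)` for the single-camera path or a
two-frame split with overlap for the two-camera large-field path, and
optional Poisson noise at a configurable flux (default 1e4
counts/pixel in the flats; the source experiment reports exposure
times, not counts, so this is a free parameter).

## Material constants

No optical constants are published for these exact formulations, so the
material table holds nominal 70 keV soft-tissue values chosen for
correct contrast *ordering*: adipose < aqueous vehicle ≈ water/agarose
< muscle < PLG; iodinated vehicle ≥ 3× tissue attenuation; and
contrast-adsorbing microspheres brighter than the spiked vehicle (the
surface-adsorption effect seen experimentally). `delta/beta` defaults
to 100 for tissue-like materials and 30 for iodinated ones. Every value
is overridable per phantom spec; only relative contrast matters for
pipeline validation.

## Pre-processing chain

Applied in the acquisition order: flat/dark-field normalisation
(`(raw - dark)/(flat - dark)`, clipped at 1e-6 before any logarithm),
then stitching (LFV) or distortion correction (module path), then
Fourier ring suppression. The ring filter damps, within the low
angular-frequency band `|f_ang| <= u_band` bins, everything above a
Butterworth detector-frequency cutoff
`H(f) = 1/(1 + (f/v_cut)^(2*order))` — the signature of a stripe is
constancy along angle with structure along the detector. Defaults
`u_band = 3`, `v_cut = 0.05 cycles/sample`, `order = 2` follow common
synchrotron practice; the original processing chain names the filter
without reporting parameters, so validation is property-based (stripe
variance reduced ≥ 90%, smooth sinograms perturbed < 1%) rather than
parameter-exact.

A consequence worth knowing: a feature lying *on* the rotation axis
produces an angle-constant sinogram trace — exactly the stripe
signature — and is attenuated by any sinogram-domain ring filter. The
standard phantom therefore places the injection site ~31 voxels off the
rotation axis, as in any real mount. Ring removal is applied per slice;
whether the original chain ran it per slice or per volume is not
recoverable from the source description.

## Reconstruction branches

Both branches use filtered back projection (frequency-domain ramp
filter with ≥2× zero padding, linear-interpolation backprojection;
Ram-Lak default to preserve 3–4 px particles, Hann optional), scaled so
a uniform disk of attenuation `mu0` reconstructs to `mu0` in 1/um.

The *attenuation* branch reconstructs `-ln(I/I0)` directly and keeps
the edge-enhancement fringes as high-frequency texture. The *phase*
branch first applies single-image phase retrieval to each projection
frame,

    T(f) = 1 / (1 + pi*lambda*d*(delta/beta)*(u^2 + v^2)),

a transport-of-intensity low-pass under a homogeneous `delta/beta`
assumption, then reconstructs the retrieved `-ln` projections. With the
ratio matched to the object the fringes cancel to first order (the
suite verifies ≥ 80% overshoot suppression on a homogeneous step, and
exact agreement with a directly-summed DFT oracle at 1e-10). The
`delta/beta` parameter defaults to 100 and is user-settable; the output
is left in retrieved neg-log units rather than converted to thickness,
because the multi-material sample violates the single-material
conversion assumption.

Vertical sub-scans (2–4 per sample, configurable overlap) are
reconstructed independently and merged into one consecutively numbered
section stack, keeping the earlier stack's sections in the overlap
("mean" mode optional).

## Microsphere detection

Microspheres at 20–100 um are at most a few detector pixels across;
intensity thresholding alone cannot separate them from tissue. The
detector combines

* an intensity criterion on the phase-branch volume (`> tau_i`), and
* a texture criterion on the magnitude of a high-pass filtered
  attenuation volume (`|v - G_sigma(v)| > tau_t`, Gaussian sigma
  default 2 px) — the high-pass concentrates the edge-enhancement
  energy the spheres carry.

Candidates are 26-connected-labelled and size-gated: components smaller
than `min_voxels` are dropped; components with bounding-box extent
above `2 × max_diameter_px` (default gate 5 px ≈ ceil(100 um / 21.5 um))
are elongated interface artifacts and rejected; components between the
single-sphere gate and twice the gate are treated as touching-sphere
clusters and split at Euclidean-distance-transform maxima (peaks ≥ 2 px
apart) via watershed — clustered deposition makes contact between
spheres the norm, and discarding merged pairs would silently cap
recall. Each kept (sub-)component contributes one voxel-rounded
centroid to the binary centre map; centres closer than
`min_separation_px` (default 3 px, the diameter of the smallest
resolvable sphere) are duplicate detections of one particle and merged,
keeping the larger component.

Detected 60–90 um spheres measure 2–4 pixels across at half maximum in
the reconstructed sections (median 3); isolated measurements of 5 px
occur at adverse sub-pixel alignment in the fringe-bearing attenuation
branch, where the overshoot ring biases the local background estimate.

The original workflow determined thresholds manually per sample and
inspected false positives by eye. Both are replaced by objective
harnesses: `score_detection` does greedy one-to-one nearest-neighbour
matching against ground truth within a match radius (default 3 px), and
`tune_thresholds` performs the per-sample threshold search (coarse
upper-quantile grid, then local refinement, maximising F1). Otsu-based
suggestions are available when no truth exists.

## Depot quantification

The vehicle is segmented from the phase volume by a single intensity
threshold (per-sample; a top-percentile default is provided). Metrics:
vehicle volume (voxel count × voxel³), microsphere–vehicle
co-localisation (fraction of centres inside the optionally dilated
mask), and radial geometry about the needle axis — median and 90th
percentile of centre-to-axis perpendicular distances versus the
vehicle mask's maximum radial extent. The "sieving" signature of the
tissue (vehicle migrating distally while spheres are retained near the
track) is operationalised as `radial_p90(spheres) <
radial_extent(vehicle)`. Visualisation helpers provide 2×2×2 block-mean
binning (partial trailing blocks averaged over available voxels) and
Gaussian rendering of centre maps (mass-conserving away from borders).

## Macrotomy comparison

The optical pipeline consumes serial section photographs: integer-pixel
alignment to per-image reference points (rotation/scale are fixed by
the camera mount), dye-channel thresholding (explicit value or Otsu,
logged for reproducibility), and stained area/volume quantification at
the standard calibration — 0.353 mm pixels, 30 um sections with every
sixth face imaged, hence a 180 um voxel depth (the identity
`30 × 6 = 180` is asserted whenever defaults are used). Microspheres
are not resolvable at this scale, so the module quantifies the vehicle
depot only. A synthetic section-stack generator (ellipsoidal dyed depot,
recorded shifts, Gaussian pixel noise) provides ground truth; its first
section defines the reference frame.

## Standard study configurations

The desk-scale presets use a 28 × 160 × 160 voxel grid at 21.5 um
(the two-camera detector's pixel size) with 400 projections over 180°
— a deliberate scale-down of the full 3600-projection, 2560-column
beamline geometry chosen so a complete simulate-reconstruct-detect
cycle runs in tens of seconds on one core; every processing step is
identical at both scales. The clustered phantom carries 40 spheres of
60–100 um (the individually resolvable regime at this pixel size; the
full formulation range 20–100 um remains the generator default)
deposited with a 300 um half-normal spread about the needle track,
inside an ellipsoidal contrast-vehicle depot (semi-axes 180 × 800 ×
950 um) that extends well beyond the sphere cluster — the geometry the
sieving observation describes. A sparse preset places isolated 60–90 um
spheres on a staggered grid, well inside the depot and away from the
rotation axis, for apparent-size measurements free of cluster overlap
effects.

## What the synthetic data does and does not show

The generator reproduces the features the processing chain must
handle: propagation fringes, gain-drift ring precursors, lens
distortion, two-camera overlap, photon noise, vertical sub-scan
overlap, and the depot/cluster geometry of an injection. It does not
model anatomy (vasculature, fascia), beam hardening (monochromatic
beam), scintillator blur, deformable tissue, or injection flow.
Passing tests therefore demonstrate that the *processing chain* is
correct and that the claimed detection/quantification properties hold
under the stated contrast and noise assumptions — not that those
properties hold for arbitrary real tissue data, where per-sample
threshold tuning and visual review remain necessary (as they did in
the original workflow).

## Numerical choices and degenerate inputs

* Intensity ratios are clipped at 1e-6 before logarithms (dead pixels).
* Angles are uniform on [0°, 180°), endpoint-exclusive.
* Distortion correction maps through the forward polynomial
  (undistortion) and a tabulated numerical inverse (simulation);
  border samples use edge replication.
* Sphere rasterisation labels voxels whose centres fall inside the
  radius (no anti-aliasing); placement rejects overlaps (centre
  distance ≥ sum of radii) and raises naming the achieved count when
  the requested number cannot be placed.
* Zero-sphere populations, zero-size depots, single-image stacks and
  empty candidate volumes are all defined no-ops rather than errors.
* The pipeline fans one global seed into per-stage child seeds via a
  counter scheme so stages can be re-run in isolation.
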