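# depotscope

Desk-scale synchrotron micro-CT simulation and analysis of
subcutaneously injected microsphere suspension depots.

Long-acting injectable formulations suspend biodegradable PLG
microspheres (20–100 um) in an aqueous or oil vehicle; after
subcutaneous injection, where the spheres and the vehicle end up in the
tissue governs drug absorption. Propagation-based phase-contrast
micro-CT at a synchrotron can image both components simultaneously in
*ex vivo* tissue — the vehicle via an iodinated contrast spike, the
spheres even label-free via edge enhancement. `depotscope` rebuilds
that entire workflow as tested, ground-truthed code: a digital tissue
phantom, the acquisition physics, the projection pre-processing chain,
dual-branch tomographic reconstruction, semi-automated microsphere
detection, depot-geometry quantification, and the optical macrotomy
pipeline used as the comparison method.

It is aimed at imaging scientists and formulation researchers who want
to prototype or validate processing choices for this kind of experiment
without beamtime.

## The model in brief

* **Acquisition.** Parallel monochromatic beam (default 70 keV),
  line integrals `M = ∫mu dl`, `D = ∫delta dl`, exit wave
  `psi = exp(-M/2 - i(2π/λ)D)` propagated a distance `d` (default 1 m)
  with the angular-spectrum factor `exp(-iπλd f²)`; detector adds column
  gain (ring precursors), lens distortion or a two-camera split, and
  Poisson noise.
* **Pre-processing.** `(raw-dark)/(flat-dark)` → stitch/undistort →
  Fourier ring filter (Butterworth suppression of angle-constant,
  detector-varying components).
* **Reconstruction.** Filtered back projection (Ram-Lak) on `-ln(I/I0)`
  (attenuation branch), and on phase-retrieved projections
  `FT⁻¹[FT(I/I0)/(1+πλd(δ/β)f²)]` (phase branch).
* **Detection.** Candidates = (phase volume > tau_i) AND (|high-pass of
  attenuation volume| > tau_t); 26-connected components, size gates,
  cluster splitting at distance-transform maxima; one centroid per
  particle; precision/recall scoring against ground truth.
* **Quantification.** Vehicle mask by intensity threshold; depot
  volume, sphere–vehicle co-localisation, and radial spread about the
  needle axis (the tissue "sieving" signature is
  `p90(sphere radial distance) < max(vehicle radial extent)`).
* **Macrotomy.** Serial section photos aligned to reference points,
  thresholded, calibrated at 0.353 mm pixels × 180 um voxel depth
  (30 um sections, every sixth imaged), stained area/volume reported.

See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

```python
import numpy as np
from depotscope import (DetectionParams, acquire_scan, build_phantom,
                        combine_vertical, preprocess_scan,
                        reconstruct_volume, segment_vehicle)
from depotscope.detect import detect_microspheres, high_pass, tune_thresholds
from depotscope.presets import standard_phantom_spec, standard_detector
from depotscope.quantify import depot_metrics

ph = build_phantom(standard_phantom_spec(contrast=True))
scan = acquire_scan(ph, detector=standard_detector(), seed=1)
corr = preprocess_scan(scan)
vols = {b: combine_vertical(reconstruct_volume(corr, branch=b), [])
        for b in ("attenuation", "phase")}
pv, av = vols["phase"].sections, vols["attenuation"].sections

params, score = tune_thresholds(pv, high_pass(av, 1.5), ph.sphere_truth,
                                DetectionParams(0, 0, hp_sigma_px=1.5))
print(f"precision={score.precision:.3f} recall={score.recall:.3f}")

cm = detect_microspheres(pv, av, params)
vehicle = segment_vehicle(pv, np.percentile(pv, 97.5))
m = depot_metrics(vehicle, cm, ph.needle_axis, ph.voxel_size_um)
print(f"n_spheres={m.n_microspheres}  vehicle={m.vehicle_volume_mm3:.3f} mm^3")
print(f"sphere radial p90 = {m.radial_p90_um:.0f} um  "
      f"vehicle extent = {m.vehicle_extent_um:.0f} um")
```

Output:

```
precision=1.000 recall=0.975
n_spheres=39  vehicle=0.178 mm^3
sphere radial p90 = 644 um  vehicle extent = 866 um
```

The tuned combined threshold finds 39 of 40 simulated spheres with no
false positives; the top-2.5% intensity cut captures the brightest core
of the contrast depot, and the microspheres cluster within ~0.64 mm of
the needle track while the vehicle reaches ~0.87 mm — the sieving
pattern in which tissue retains particles near the injection site as
the vehicle migrates distally. (Sweeping the segmentation threshold
against a reference mask, as `scripts/acceptance.py` does, recovers the
full depot volume to within ~1%.)

A command-line interface mirrors the stages
(`depotscope phantom | simulate | preprocess | reconstruct | detect |
quantify | macrotomy | run`); `depotscope run --config run.yaml
--seed 1 --out runs/` executes the whole chain with a provenance
manifest.

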