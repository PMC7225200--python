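"""Standard desk-scale study configurations.

These presets define the reference simulation conditions used by the
validation suite: a layered porcine-subcutis phantom at the large-
field-of-view detector scale (21.5 um pixels), imaged at 70 keV with
1 m propagation distance. The grid is 28 x 160 x 160 voxels with 400
projections — a deliberate scale-down of the beamline's 3600-projection,
2560-column geometry that keeps every processing step identical while
fitting a workstation.

The injection site is placed off the tomographic rotation axis, as in
any real mount; this matters because sinogram-domain ring suppression
attenuates objects lying exactly on the axis.
"""

from __future__ import annotations

import numpy as np

from .simulate import DetectorConfig

__all__ = ["standard_phantom_spec", "sparse_phantom_spec",
           "standard_detector", "noisy_detector"]

#: depot centre (z, y, x) in voxels; ~31 voxels off the rotation axis
DEPOT_CENTRE = (14, 62, 105)


def standard_phantom_spec(contrast: bool = True, n_spheres: int = 40,
                          diameter_range_um: tuple[float, float] = (60.0, 100.0),
                          seed: int = 3, n_angles: int = 400) -> dict:
    """Layered-tissue phantom with an off-axis depot and clustered spheres.

    The vehicle depot is an ellipsoid (semi-axes 180 x 800 x 950 um)
    that extends much further in-plane than the microsphere cluster
    (sigma 300 um about the needle track), emulating vehicle migration
    to distal sites while the tissue sieves the spheres near the centre
    of injection. ``contrast`` selects the iodinated vehicle and
    contrast-adsorbing spheres; without it the label-free materials are
    used. The default diameter range covers the individually resolvable
    regime at 21.5 um pixels.
    """
    return {
        "grid": {"shape": [28, 160, 160]},
        "beam": {"energy_keV": 70.0, "propagation_distance_um": 1.0e6,
                 "pixel_size_um": 21.5, "n_angles": n_angles,
                 "angular_range_deg": 180.0},
        "outside": "air",
        "background": "agarose",
        "layers": [{"material": "adipose", "thickness_voxels": 14},
                   {"material": "muscle", "thickness_voxels": 14}],
        "depot": {"material": "vehicle_contrast" if contrast else "vehicle",
                  "centre_voxel": list(DEPOT_CENTRE),
                  "semi_axes_um": [180.0, 800.0, 950.0]},
        "needle": {"radius_um": 25.0},
        "spheres": {"n": n_spheres,
                    "diameter_range_um": list(diameter_range_um),
                    "placement": "clustered-near-axis",
                    "cluster_sigma_um": 300.0,
                    "material": "plg_contrast" if contrast else "plg",
                    "seed": seed},
    }


def sparse_phantom_spec(diameters_um: np.ndarray | None = None,
                        seed: int = 5, n_angles: int = 400) -> dict:
    """Isolated 60-90 um spheres on a staggered grid inside the depot.

    Used to measure the apparent (above-half-max) particle size without
    interference between touching spheres: centres are >= 14 voxels
    apart with randomised sub-voxel offsets so the measurement samples
    every partial-voxel alignment.
    """
    if diameters_um is None:
        diameters_um = np.linspace(60.0, 90.0, 16)
    rng = np.random.default_rng(seed)
    cz, cy, cx = DEPOT_CENTRE
    semi_y, semi_x = 800.0 / 21.5, 950.0 / 21.5
    centres = []
    k = 0
    for y in range(44, 96, 12):
        for x in range(76, 140, 14):
            if k >= len(diameters_um):
                break
            # keep the measurement clean: spheres well inside the depot
            # (not straddling its boundary) and away from the rotation
            # axis, where sinogram-domain ring suppression bites
            inside = ((y - cy) / semi_y) ** 2 + ((x - cx) / semi_x) ** 2
            if inside > 0.5 or np.hypot(y - 80, x - 80) < 8:
                continue
            centres.append((8.0 + (k % 3) * 6 + rng.uniform(-0.4, 0.4),
                            y + rng.uniform(-0.5, 0.5),
                            x + rng.uniform(-0.5, 0.5),
                            float(diameters_um[k]) / 2.0))
            k += 1
    spec = standard_phantom_spec(contrast=True, n_angles=n_angles)
    spec["spheres"] = {"n": len(centres), "placement": "fixed-list",
                       "fixed_centres": centres, "material": "plg_contrast"}
    return spec


def standard_detector(camera_model: str = "module1") -> DetectorConfig:
    """Noise-free detector with gain stripes and (module1) lens distortion."""
    return DetectorConfig(camera_model=camera_model, noise=False)


def noisy_detector(camera_model: str = "module1") -> DetectorConfig:
    """Detector with Poisson noise at the default flux (1e4 counts/pixel)."""
    return DetectorConfig(camera_model=camera_model, noise=True)
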