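"""Acquisition geometry for parallel-beam propagation-based imaging.

The defaults mirror a hard X-ray imaging branchline: monochromatic 70 keV
beam, 1 m sample-to-detector propagation distance (edge enhancement),
effective detector pixels of 18.5 or 21.5 um, and projections spread
uniformly over 180 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: hc in keV.um; lambda_um = HC_KEV_UM / energy_keV
HC_KEV_UM = 1.23984193e-3


@dataclass(frozen=True)
class BeamConfig:
    """Monochromatic parallel-beam scan geometry.

    Parameters
    ----------
    energy_keV : float
        Photon energy in keV.
    propagation_distance_um : float
        Sample-to-detector distance d in micrometres. ``0`` switches
        propagation-based phase contrast off (pure Beer-Lambert contact
        image).
    pixel_size_um : float
        Effective detector pixel size in micrometres; also the phantom
        voxel size (isotropic voxels).
    n_angles : int
        Number of projections, uniformly spaced on
        ``[0, angular_range_deg)`` endpoint-exclusive.
    angular_range_deg : float
        Angular span in degrees, in ``(0, 180]``.
    """

    energy_keV: float = 70.0
    propagation_distance_um: float = 1.0e6
    pixel_size_um: float = 21.5
    n_angles: int = 400
    angular_range_deg: float = 180.0

    def __post_init__(self) -> None:
        if self.energy_keV <= 0:
            raise ValueError("energy_keV must be positive")
        if self.propagation_distance_um < 0:
            raise ValueError("propagation_distance_um must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_angles < 2:
            raise ValueError("n_angles must be >= 2")
        if not 0 < self.angular_range_deg <= 180:
            raise ValueError("angular_range_deg must lie in (0, 180]")

    @property
    def wavelength_um(self) -> float:
        """Photon wavelength lambda = hc/E in micrometres."""
        return HC_KEV_UM / self.energy_keV

    def angles_deg(self) -> np.ndarray:
        """Projection angles in degrees, endpoint-exclusive."""
        return np.arange(self.n_angles) * (self.angular_range_deg / self.n_angles)

    def to_dict(self) -> dict:
        return {
            "energy_keV": self.energy_keV,
            "propagation_distance_um": self.propagation_distance_um,
            "pixel_size_um": self.pixel_size_um,
            "n_angles": self.n_angles,
            "angular_range_deg": self.angular_range_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BeamConfig":
        return cls(**{k: d[k] for k in (
            "energy_keV", "propagation_distance_um", "pixel_size_um",
            "n_angles", "angular_range_deg") if k in d})
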