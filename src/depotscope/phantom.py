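"""Digital tissue phantoms for injected microsphere suspension depots.

A phantom is a voxelised label grid (z, y, x) over a table of X-ray
materials, representing layered porcine subcutis (agarose embedding,
adipose and muscle layers) with an injected vehicle depot, a needle
track, and a population of 20-100 um PLG microspheres. It is the ground
truth against which every downstream stage (simulation, reconstruction,
detection, quantification) is validated.

Axis order is (z, y, x), 0-based, with voxel centres at integer
coordinates and isotropic voxels equal to the detector pixel size. The
tomographic rotation axis is z; tissue layers are stacked along z and
the needle is injected along z (perpendicular to the layers), so the
radial spread of formulation components about the needle axis is an
in-plane distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile
import yaml

from .beam import BeamConfig

__all__ = [
    "Material", "SpherePopulation", "TissuePhantom",
    "material_defaults", "build_phantom", "rasterize_spheres",
    "load_phantom_spec", "save_phantom", "load_phantom",
]


class PhantomConfigError(ValueError):
    """Bad phantom specification (unknown material, geometry outside grid)."""


class PlacementError(RuntimeError):
    """Sphere placement failed (overlap constraint unsatisfiable)."""


@dataclass(frozen=True)
class Material:
    """X-ray optical constants of one phantom material.

    delta and beta are the real decrement and imaginary part of the
    refractive index n = 1 - delta + i*beta; mu = 4*pi*beta/lambda is
    the linear attenuation coefficient in 1/um. The identity between mu
    and beta is enforced on construction.
    """

    name: str
    delta: float
    beta: float
    mu: float
    wavelength_um: float

    def __post_init__(self) -> None:
        if self.delta < 0 or self.beta < 0:
            raise ValueError(f"{self.name}: delta and beta must be >= 0")
        expected = 4.0 * np.pi * self.beta / self.wavelength_um
        scale = max(abs(expected), abs(self.mu), 1e-300)
        if abs(self.mu - expected) > 1e-9 * scale:
            raise ValueError(
                f"{self.name}: mu={self.mu} inconsistent with 4*pi*beta/lambda={expected}")

    @classmethod
    def from_mu(cls, name: str, mu: float, delta_over_beta: float,
                wavelength_um: float) -> "Material":
        """Build a material from attenuation mu (1/um) and a delta/beta ratio."""
        beta = mu * wavelength_um / (4.0 * np.pi)
        return cls(name=name, delta=delta_over_beta * beta, beta=beta,
                   mu=mu, wavelength_um=wavelength_um)


# Nominal linear attenuation coefficients (1/um) and delta/beta ratios at
# 70 keV. The printed literature gives no constants for these exact
# formulations, so the table is tuned for correct contrast ordering:
# adipose < aqueous vehicle ~ water/agarose < muscle < PLG, iodinated
# vehicle >= 3x tissue, and contrast-adsorbing spheres brighter than the
# spiked vehicle. All values are overridable per phantom spec.
_DEFAULT_MU_DB: dict[str, tuple[float, float]] = {
    "air":              (0.0,     0.0),
    "water":            (1.93e-5, 100.0),
    "agarose":          (1.95e-5, 100.0),
    "adipose":          (1.75e-5, 100.0),
    "muscle":           (2.05e-5, 100.0),
    "vehicle":          (1.97e-5, 100.0),   # aqueous CMC, unspiked
    "vehicle_mct":      (1.80e-5, 100.0),   # non-aqueous triglyceride
    "vehicle_contrast": (6.00e-5, 30.0),    # 10% iodinated contrast spike
    "plg":              (2.40e-5, 100.0),
    "plg_contrast":     (9.00e-5, 30.0),    # contrast surface-adsorption
}


def material_defaults(energy_keV: float = 70.0,
                      overrides: dict | None = None) -> dict[str, Material]:
    """Default material table (name -> Material) at the given energy.

    Attenuation values are nominal soft-tissue figures at 70 keV; the
    wavelength (hence beta and delta) follows the requested energy.
    ``overrides`` maps material name to a ``{"mu": ..., "delta_over_beta": ...}``
    dict, partially overriding the defaults or adding new materials.
    """
    if energy_keV <= 0:
        raise ValueError("energy_keV must be positive")
    lam = BeamConfig(energy_keV=energy_keV).wavelength_um
    table = dict(_DEFAULT_MU_DB)
    for name, ov in (overrides or {}).items():
        mu, db = table.get(name, (0.0, 0.0))
        table[name] = (float(ov.get("mu", mu)), float(ov.get("delta_over_beta", db)))
    return {name: Material.from_mu(name, mu, db, lam)
            for name, (mu, db) in table.items()}


@dataclass(frozen=True)
class SpherePopulation:
    """Specification of a microsphere population to place in a phantom.

    placement:
        ``"clustered-near-axis"`` draws in-plane radial offsets from a
        half-normal about the needle axis (the concentrated near-track
        deposition pattern); ``"uniform-in-depot"`` rejection-samples
        inside the depot mask; ``"fixed-list"`` uses ``fixed_centres``
        verbatim (centres in voxel units, radii in um).
    """

    n: int
    diameter_range_um: tuple[float, float] = (20.0, 100.0)
    placement: str = "clustered-near-axis"
    rng_seed: int = 0
    cluster_sigma_um: float = 400.0
    fixed_centres: tuple[tuple[float, float, float, float], ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.diameter_range_um
        if not 0 < lo <= hi:
            raise ValueError("diameter_range_um must satisfy 0 < min <= max")
        if self.placement not in ("clustered-near-axis", "uniform-in-depot",
                                  "fixed-list"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass
class TissuePhantom:
    """Voxelised phantom: label grid + material table + ground truth."""

    labels: np.ndarray                     # (z, y, x) int16
    materials: dict[int, Material]         # label -> material
    label_names: dict[str, int]            # material name -> label
    voxel_size_um: float
    beam: BeamConfig
    sphere_truth: list[tuple[float, float, float, float]] = field(default_factory=list)
    # (zc, yc, xc) voxel coords + radius_um per sphere
    needle_axis: tuple[np.ndarray, np.ndarray] | None = None  # (point, unit dir)
    depot_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        present = np.unique(self.labels)
        missing = [int(l) for l in present if int(l) not in self.materials]
        if missing:
            raise PhantomConfigError(f"labels without material entry: {missing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def _lookup(self, attr: str) -> np.ndarray:
        lut = np.zeros(max(self.materials) + 1)
        for lab, mat in self.materials.items():
            lut[lab] = getattr(mat, attr)
        return lut[self.labels]

    def mu_volume(self) -> np.ndarray:
        """Linear attenuation coefficient per voxel (1/um)."""
        return self._lookup("mu")

    def delta_volume(self) -> np.ndarray:
        """Refractive index decrement per voxel (dimensionless)."""
        return self._lookup("delta")


def _inscribed_circle_mask(ny: int, nx: int) -> np.ndarray:
    """In-plane mask of the circle inscribed in the slice (rotation axis
    at index N//2, matching the projector's centre convention)."""
    cy, cx = ny // 2, nx // 2
    yy, xx = np.mgrid[:ny, :nx]
    r = min(cy, cx, ny - 1 - cy, nx - 1 - cx)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


def load_phantom_spec(path) -> dict:
    """Read a phantom specification from a YAML file."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def build_phantom(spec: dict) -> TissuePhantom:
    """Build a voxelised phantom from a specification mapping.

    The spec declares the grid, beam geometry, tissue layers stacked
    along z, an ellipsoidal vehicle depot centred on the needle axis, a
    cylindrical needle track, and optionally a sphere population (placed
    by :func:`rasterize_spheres`). Deterministic given the spec's seed.

    Spec keys (all geometric lengths in um unless suffixed ``_voxel``)::

        grid:    {shape: [nz, ny, nx]}
        beam:    BeamConfig fields
        outside: material beyond the inscribed sample cylinder (default air)
        background: material inside the cylinder (default agarose)
        layers:  [{material, thickness_voxels}, ...]   # stacked along z
        depot:   {material, centre_voxel: [z,y,x], semi_axes_um: [az,ay,ax]}
        needle:  {radius_um, material}   # along z through depot centre
        spheres: SpherePopulation fields (+ material)
        materials: per-name {mu, delta_over_beta} overrides
        seed:    integer
    """
    beam = BeamConfig.from_dict(spec.get("beam", {}))
    nz, ny, nx = spec["grid"]["shape"]
    voxel = beam.pixel_size_um

    mats = material_defaults(beam.energy_keV, spec.get("materials"))

    used: list[str] = []

    def label_of(name: str) -> int:
        if name not in mats:
            raise PhantomConfigError(f"unknown material {name!r}")
        if name not in used:
            used.append(name)
        return used.index(name)

    outside = label_of(spec.get("outside", "air"))
    background = label_of(spec.get("background", "agarose"))

    labels = np.full((nz, ny, nx), outside, dtype=np.int16)
    circle = _inscribed_circle_mask(ny, nx)
    labels[:, circle] = background

    z0 = 0
    for layer in spec.get("layers", []):
        t = int(layer["thickness_voxels"])
        lab = label_of(layer["material"])
        labels[z0:z0 + t][:, circle] = lab
        z0 += t

    zz, yy, xx = np.mgrid[:nz, :ny, :nx].astype(float)

    depot_mask = np.zeros((nz, ny, nx), dtype=bool)
    needle_axis = None
    depot = spec.get("depot")
    if depot is not None:
        cz, cy, cx = depot["centre_voxel"]
        if not (0 <= cz < nz and 0 <= cy < ny and 0 <= cx < nx):
            raise PhantomConfigError("depot centre outside grid")
        az, ay, ax = (s / voxel for s in depot["semi_axes_um"])  # to voxels
        if cz + az > nz - 1 or cz - az < 0:
            raise PhantomConfigError("depot extends outside grid along z")
        depot_mask = (((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2
                      + ((xx - cx) / ax) ** 2) <= 1.0
        depot_mask &= circle[None, :, :]
        if not depot_mask.any():
            raise PhantomConfigError("depot does not intersect the sample")
        labels[depot_mask] = label_of(depot["material"])

        needle = spec.get("needle")
        if needle is not None:
            nr = needle.get("radius_um", 30.0) / voxel
            nlab = label_of(needle.get("material", depot["material"]))
            track = ((yy - cy) ** 2 + (xx - cx) ** 2 <= nr ** 2) & (zz <= cz)
            track &= circle[None, :, :]
            labels[track] = nlab
            depot_mask |= track
        needle_axis = (np.array([float(cz), float(cy), float(cx)]),
                       np.array([1.0, 0.0, 0.0]))

    materials = {i: mats[name] for i, name in enumerate(used)}
    ph = TissuePhantom(labels=labels, materials=materials,
                       label_names={n: i for i, n in enumerate(used)},
                       voxel_size_um=voxel, beam=beam,
                       needle_axis=needle_axis, depot_mask=depot_mask)

    sph = spec.get("spheres")
    if sph is not None and sph.get("n", 0) >= 0:
        sphere_material = sph.get("material", "plg")
        pop = SpherePopulation(
            n=int(sph.get("n", 0)),
            diameter_range_um=tuple(sph.get("diameter_range_um", (20.0, 100.0))),
            placement=sph.get("placement", "clustered-near-axis"),
            rng_seed=int(sph.get("seed", spec.get("seed", 0))),
            cluster_sigma_um=float(sph.get("cluster_sigma_um", 400.0)),
            fixed_centres=tuple(tuple(c) for c in sph.get("fixed_centres", ())),
        )
        ph = rasterize_spheres(ph, pop, material=sphere_material)
    return ph


def _draw_centres(ph: TissuePhantom, pop: SpherePopulation,
                  rng: np.random.Generator, max_retries: int = 2000):
    """Yield candidate (z, y, x, radius_um) tuples per placement mode."""
    nz, ny, nx = ph.shape
    lo, hi = pop.diameter_range_um
    if pop.placement == "fixed-list":
        for c in pop.fixed_centres:
            yield c
        return
    if pop.placement == "clustered-near-axis":
        if ph.needle_axis is None:
            raise PhantomConfigError("clustered-near-axis needs a needle axis")
        p0 = ph.needle_axis[0]
        zlo = max(1.0, p0[0] - 0.35 * nz)
        zhi = min(nz - 2.0, p0[0] + 0.35 * nz)
        for _ in range(max_retries):
            r_um = 0.5 * rng.uniform(lo, hi)
            rad = abs(rng.normal(0.0, pop.cluster_sigma_um)) / ph.voxel_size_um
            ang = rng.uniform(0, 2 * np.pi)
            yield (rng.uniform(zlo, zhi),
                   p0[1] + rad * np.sin(ang),
                   p0[2] + rad * np.cos(ang), r_um)
        return
    # uniform-in-depot
    if ph.depot_mask is None or not ph.depot_mask.any():
        raise PhantomConfigError("uniform-in-depot needs a nonempty depot")
    idx = np.argwhere(ph.depot_mask)
    for _ in range(max_retries):
        z, y, x = idx[rng.integers(len(idx))] + rng.uniform(-0.5, 0.5, 3)
        yield (z, y, x, 0.5 * rng.uniform(lo, hi))


def rasterize_spheres(phantom: TissuePhantom, population: SpherePopulation,
                      material: str = "plg") -> TissuePhantom:
    """Place non-overlapping spheres and write their labels into the grid.

    A voxel is labelled when its centre lies within a sphere's radius
    (no anti-aliasing). Placement rejects candidates that overlap an
    accepted sphere (centre distance < sum of radii) or protrude outside
    the sample cylinder. Raises :class:`PlacementError` naming the
    achieved count when the requested n cannot be placed.
    """
    mats = material_defaults(phantom.beam.energy_keV)
    if material in phantom.label_names:
        lab = phantom.label_names[material]
    else:
        if material not in mats:
            raise PhantomConfigError(f"unknown material {material!r}")
        lab = max(phantom.materials) + 1
        phantom.materials[lab] = mats[material]
        phantom.label_names[material] = lab

    nz, ny, nx = phantom.shape
    voxel = phantom.voxel_size_um
    circle_r = min(ny // 2, nx // 2, ny - 1 - ny // 2, nx - 1 - nx // 2)
    cy, cx = ny // 2, nx // 2

    accepted: list[tuple[float, float, float, float]] = []
    fixed = population.placement == "fixed-list"
    for (z, y, x, r_um) in _draw_centres(phantom, population, np.random.default_rng(
            population.rng_seed)):
        if len(accepted) >= population.n:
            break
        r_vox = r_um / voxel
        in_grid = (r_vox <= z <= nz - 1 - r_vox
                   and np.hypot(y - cy, x - cx) + r_vox <= circle_r)
        overlap = any(np.sqrt((z - az) ** 2 + (y - ay) ** 2 + (x - ax) ** 2)
                      < (r_um + ar) / voxel
                      for az, ay, ax, ar in accepted)
        if fixed and (not in_grid or overlap):
            raise PlacementError(
                f"fixed sphere at ({z},{y},{x}) invalid after {len(accepted)} placed")
        if in_grid and not overlap:
            accepted.append((float(z), float(y), float(x), float(r_um)))

    if len(accepted) < population.n:
        raise PlacementError(
            f"placed {len(accepted)} of {population.n} spheres before retry limit")

    for (z, y, x, r_um) in accepted:
        r_vox = r_um / voxel
        zlo, zhi = int(np.floor(z - r_vox)), int(np.ceil(z + r_vox)) + 1
        ylo, yhi = int(np.floor(y - r_vox)), int(np.ceil(y + r_vox)) + 1
        xlo, xhi = int(np.floor(x - r_vox)), int(np.ceil(x + r_vox)) + 1
        sz, sy, sx = np.mgrid[zlo:zhi, ylo:yhi, xlo:xhi]
        inside = ((sz - z) ** 2 + (sy - y) ** 2 + (sx - x) ** 2) <= r_vox ** 2
        phantom.labels[zlo:zhi, ylo:yhi, xlo:xhi][inside] = lab

    phantom.sphere_truth.extend(accepted)
    return phantom


def save_phantom(phantom: TissuePhantom, out_dir) -> None:
    """Write the label volume (multi-page TIFF) and a JSON sidecar."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "labels.tif", phantom.labels)
    sidecar = {
        "voxel_size_um": phantom.voxel_size_um,
        "beam": phantom.beam.to_dict(),
        "materials": {str(lab): {"name": m.name, "mu": m.mu, "delta": m.delta,
                                 "beta": m.beta}
                      for lab, m in phantom.materials.items()},
        "label_names": phantom.label_names,
        "sphere_truth": [list(s) for s in phantom.sphere_truth],
        "needle_axis": None if phantom.needle_axis is None else
            [phantom.needle_axis[0].tolist(), phantom.needle_axis[1].tolist()],
    }
    (out / "phantom.json").write_text(json.dumps(sidecar, indent=1))
    if phantom.depot_mask is not None:
        tifffile.imwrite(out / "depot_mask.tif",
                         phantom.depot_mask.astype(np.uint8))


def load_phantom(in_dir) -> TissuePhantom:
    """Load a phantom written by :func:`save_phantom`."""
    from pathlib import Path
    src = Path(in_dir)
    labels = tifffile.imread(src / "labels.tif")
    meta = json.loads((src / "phantom.json").read_text())
    beam = BeamConfig.from_dict(meta["beam"])
    lam = beam.wavelength_um
    materials = {int(k): Material(name=v["name"], delta=v["delta"],
                                  beta=v["beta"], mu=v["mu"], wavelength_um=lam)
                 for k, v in meta["materials"].items()}
    depot_path = src / "depot_mask.tif"
    depot = tifffile.imread(depot_path).astype(bool) if depot_path.exists() else None
    axis = meta.get("needle_axis")
    return TissuePhantom(
        labels=labels, materials=materials, label_names=meta["label_names"],
        voxel_size_um=meta["voxel_size_um"], beam=beam,
        sphere_truth=[tuple(s) for s in meta["sphere_truth"]],
        needle_axis=None if axis is None else (np.array(axis[0]), np.array(axis[1])),
        depot_mask=depot)
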