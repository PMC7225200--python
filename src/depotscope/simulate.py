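"""Forward simulation of parallel-beam propagation-based phase-contrast
acquisition.

The chain per tomographic slice is: line integrals of mu and delta
(rotate-and-sum projection), free-space Fresnel propagation of the exit
wave over the sample-to-detector distance (edge enhancement), then
detector effects — per-column gain stripes (the source of ring
artifacts), radial lens distortion (single-camera "module1" path) or a
two-camera split with overlap ("lfv" path), and Poisson photon noise.

Propagation is one-dimensional per sinogram row, which is exact for a
parallel synchrotron beam when slices are independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.transform import radon

from .beam import BeamConfig
from .phantom import TissuePhantom

__all__ = [
    "DetectorConfig", "ProjectionSet", "Scan",
    "project_slice", "fresnel_propagate", "apply_detector", "acquire_scan",
    "distort_frame", "save_scan", "load_scan",
]


class GeometryError(ValueError):
    pass


class DetectorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DetectorConfig:
    """Detector model applied after propagation.

    camera_model "module1" is a single camera with radial lens
    distortion; "lfv" is two side-by-side cameras producing two
    overlapping sub-frames that must be stitched downstream.
    gain_sigma sets the per-column multiplicative gain spread (rings);
    flux is the mean flat-field counts per pixel; noise=False disables
    Poisson statistics (infinite-flux limit). k1, k2 are the forward
    radial distortion coefficients r_d = r_u (1 + k1 r_u^2 + k2 r_u^4).
    """

    camera_model: str = "module1"
    gain_sigma: float = 0.02
    gain_drift_sigma: float = 0.005
    flux: float = 1.0e4
    noise: bool = False
    dark_level: float = 10.0
    k1: float = 1.0e-8
    k2: float = 0.0
    lfv_overlap_px: int = 32
    n_flats: int = 4
    n_darks: int = 4

    def __post_init__(self) -> None:
        if self.camera_model not in ("module1", "lfv"):
            raise DetectorConfigError(f"unknown camera_model {self.camera_model!r}")
        if self.flux <= 0:
            raise DetectorConfigError("flux must be positive")


@dataclass
class ProjectionSet:
    """Raw frames for one vertical sub-scan.

    images has shape (n_angles, rows, cols) for module1, or is a pair
    of such arrays (left, right) for the lfv camera. flats/darks are
    stacks of reference frames with matching detector shape.
    """

    images: np.ndarray | tuple[np.ndarray, np.ndarray]
    flats: np.ndarray | tuple[np.ndarray, np.ndarray]
    darks: np.ndarray | tuple[np.ndarray, np.ndarray]
    angles_deg: np.ndarray
    beam: BeamConfig
    camera_model: str
    gain_map: np.ndarray        # per-column gain seen by the projections
    flat_gain_map: np.ndarray   # per-column gain seen by the flats
    distortion_coeffs: tuple[float, float]
    row_range: tuple[int, int]  # phantom z rows covered [lo, hi)

    def __post_init__(self) -> None:
        frames = self.images[0] if isinstance(self.images, tuple) else self.images
        if len(frames) != len(self.angles_deg):
            raise ValueError("one frame per angle required")


@dataclass
class Scan:
    """A full acquisition: 1-4 vertical sub-scans plus ground truth."""

    subscans: list[ProjectionSet]
    overlap_rows: int
    lfv_overlap_px: int = 0
    phantom: TissuePhantom | None = None


def project_slice(mu_slice: np.ndarray, delta_slice: np.ndarray,
                  angles_deg: np.ndarray, beam: BeamConfig
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Parallel-beam line integrals of mu and delta for one slice.

    Rotate-and-sum projection with linear interpolation, rotation axis
    at index N//2. Returns (mu_int, delta_int) of shape
    (n_angles, n_detector) in units of mu*um and delta*um. The slice
    must be square; material outside the inscribed circle is ignored.
    """
    if mu_slice.shape[0] != mu_slice.shape[1]:
        raise GeometryError("slice must be square (rotation axis at centre)")
    if mu_slice.shape != delta_slice.shape:
        raise GeometryError("mu and delta slices must be congruent")
    theta = np.asarray(angles_deg, dtype=float)
    mu_int = radon(mu_slice, theta=theta, circle=True).T * beam.pixel_size_um
    delta_int = radon(delta_slice, theta=theta, circle=True).T * beam.pixel_size_um
    return mu_int, delta_int


def fresnel_propagate(mu_integral: np.ndarray, delta_integral: np.ndarray,
                      beam: BeamConfig) -> np.ndarray:
    """Propagate the exit wave to the detector; return intensity I/I0.

    The monochromatic exit wave psi = exp(-mu_int/2 - i (2 pi/lambda)
    delta_int) is propagated by the angular-spectrum method with
    transfer function exp(-i pi lambda d f^2) along the last axis
    (detector columns of one sinogram row). With d = 0 the contact
    image exp(-mu_int) is returned exactly.
    """
    d = beam.propagation_distance_um
    if d == 0:
        return np.exp(-mu_integral)
    lam = beam.wavelength_um
    psi = np.exp(-mu_integral / 2.0 - 1j * (2.0 * np.pi / lam) * delta_integral)
    f = np.fft.fftfreq(psi.shape[-1], d=beam.pixel_size_um)
    H = np.exp(-1j * np.pi * lam * d * f ** 2)
    psi_d = np.fft.ifft(np.fft.fft(psi, axis=-1) * H, axis=-1)
    return np.abs(psi_d) ** 2


def _inverse_radius_table(k1: float, k2: float, r_max: float,
                          n: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Tabulate r_u as a function of r_d by sampling the forward polynomial."""
    r_u = np.linspace(0.0, 1.5 * r_max, n)
    r_d = r_u * (1.0 + k1 * r_u ** 2 + k2 * r_u ** 4)
    if np.any(np.diff(r_d) <= 0):
        raise DetectorConfigError("distortion polynomial not invertible over frame")
    return r_d, r_u


def distort_frame(frame: np.ndarray, k1: float, k2: float) -> np.ndarray:
    """Apply forward radial lens distortion about the frame centre.

    The detector samples the ideal image at the undistorted radius
    r_u = f^{-1}(r_d); the inverse is tabulated numerically and
    interpolated, then the image resampled bilinearly.
    """
    if k1 == 0 and k2 == 0:
        return frame.copy()
    from scipy.ndimage import map_coordinates
    ny, nx = frame.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[:ny, :nx]
    dy, dx = yy - cy, xx - cx
    r_d = np.hypot(dy, dx)
    tab_rd, tab_ru = _inverse_radius_table(k1, k2, float(r_d.max()))
    r_u = np.interp(r_d, tab_rd, tab_ru)
    scale = np.where(r_d > 0, r_u / np.maximum(r_d, 1e-12), 1.0)
    coords = np.array([cy + dy * scale, cx + dx * scale])
    return map_coordinates(frame, coords, order=1, mode="nearest")


def split_lfv(frame: np.ndarray, overlap_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Split a frame into two overlapping camera sub-frames.

    Widths satisfy w_left + w_right - overlap = full width, with the
    left camera taking the extra column when the padded width is odd.
    """
    w = frame.shape[-1]
    if overlap_px >= w or overlap_px < 1:
        raise DetectorConfigError("lfv overlap must be in [1, frame width)")
    w_left = (w + overlap_px + 1) // 2
    w_right = w + overlap_px - w_left
    return frame[..., :w_left].copy(), frame[..., w - w_right:].copy()


def apply_detector(intensity: np.ndarray, gain_map: np.ndarray,
                   config: DetectorConfig,
                   rng: np.random.Generator | None = None
                   ) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Convert ideal detector-plane intensity (I/I0) into raw frames.

    Applies per-column gain, scales to the configured flux, applies
    forward lens distortion (module1) or splits into two overlapping
    sub-frames (lfv), and optionally draws Poisson counts. Deterministic
    given the generator state.
    """
    if np.any(gain_map <= 0):
        raise DetectorConfigError("gain_map must be positive")
    counts = intensity * gain_map[np.newaxis, :] * config.flux + config.dark_level
    if config.camera_model == "module1":
        counts = distort_frame(counts, config.k1, config.k2)
        if config.noise:
            if rng is None:
                raise ValueError("noise enabled but no rng supplied")
            counts = rng.poisson(counts).astype(float)
        return counts
    left, right = split_lfv(counts, config.lfv_overlap_px)
    if config.noise:
        if rng is None:
            raise ValueError("noise enabled but no rng supplied")
        left = rng.poisson(left).astype(float)
        right = rng.poisson(right).astype(float)
    return left, right


def _subscan_ranges(nz: int, n_subscans: int, overlap_rows: int
                    ) -> list[tuple[int, int]]:
    """Row ranges of the vertical sub-scans covering [0, nz) with the
    requested pairwise overlap."""
    if n_subscans == 1:
        return [(0, nz)]
    rows = (nz + (n_subscans - 1) * overlap_rows + n_subscans - 1) // n_subscans
    ranges = []
    for i in range(n_subscans):
        lo = i * (rows - overlap_rows)
        hi = min(lo + rows, nz)
        ranges.append((lo, hi))
    ranges[-1] = (max(0, nz - rows), nz)
    return ranges


def acquire_scan(phantom: TissuePhantom, beam: BeamConfig | None = None,
                 detector: DetectorConfig | None = None,
                 seed: int = 0, n_subscans: int = 1,
                 overlap_rows: int = 16) -> Scan:
    """Simulate a full tomographic acquisition of a phantom.

    Each vertical sub-scan images a contiguous range of phantom z rows;
    consecutive sub-scans overlap by ``overlap_rows``. Per sub-scan the
    detector sees frames of shape (rows, n_x) per angle, plus flat
    (beam-only) and dark (shutter-closed) reference frames. All
    randomness (gain stripes, noise) is driven by ``seed``.
    """
    beam = beam or phantom.beam
    detector = detector or DetectorConfig()
    if abs(beam.pixel_size_um - phantom.voxel_size_um) > 1e-9:
        raise GeometryError("phantom voxel size must equal detector pixel size")

    rng = np.random.default_rng(seed)
    nz, ny, nx = phantom.shape
    angles = beam.angles_deg()
    mu_vol = phantom.mu_volume()
    delta_vol = phantom.delta_volume()
    flat_gain = 1.0 + detector.gain_sigma * rng.standard_normal(nx)
    flat_gain = np.clip(flat_gain, 0.5, 2.0)
    # column gain drifts slightly between flat acquisition and the scan;
    # the residual after flat-fielding is what produces ring artifacts
    gain_map = flat_gain * (1.0 + detector.gain_drift_sigma
                            * rng.standard_normal(nx))

    # per-slice sinogram-domain intensity, shared across sub-scans
    intens = np.empty((nz, len(angles), nx))
    for z in range(nz):
        mu_int, d_int = project_slice(mu_vol[z], delta_vol[z], angles, beam)
        intens[z] = fresnel_propagate(mu_int, d_int, beam)

    subscans = []
    for (lo, hi) in _subscan_ranges(nz, n_subscans, overlap_rows):
        frames_ideal = np.transpose(intens[lo:hi], (1, 0, 2))  # (angle, row, col)
        proj = [apply_detector(fr, gain_map, detector, rng) for fr in frames_ideal]
        ones = np.ones((hi - lo, nx))
        flats = [apply_detector(ones, flat_gain, detector, rng)
                 for _ in range(detector.n_flats)]
        # darks: shutter closed, only the dark level (+ noise)
        darks = []
        for _ in range(detector.n_darks):
            d = np.full((hi - lo, nx), float(detector.dark_level))
            if detector.noise:
                d = rng.poisson(d).astype(float)
            if detector.camera_model == "lfv":
                d = split_lfv(d, detector.lfv_overlap_px)
            darks.append(d)
        if detector.camera_model == "lfv":
            images = (np.stack([p[0] for p in proj]), np.stack([p[1] for p in proj]))
            flats_s = (np.stack([f[0] for f in flats]), np.stack([f[1] for f in flats]))
            darks_s = (np.stack([d[0] for d in darks]), np.stack([d[1] for d in darks]))
        else:
            images = np.stack(proj)
            flats_s = np.stack(flats)
            darks_s = np.stack(darks)
        subscans.append(ProjectionSet(
            images=images, flats=flats_s, darks=darks_s, angles_deg=angles,
            beam=beam, camera_model=detector.camera_model, gain_map=gain_map,
            flat_gain_map=flat_gain,
            distortion_coeffs=(detector.k1, detector.k2), row_range=(lo, hi)))
    return Scan(subscans=subscans,
                overlap_rows=overlap_rows if n_subscans > 1 else 0,
                lfv_overlap_px=(detector.lfv_overlap_px
                                if detector.camera_model == "lfv" else 0),
                phantom=phantom)


def save_scan(scan: Scan, out_dir) -> None:
    """Write projection/flat/dark TIFFs and a scan.json metadata sidecar."""
    out = Path(out_dir)
    for si, ps in enumerate(scan.subscans):
        sub = out / f"subscan_{si:02d}"
        sub.mkdir(parents=True, exist_ok=True)
        cams = ps.images if isinstance(ps.images, tuple) else (ps.images,)
        flats = ps.flats if isinstance(ps.flats, tuple) else (ps.flats,)
        darks = ps.darks if isinstance(ps.darks, tuple) else (ps.darks,)
        for ci, (imgs, fls, dks) in enumerate(zip(cams, flats, darks)):
            tag = f"_cam{ci}" if len(cams) > 1 else ""
            for ai, frame in enumerate(imgs):
                tifffile.imwrite(sub / f"proj{tag}_{ai:04d}.tif",
                                 frame.astype(np.float32))
            for fi, fr in enumerate(fls):
                tifffile.imwrite(sub / f"flat{tag}_{fi:02d}.tif",
                                 fr.astype(np.float32))
            for di, dr in enumerate(dks):
                tifffile.imwrite(sub / f"dark{tag}_{di:02d}.tif",
                                 dr.astype(np.float32))
    meta = {
        "beam": scan.subscans[0].beam.to_dict(),
        "camera_model": scan.subscans[0].camera_model,
        "angles_deg": scan.subscans[0].angles_deg.tolist(),
        "gain_map": scan.subscans[0].gain_map.tolist(),
        "flat_gain_map": scan.subscans[0].flat_gain_map.tolist(),
        "distortion_coeffs": list(scan.subscans[0].distortion_coeffs),
        "row_ranges": [list(ps.row_range) for ps in scan.subscans],
        "overlap_rows": scan.overlap_rows,
        "lfv_overlap_px": scan.lfv_overlap_px,
        "n_subscans": len(scan.subscans),
    }
    (out / "scan.json").write_text(json.dumps(meta, indent=1))


def load_scan(in_dir) -> Scan:
    """Load a scan written by :func:`save_scan` (ground truth not restored)."""
    src = Path(in_dir)
    meta = json.loads((src / "scan.json").read_text())
    beam = BeamConfig.from_dict(meta["beam"])
    subscans = []
    for si, rr in enumerate(meta["row_ranges"]):
        sub = src / f"subscan_{si:02d}"
        n_cams = 2 if meta["camera_model"] == "lfv" else 1
        per_cam = []
        for ci in range(n_cams):
            tag = f"_cam{ci}" if n_cams > 1 else ""
            imgs = np.stack([tifffile.imread(p) for p in
                             sorted(sub.glob(f"proj{tag}_*.tif"))])
            fls = np.stack([tifffile.imread(p) for p in
                            sorted(sub.glob(f"flat{tag}_*.tif"))])
            dks = np.stack([tifffile.imread(p) for p in
                            sorted(sub.glob(f"dark{tag}_*.tif"))])
            per_cam.append((imgs, fls, dks))
        if n_cams == 2:
            images = (per_cam[0][0], per_cam[1][0])
            flats = (per_cam[0][1], per_cam[1][1])
            darks = (per_cam[0][2], per_cam[1][2])
        else:
            images, flats, darks = per_cam[0]
        subscans.append(ProjectionSet(
            images=images, flats=flats, darks=darks,
            angles_deg=np.array(meta["angles_deg"]), beam=beam,
            camera_model=meta["camera_model"],
            gain_map=np.array(meta["gain_map"]),
            flat_gain_map=np.array(meta["flat_gain_map"]),
            distortion_coeffs=tuple(meta["distortion_coeffs"]),
            row_range=tuple(rr)))
    return Scan(subscans=subscans, overlap_rows=meta["overlap_rows"],
                lfv_overlap_px=meta.get("lfv_overlap_px", 0))
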