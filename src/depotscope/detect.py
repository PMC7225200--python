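"""Semi-automated microsphere detection in reconstructed volumes.

Individual 20-100 um PLG microspheres appear as 3-4 pixel bright blobs.
Intensity thresholding alone cannot separate them from tissue; the
detector therefore combines an intensity criterion on the phase-
retrieved volume with a texture criterion — the magnitude of a
high-pass filtered attenuation volume, which concentrates the edge-
enhancement energy that small spheres carry. Candidate voxels are
grouped into 26-connected components, size-gated, and reduced to a
binary map with one marked voxel at each component centroid.

The manual false-positive review of the original workflow is replaced
by :func:`score_detection`, which matches detected centres one-to-one
against ground truth; :func:`tune_thresholds` plays the role of the
per-sample manual threshold choice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "DetectionParams", "CentreMap", "DetectionScore",
    "high_pass", "combined_threshold", "extract_centres", "score_detection",
    "suggest_thresholds", "tune_thresholds", "detect_microspheres",
    "apparent_extent_px",
]


class ContractError(ValueError):
    pass


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds and gates for combined intensity + texture detection.

    tau_intensity applies to the phase-branch volume, tau_texture to the
    |high-pass| of the attenuation branch (Gaussian scale hp_sigma_px).
    Components smaller than min_voxels or with a bounding-box extent
    above max_diameter_px (default 5 ~ ceil(100 um / 21.5 um pixel)) are
    discarded. roi_list holds [z0,z1,y0,y1,x0,x1] half-open boxes; empty
    means the whole volume.
    """

    tau_intensity: float
    tau_texture: float
    hp_sigma_px: float = 2.0
    min_voxels: int = 1
    max_diameter_px: int = 5
    min_separation_px: float = 3.0
    roi_list: tuple[tuple[int, int, int, int, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.max_diameter_px < 1:
            raise ValueError("max_diameter_px must be >= 1")
        if np.isnan(self.tau_intensity) or np.isnan(self.tau_texture):
            raise ValueError("thresholds must not be NaN")


@dataclass
class CentreMap:
    """Binary centre map plus per-component metadata.

    centres rows are (z, y, x, voxel_count, mean_phase, mean_atten);
    binary marks exactly one voxel per detected microsphere.
    """

    binary: np.ndarray
    centres: list[tuple[int, int, int, int, float, float]]
    params: DetectionParams

    def __post_init__(self) -> None:
        if int(np.count_nonzero(self.binary)) != len(self.centres):
            raise ValueError("binary marks and centre list disagree")

    def coordinates(self) -> np.ndarray:
        """(n, 3) array of centre voxel coordinates."""
        if not self.centres:
            return np.empty((0, 3))
        return np.array([c[:3] for c in self.centres], dtype=float)


@dataclass(frozen=True)
class DetectionScore:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f1: float
    match_radius_px: float


def high_pass(volume: np.ndarray, sigma_px: float = 2.0) -> np.ndarray:
    """Volume minus its Gaussian-smoothed copy (zero mean over flats)."""
    if sigma_px <= 0:
        raise ContractError("sigma_px must be positive")
    return volume - ndimage.gaussian_filter(volume, sigma_px)


def _roi_mask(shape: tuple[int, ...],
              roi_list: tuple[tuple[int, int, int, int, int, int], ...]
              ) -> np.ndarray | None:
    if not roi_list:
        return None
    mask = np.zeros(shape, dtype=bool)
    for (z0, z1, y0, y1, x0, x1) in roi_list:
        mask[z0:z1, y0:y1, x0:x1] = True
    return mask


def combined_threshold(phase_vol: np.ndarray, texture_vol: np.ndarray,
                       params: DetectionParams) -> np.ndarray:
    """Candidate voxels passing both the intensity and texture criteria.

    candidate = (phase > tau_intensity) AND (|texture| > tau_texture),
    restricted to the ROI boxes when any are given.
    """
    if phase_vol.shape != texture_vol.shape:
        raise ContractError("phase and texture volumes must be congruent")
    cand = (phase_vol > params.tau_intensity) \
        & (np.abs(texture_vol) > params.tau_texture)
    roi = _roi_mask(phase_vol.shape, params.roi_list)
    if roi is not None:
        cand &= roi
    return cand


def _split_component(comp: np.ndarray) -> list[np.ndarray]:
    """Split a touching-sphere component at distance-transform maxima.

    Clustered deposition routinely leaves microspheres in contact, so
    their candidate blobs 26-connect into one component. The Euclidean
    distance transform of the component peaks once per sphere core; a
    watershed from those peaks recovers the individuals. Returns the
    list of sub-component masks (length 1 if no split is found).
    """
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed
    edt = ndimage.distance_transform_edt(np.pad(comp, 1))[
        tuple(slice(1, -1) for _ in range(comp.ndim))]
    # resolvable spheres (>= 60 um at ~20 um pixels) sit >= 3 px apart;
    # closer distance-transform peaks are one particle, not two
    peaks = peak_local_max(edt, min_distance=2, labels=comp,
                           exclude_border=False)
    if len(peaks) < 2:
        return [comp]
    markers = np.zeros(comp.shape, dtype=int)
    for m, (z, y, x) in enumerate(peaks, start=1):
        markers[z, y, x] = m
    regions = watershed(-edt, markers, mask=comp)
    return [regions == m for m in range(1, len(peaks) + 1)]


def extract_centres(candidates: np.ndarray, params: DetectionParams,
                    phase_vol: np.ndarray | None = None,
                    atten_vol: np.ndarray | None = None) -> CentreMap:
    """Reduce a candidate volume to one marked centre per microsphere.

    26-connected component labelling with size gating: components with
    fewer than min_voxels voxels are noise and dropped; components with
    a bounding-box extent above 2x max_diameter_px in any axis are
    elongated interface artifacts (tissue boundaries) and rejected;
    components between max_diameter_px and that limit are candidate
    touching-sphere clusters and are split at distance-transform maxima,
    each sub-component kept if it fits the single-sphere gate. The
    centre is the voxel-rounded centroid of each (sub-)component.
    """
    if candidates.dtype != bool:
        raise ContractError("candidates must be boolean")
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(candidates, structure=structure)
    binary = np.zeros_like(candidates)
    centres: list[tuple[int, int, int, int, float, float]] = []
    if not n:
        return CentreMap(binary=binary, centres=centres, params=params)

    def emit(comp: np.ndarray, origin: tuple[int, int, int]) -> None:
        count = int(comp.sum())
        if count < params.min_voxels:
            return
        zz, yy, xx = np.nonzero(comp)
        cz = int(round(zz.mean())) + origin[0]
        cy = int(round(yy.mean())) + origin[1]
        cx = int(round(xx.mean())) + origin[2]
        sl = tuple(slice(o, o + s) for o, s in zip(origin, comp.shape))
        mean_phase = float(phase_vol[sl][comp].mean()) \
            if phase_vol is not None else float("nan")
        mean_atten = float(atten_vol[sl][comp].mean()) \
            if atten_vol is not None else float("nan")
        binary[cz, cy, cx] = True
        centres.append((cz, cy, cx, count, mean_phase, mean_atten))

    for i, sl in enumerate(ndimage.find_objects(labels), start=1):
        extent = max(s.stop - s.start for s in sl)
        comp = labels[sl] == i
        origin = (sl[0].start, sl[1].start, sl[2].start)
        if extent > 2 * params.max_diameter_px:
            continue
        if extent <= params.max_diameter_px:
            emit(comp, origin)
            continue
        for sub in _split_component(comp):
            coords = np.nonzero(sub)
            sub_extent = max(int(c.max() - c.min()) + 1 for c in coords)
            if sub_extent <= params.max_diameter_px:
                emit(sub, origin)

    # merge fragments of one particle: two resolvable spheres cannot sit
    # closer than the minimum particle diameter, so nearer centres are
    # duplicate detections (keep the larger component). Non-maximum
    # suppression over a KD-tree keeps this linearithmic.
    if params.min_separation_px > 0 and len(centres) > 1:
        from scipy.spatial import cKDTree
        order = sorted(range(len(centres)), key=lambda i: -centres[i][3])
        pts = np.array([c[:3] for c in centres], dtype=float)
        tree = cKDTree(pts)
        suppressed = np.zeros(len(centres), dtype=bool)
        keep = []
        for i in order:
            if suppressed[i]:
                binary[centres[i][0], centres[i][1], centres[i][2]] = False
                continue
            keep.append(centres[i])
            for j in tree.query_ball_point(pts[i], params.min_separation_px):
                if j != i:
                    suppressed[j] = True
        centres = keep
    return CentreMap(binary=binary, centres=centres, params=params)


def score_detection(centre_map: CentreMap | np.ndarray,
                    sphere_truth: list | np.ndarray,
                    match_radius_px: float = 3.0) -> DetectionScore:
    """Score detected centres against ground-truth sphere centres.

    Greedy one-to-one nearest-neighbour matching: candidate pairs within
    the match radius are matched in order of increasing distance, each
    truth and each detection used at most once. precision = TP/(TP+FP),
    recall = TP/(TP+FN), both 0 when their denominator is 0.
    """
    if match_radius_px <= 0:
        raise ContractError("match_radius_px must be positive")
    det = centre_map.coordinates() if isinstance(centre_map, CentreMap) \
        else np.asarray(centre_map, dtype=float).reshape(-1, 3)
    truth = np.asarray([t[:3] for t in sphere_truth], dtype=float) \
        if len(sphere_truth) else np.empty((0, 3))
    pairs = []
    for i in range(len(det)):
        d = np.linalg.norm(truth - det[i], axis=1) if len(truth) else np.empty(0)
        for j in np.nonzero(d <= match_radius_px)[0]:
            pairs.append((d[j], i, j))
    pairs.sort(key=lambda p: p[0])
    used_det: set[int] = set()
    used_truth: set[int] = set()
    for _, i, j in pairs:
        if i not in used_det and j not in used_truth:
            used_det.add(i)
            used_truth.add(j)
    tp = len(used_det)
    fp = len(det) - tp
    fn = len(truth) - tp
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return DetectionScore(tp, fp, fn, precision, recall, f1, match_radius_px)


def suggest_thresholds(phase_vol: np.ndarray, texture_vol: np.ndarray,
                       roi_list=()) -> tuple[float, float]:
    """Otsu-based starting thresholds over the ROI histograms.

    A convenience replacing the first manual threshold guess; per-sample
    refinement (manual or :func:`tune_thresholds`) is still expected.
    """
    from skimage.filters import threshold_otsu
    roi = _roi_mask(phase_vol.shape, tuple(tuple(r) for r in roi_list))
    pv = phase_vol[roi] if roi is not None else phase_vol.ravel()
    tv = np.abs(texture_vol[roi] if roi is not None else texture_vol.ravel())
    return float(threshold_otsu(pv)), float(threshold_otsu(tv))


def tune_thresholds(phase_vol: np.ndarray, texture_vol: np.ndarray,
                    sphere_truth, params: DetectionParams,
                    match_radius_px: float = 3.0,
                    n_grid: int = 10) -> tuple[DetectionParams, DetectionScore]:
    """Search tau_intensity and tau_texture for maximum F1.

    Stands in for the per-sample manual threshold determination: a
    coarse upper-quantile grid over both volumes followed by a local
    refinement around the best coarse cell. Requires ground truth, so
    it applies to simulated scans (or any scan with an independently
    annotated truth set).
    """
    abs_tex = np.abs(texture_vol)

    def evaluate(ti: float, tt: float):
        p = replace(params, tau_intensity=float(ti), tau_texture=float(tt))
        cand = combined_threshold(phase_vol, texture_vol, p)
        cm = extract_centres(cand, p)
        sc = score_detection(cm, sphere_truth, match_radius_px)
        return (sc.f1, min(sc.precision, sc.recall)), p, sc

    q = np.linspace(95.0, 99.95, n_grid)
    qi_grid = dict(zip(q, np.percentile(phase_vol, q)))
    qt_grid = dict(zip(q, np.percentile(abs_tex, q)))
    best = None
    best_q = None
    for qi, ti in qi_grid.items():
        for qt, tt in qt_grid.items():
            cand = evaluate(ti, tt)
            if best is None or cand[0] > best[0]:
                best, best_q = cand, (qi, qt)

    # refine on a finer quantile grid around the best coarse cell
    step = q[1] - q[0]
    qi_fine = np.clip(np.linspace(best_q[0] - step, best_q[0] + step, 7),
                      50.0, 99.999)
    qt_fine = np.clip(np.linspace(best_q[1] - step, best_q[1] + step, 7),
                      50.0, 99.999)
    for ti in np.percentile(phase_vol, qi_fine):
        for tt in np.percentile(abs_tex, qt_fine):
            cand = evaluate(ti, tt)
            if cand[0] > best[0]:
                best = cand
    return best[1], best[2]


def apparent_extent_px(volume: np.ndarray, centre: tuple[int, int, int],
                       window: int = 5) -> int:
    """Above-half-max in-plane extent (pixels) of a detected particle.

    The local peak is searched within one voxel of the marked centre;
    the background is the median of the square ring ``window`` pixels
    out; the extent is the longest contiguous run of pixels above
    half-maximum through the peak along the x and y profiles. This is
    the apparent particle diameter in reconstructed sections, which for
    60-100 um microspheres at ~20 um pixels is a few pixels.
    """
    z, y, x = (int(c) for c in centre)
    sub = volume[z - 1:z + 2, y - 1:y + 2, x - 1:x + 2]
    dz, dy, dx = np.unravel_index(int(np.argmax(sub)), sub.shape)
    z, y, x = z + dz - 1, y + dy - 1, x + dx - 1
    w = window
    patch = volume[z, y - w:y + w + 1, x - w:x + w + 1]
    if patch.shape != (2 * w + 1, 2 * w + 1):
        raise ContractError("centre too close to the volume border")
    ring = np.concatenate([patch[0, :], patch[-1, :], patch[:, 0], patch[:, -1]])
    half = np.median(ring) + (volume[z, y, x] - np.median(ring)) / 2.0
    best = 0
    for prof in (volume[z, y, x - w:x + w + 1], volume[z, y - w:y + w + 1, x]):
        above = prof > half
        if not above[w]:
            continue
        i0 = i1 = w
        while i0 - 1 >= 0 and above[i0 - 1]:
            i0 -= 1
        while i1 + 1 < len(above) and above[i1 + 1]:
            i1 += 1
        best = max(best, i1 - i0 + 1)
    return best


def detect_microspheres(phase_vol: np.ndarray, atten_vol: np.ndarray,
                        params: DetectionParams) -> CentreMap:
    """Full detection pass: high-pass texture, combined threshold,
    component extraction."""
    texture = high_pass(atten_vol, params.hp_sigma_px)
    cand = combined_threshold(phase_vol, texture, params)
    return extract_centres(cand, params, phase_vol=phase_vol, atten_vol=atten_vol)
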