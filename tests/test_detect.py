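"""Microsphere detection: thresholding, component extraction, scoring."""

import numpy as np
import pytest

from depotscope import (DetectionParams, combined_threshold,
                        extract_centres, high_pass, score_detection)
from depotscope.detect import ContractError, apparent_extent_px


def params(**over):
    base = dict(tau_intensity=0.5, tau_texture=0.1)
    base.update(over)
    return DetectionParams(**base)


class TestHighPass:
    def test_constant_volume_maps_to_zero(self):
        out = high_pass(np.full((8, 8, 8), 3.0), 2.0)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_impulse_response_peaks_at_impulse(self):
        vol = np.zeros((9, 9, 9))
        vol[4, 4, 4] = 1.0
        out = high_pass(vol, 2.0)
        assert np.unravel_index(np.argmax(out), out.shape) == (4, 4, 4)

    def test_sphere_surfaces_carry_texture_energy(self, contrast_recon):
        # edge enhancement concentrates high frequencies at the spheres
        ph = contrast_recon["phantom"]
        tex = np.abs(high_pass(contrast_recon["atten"], 2.0))
        sphere_lab = ph.label_names["plg_contrast"]
        spheres = ph.labels == sphere_lab
        # uniform tissue interior away from boundaries
        from scipy.ndimage import binary_erosion
        muscle = binary_erosion(ph.labels == ph.label_names["muscle"],
                                iterations=3)
        assert tex[spheres].mean() >= 5.0 * tex[muscle].mean()


class TestCombinedThreshold:
    def test_infinite_intensity_threshold_empty(self):
        vol = np.random.default_rng(0).normal(size=(4, 4, 4))
        out = combined_threshold(vol, vol, params(tau_intensity=np.inf))
        assert not out.any()

    def test_permissive_thresholds_select_everything(self):
        vol = np.abs(np.random.default_rng(0).normal(size=(4, 4, 4))) + 0.1
        out = combined_threshold(vol, vol, params(tau_intensity=-np.inf,
                                                  tau_texture=0.0))
        assert out.all()

    def test_roi_restriction(self):
        vol = np.ones((6, 6, 6))
        out = combined_threshold(vol, vol, params(
            tau_intensity=0.5, tau_texture=0.5,
            roi_list=((0, 2, 0, 6, 0, 6),)))
        assert out[:2].all() and not out[2:].any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            combined_threshold(np.ones((4, 4, 4)), np.ones((4, 4, 5)),
                               params())

    def test_candidates_touch_most_true_spheres(self, contrast_recon,
                                                contrast_detection):
        ph = contrast_recon["phantom"]
        p, _, texture = contrast_detection
        cand = combined_threshold(contrast_recon["phase"], texture, p)
        covered = 0
        for (z, y, x, r_um) in ph.sphere_truth:
            zi, yi, xi = int(round(z)), int(round(y)), int(round(x))
            if cand[zi - 1:zi + 2, yi - 1:yi + 2, xi - 1:xi + 2].any():
                covered += 1
        assert covered >= 0.9 * len(ph.sphere_truth)


class TestExtractCentres:
    def test_empty_candidates_empty_map(self):
        cm = extract_centres(np.zeros((4, 4, 4), dtype=bool), params())
        assert cm.centres == [] and not cm.binary.any()

    def test_small_blob_centroid(self):
        cand = np.zeros((6, 6, 6), dtype=bool)
        cand[2:4, 2:4, 2:4] = True  # centroid (2.5, 2.5, 2.5) -> rounds
        cm = extract_centres(cand, params())
        assert len(cm.centres) == 1
        z, y, x = cm.centres[0][:3]
        assert (z, y, x) in [(2, 2, 2), (2, 2, 3), (3, 3, 3), (2, 3, 2),
                             (3, 2, 2), (2, 3, 3), (3, 2, 3), (3, 3, 2)]
        assert cm.centres[0][3] == 8

    def test_elongated_boundary_artifact_rejected(self):
        cand = np.zeros((4, 20, 4), dtype=bool)
        cand[1, 2:14, 1] = True  # 12 px long ridge
        cm = extract_centres(cand, params(max_diameter_px=5))
        assert cm.centres == []

    def test_touching_pair_is_split(self):
        # two 3-px blobs in contact: one 26-connected component of
        # extent 7, recovered as two centres
        cand = np.zeros((7, 9, 16), dtype=bool)
        zz, yy, xx = np.mgrid[:7, :9, :16]
        cand |= (zz - 3) ** 2 + (yy - 4) ** 2 + (xx - 5) ** 2 <= 1.6 ** 2
        cand |= (zz - 3) ** 2 + (yy - 4) ** 2 + (xx - 9) ** 2 <= 1.6 ** 2
        cm = extract_centres(cand, params(max_diameter_px=5))
        assert len(cm.centres) == 2
        xs = sorted(c[2] for c in cm.centres)
        assert abs(xs[0] - 5) <= 1 and abs(xs[1] - 9) <= 1

    def test_min_voxels_gate(self):
        cand = np.zeros((4, 4, 4), dtype=bool)
        cand[1, 1, 1] = True
        assert extract_centres(cand, params(min_voxels=2)).centres == []


class TestScoreDetection:
    def test_perfect_detection(self):
        truth = [(2, 2, 2, 30.0), (5, 5, 5, 40.0)]
        sc = score_detection(np.array([[2, 2, 2], [5, 5, 5]]), truth, 2.0)
        assert (sc.precision, sc.recall, sc.f1) == (1.0, 1.0, 1.0)

    def test_no_detections_zero_scores(self):
        sc = score_detection(np.empty((0, 3)), [(1, 1, 1, 30.0)], 2.0)
        assert sc.recall == 0.0 and sc.precision == 0.0

    def test_match_at_exact_radius_counts(self):
        sc = score_detection(np.array([[10, 10, 12]]), [(10, 10, 10, 30.0)],
                             match_radius_px=2.0)
        assert sc.true_positives == 1

    def test_matching_is_one_to_one(self):
        # two detections near one truth: only one may match
        sc = score_detection(np.array([[5, 5, 5], [5, 5, 6]]),
                             [(5, 5, 5, 30.0)], 2.0)
        assert sc.true_positives == 1 and sc.false_positives == 1


class TestDetectionQuality:
    def test_contrast_phantom_precision_and_recall(self, contrast_detection):
        """Tuned detection on the noise-free contrast-agent phantom finds
        essentially every resolvable sphere with few false positives."""
        _, score, _ = contrast_detection
        assert score.precision >= 0.95
        assert score.recall >= 0.95

    def test_label_free_detection_degrades_but_works(self, contrast_detection,
                                                     labelfree_detection):
        _, score_lf, _ = labelfree_detection
        _, score_c, _ = contrast_detection
        assert score_lf.recall > 0.0
        assert score_lf.recall <= score_c.recall

    def test_combined_beats_single_criterion_on_noisy_scan(
            self, noisy_recon, noisy_detection):
        """At matched recall, requiring both intensity and texture gives
        precision at least as good as either criterion alone."""
        p, score_combined, texture = noisy_detection
        pv = noisy_recon["phase"]
        truth = noisy_recon["phantom"].sphere_truth

        def best_single(kind):
            best_precision = 0.0
            for q in np.linspace(90.0, 99.95, 30):
                if kind == "intensity":
                    single = DetectionParams(
                        tau_intensity=float(np.percentile(pv, q)),
                        tau_texture=-1.0, hp_sigma_px=p.hp_sigma_px,
                        max_diameter_px=p.max_diameter_px)
                else:
                    single = DetectionParams(
                        tau_intensity=-np.inf,
                        tau_texture=float(np.percentile(np.abs(texture), q)),
                        hp_sigma_px=p.hp_sigma_px,
                        max_diameter_px=p.max_diameter_px)
                cand = combined_threshold(pv, texture, single)
                sc = score_detection(extract_centres(cand, single), truth)
                if sc.recall >= score_combined.recall:
                    best_precision = max(best_precision, sc.precision)
            return best_precision

        assert score_combined.precision >= best_single("intensity")
        assert score_combined.precision >= best_single("texture")

    def test_apparent_size_of_isolated_spheres(self, sparse_recon,
                                               sparse_detection):
        """Isolated 60-90 um spheres appear 2-4 pixels across at half
        maximum in both reconstruction branches."""
        p, score, _ = sparse_detection
        assert score.recall == 1.0
        from depotscope.detect import detect_microspheres
        cm = detect_microspheres(sparse_recon["phase"],
                                 sparse_recon["atten"], p)
        truth = np.array([t[:3] for t in
                          sparse_recon["phantom"].sphere_truth])
        for centre in cm.centres:
            dist = np.linalg.norm(truth - np.array(centre[:3]), axis=1).min()
            if dist > 3.0:
                continue  # apparent size is defined for true spheres
            for vol in (sparse_recon["phase"], sparse_recon["atten"]):
                ext = apparent_extent_px(vol, centre[:3])
                assert 2 <= ext <= 4

    def test_component_extents_match_apparent_particle_size(
            self, sparse_recon, sparse_detection):
        from scipy import ndimage
        p, _, texture = sparse_detection
        cand = combined_threshold(sparse_recon["phase"], texture, p)
        labels, _ = ndimage.label(cand, structure=np.ones((3, 3, 3), bool))
        truth = sparse_recon["phantom"].sphere_truth
        for (z, y, x, r_um) in truth:
            zi, yi, xi = int(round(z)), int(round(y)), int(round(x))
            lab = labels[zi - 1:zi + 2, yi - 1:yi + 2, xi - 1:xi + 2].max()
            assert lab > 0
            sl = ndimage.find_objects(labels)[lab - 1]
            extent = max(s.stop - s.start for s in sl)
            assert 2 <= extent <= 5
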