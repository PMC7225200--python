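"""Reconstruction: FBP scaling, phase retrieval, branch behaviour."""

import numpy as np
import pytest

from depotscope import (BeamConfig, DetectorConfig, ReconVolume, Sinogram,
                        acquire_scan, build_phantom, combine_vertical,
                        fbp_slice, paganin_filter, preprocess_scan,
                        reconstruct_volume)
from depotscope.reconstruct import CombineError, ContractError
from depotscope.simulate import fresnel_propagate, project_slice

BEAM = BeamConfig(energy_keV=70.0, propagation_distance_um=1.0e6,
                  pixel_size_um=21.5, n_angles=360)


def disk(n, radius, value, centre=None):
    yy, xx = np.mgrid[:n, :n]
    cy, cx = centre if centre else (n // 2, n // 2)
    img = np.zeros((n, n))
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2] = value
    return img


class TestFbpSlice:
    def test_uniform_disk_value_recovered(self):
        mu0 = 1e-3
        sl = disk(120, 40, mu0)
        mu_int, _ = project_slice(sl, np.zeros_like(sl), BEAM.angles_deg(),
                                  BEAM)
        rec = fbp_slice(Sinogram(mu_int, 0, "neg-log"), BEAM.angles_deg(),
                        BEAM.pixel_size_um)
        yy, xx = np.mgrid[:120, :120]
        inside = (yy - 60) ** 2 + (xx - 60) ** 2 <= 32 ** 2
        assert rec[inside].mean() == pytest.approx(mu0, rel=0.05)

    def test_zero_sinogram_gives_zero_section(self):
        rec = fbp_slice(Sinogram(np.zeros((90, 64)), 0, "neg-log"),
                        np.arange(90) * 2.0, 21.5)
        assert np.allclose(rec, 0.0, atol=1e-12)

    def test_point_object_reconstructs_at_its_position(self):
        sl = np.zeros((101, 101))
        sl[30, 70] = 1.0
        mu_int, _ = project_slice(sl, np.zeros_like(sl), BEAM.angles_deg(),
                                  BEAM)
        rec = fbp_slice(Sinogram(mu_int, 0, "neg-log"), BEAM.angles_deg(),
                        BEAM.pixel_size_um)
        peak = np.unravel_index(np.argmax(rec), rec.shape)
        assert abs(peak[0] - 30) <= 1 and abs(peak[1] - 70) <= 1

    def test_intensity_ratio_sinogram_rejected(self):
        with pytest.raises(ContractError):
            fbp_slice(Sinogram(np.ones((10, 8)), 0, "intensity-ratio"),
                      np.arange(10) * 18.0, 21.5)

    def test_radon_fbp_roundtrip_on_smooth_phantom(self):
        from scipy.ndimage import gaussian_filter
        sl = gaussian_filter(disk(128, 45, 1e-3)
                             + disk(128, 18, 8e-4, (50, 76)), 3.0)
        mu_int, _ = project_slice(sl, np.zeros_like(sl), BEAM.angles_deg(),
                                  BEAM)
        rec = fbp_slice(Sinogram(mu_int, 0, "neg-log"), BEAM.angles_deg(),
                        BEAM.pixel_size_um)
        yy, xx = np.mgrid[:128, :128]
        inside = (yy - 64) ** 2 + (xx - 64) ** 2 <= 60 ** 2
        nrmse = (np.sqrt(np.mean((rec[inside] - sl[inside]) ** 2))
                 / np.ptp(sl[inside]))
        assert nrmse <= 0.03


class TestPaganinFilter:
    def test_zero_distance_equals_neg_log(self):
        rng = np.random.default_rng(4)
        frame = rng.uniform(0.4, 1.0, (16, 16))
        beam = BeamConfig(propagation_distance_um=0.0, n_angles=8)
        assert np.array_equal(paganin_filter(frame, beam), -np.log(frame))

    def test_constant_frame_passes_through_dc(self):
        frame = np.full((16, 16), 0.7)
        out = paganin_filter(frame, BEAM, delta_over_beta=100.0)
        assert np.allclose(out, -np.log(0.7), atol=1e-12)

    def test_matches_direct_discrete_fourier_oracle(self):
        # independent oracle: O(n^4) double-sum DFT on a 16x16 frame
        rng = np.random.default_rng(5)
        frame = rng.uniform(0.5, 1.0, (16, 16))
        dob = 100.0
        out = paganin_filter(frame, BEAM, dob)

        n = 16
        lam, d, px = (BEAM.wavelength_um, BEAM.propagation_distance_um,
                      BEAM.pixel_size_um)
        ks = np.fft.fftfreq(n, d=px)
        F = np.zeros((n, n), dtype=complex)
        for a in range(n):
            for b in range(n):
                acc = 0.0
                for i in range(n):
                    for j in range(n):
                        acc += frame[i, j] * np.exp(-2j * np.pi
                                                    * (a * i + b * j) / n)
                F[a, b] = acc / (1.0 + np.pi * lam * d * dob
                                 * (ks[a] ** 2 + ks[b] ** 2))
        direct = np.zeros((n, n), dtype=complex)
        for i in range(n):
            for j in range(n):
                acc = 0.0
                for a in range(n):
                    for b in range(n):
                        acc += F[a, b] * np.exp(2j * np.pi
                                                * (a * i + b * j) / n)
                direct[i, j] = acc / n ** 2
        expected = -np.log(np.clip(np.real(direct), 1e-6, None))
        assert np.abs(out - expected).max() < 1e-10

    def test_retrieval_is_a_pure_low_pass(self):
        rng = np.random.default_rng(6)
        frame = rng.uniform(0.5, 1.0, (32, 32))
        out_spec = np.abs(np.fft.fft2(np.exp(-paganin_filter(frame, BEAM))))
        in_spec = np.abs(np.fft.fft2(frame))
        assert np.all(out_spec <= in_spec + 1e-12)

    def test_non_positive_frame_rejected(self):
        frame = np.ones((8, 8))
        frame[3, 3] = 0.0
        with pytest.raises(ContractError):
            paganin_filter(frame, BEAM)

    def test_edge_fringes_suppressed_with_matched_ratio(self):
        # homogeneous step: delta/beta consistent everywhere, so the
        # retrieval removes the propagation fringes almost entirely
        n = 512
        dob = 100.0
        mu_int = np.zeros(n)
        mu_int[n // 2:] = 1.93e-5 * 500.0
        delta_int = dob * BEAM.wavelength_um / (4 * np.pi) * mu_int
        intensity = fresnel_propagate(mu_int, delta_int, BEAM)
        raw_neglog = -np.log(intensity)
        retrieved = paganin_filter(np.tile(intensity, (4, 1)), BEAM, dob)[0]
        right = mu_int[-1]
        overshoot_raw = raw_neglog.max() - right
        overshoot_ret = retrieved.max() - right
        assert overshoot_ret <= 0.2 * overshoot_raw


@pytest.fixture(scope="module")
def small_scan():
    spec = {
        "grid": {"shape": [8, 96, 96]},
        "beam": {"energy_keV": 70.0, "propagation_distance_um": 1.0e6,
                 "pixel_size_um": 21.5, "n_angles": 180,
                 "angular_range_deg": 180.0},
        "outside": "air", "background": "agarose",
        "depot": {"material": "vehicle_contrast", "centre_voxel": [4, 38, 56],
                  "semi_axes_um": [50, 300, 350]},
    }
    ph = build_phantom(spec)
    scan = acquire_scan(ph, detector=DetectorConfig(k1=0.0, noise=False),
                        seed=0)
    return ph, preprocess_scan(scan)


class TestReconstructVolume:
    def test_branches_coincide_without_propagation(self):
        spec = {
            "grid": {"shape": [4, 64, 64]},
            "beam": {"energy_keV": 70.0, "propagation_distance_um": 0.0,
                     "pixel_size_um": 21.5, "n_angles": 90,
                     "angular_range_deg": 180.0},
            "outside": "air", "background": "water"}
        ph = build_phantom(spec)
        scan = acquire_scan(ph, detector=DetectorConfig(k1=0.0, noise=False),
                            seed=0)
        corr = preprocess_scan(scan, ring_filter=False)
        att = reconstruct_volume(corr, "attenuation")[0]
        phs = reconstruct_volume(corr, "phase")[0]
        assert np.abs(att.sections - phs.sections).max() < 1e-6

    def test_phase_branch_smooths_edge_enhanced_data(self, small_scan):
        _, corr = small_scan
        att = reconstruct_volume(corr, "attenuation")[0].sections
        phs = reconstruct_volume(corr, "phase")[0].sections
        def tv(vol):
            return (np.abs(np.diff(vol, axis=1)).sum()
                    + np.abs(np.diff(vol, axis=2)).sum())
        assert tv(phs) < tv(att)

    def test_two_material_means_within_ten_percent(self):
        # contact scan isolates FBP fidelity from propagation fringes
        spec = {
            "grid": {"shape": [8, 96, 96]},
            "beam": {"energy_keV": 70.0, "propagation_distance_um": 0.0,
                     "pixel_size_um": 21.5, "n_angles": 180,
                     "angular_range_deg": 180.0},
            "outside": "air", "background": "agarose",
            "depot": {"material": "vehicle_contrast",
                      "centre_voxel": [4, 38, 56],
                      "semi_axes_um": [50, 300, 350]}}
        ph = build_phantom(spec)
        scan = acquire_scan(ph, detector=DetectorConfig(k1=0.0, noise=False),
                            seed=0)
        corr = preprocess_scan(scan, ring_filter=False)
        att = reconstruct_volume(corr, "attenuation")[0].sections
        mu = ph.mu_volume()
        from scipy.ndimage import binary_erosion
        depot = binary_erosion(ph.depot_mask, iterations=2)
        yy, xx = np.mgrid[:96, :96]
        tissue = (~ph.depot_mask
                  & ((yy - 48) ** 2 + (xx - 48) ** 2 < 30 ** 2)[np.newaxis])
        for region in (depot, tissue):
            truth = mu[region].mean()
            assert att[region].mean() == pytest.approx(truth, rel=0.10)

    def test_provenance_records_branch_chain(self, small_scan):
        _, corr = small_scan
        vol = reconstruct_volume(corr, "phase", delta_over_beta=50.0)[0]
        steps = [s["step"] for s in vol.provenance]
        assert steps[-2:] == ["paganin", "fbp"]


class TestCombineVertical:
    def make(self, n, fill, branch="attenuation"):
        return ReconVolume(np.full((n, 4, 4), float(fill)), branch, 21.5)

    def test_two_stacks_with_overlap_concatenate_consecutively(self):
        out = combine_vertical([self.make(40, 1), self.make(40, 2)], [16])
        assert out.n_sections == 64
        assert np.allclose(out.sections[:40], 1.0)
        assert np.allclose(out.sections[40:], 2.0)

    def test_single_stack_returned_unchanged(self):
        a = self.make(10, 3)
        out = combine_vertical([a], [])
        assert np.array_equal(out.sections, a.sections)

    def test_full_overlap_of_duplicate_equals_original(self):
        a = self.make(12, 5)
        out = combine_vertical([a, self.make(12, 5)], [12])
        assert np.array_equal(out.sections, a.sections)

    def test_branch_mismatch_rejected(self):
        with pytest.raises(CombineError):
            combine_vertical([self.make(8, 1),
                              self.make(8, 1, branch="phase")], [2])

    def test_mean_mode_averages_overlap(self):
        out = combine_vertical([self.make(6, 0), self.make(6, 2)], [2],
                               mode="mean")
        assert out.n_sections == 10
        assert np.allclose(out.sections[4:6], 1.0)

    def test_simulated_subscan_overlap_sections_agree(self):
        spec = {
            "grid": {"shape": [20, 64, 64]},
            "beam": {"energy_keV": 70.0, "propagation_distance_um": 1.0e6,
                     "pixel_size_um": 21.5, "n_angles": 90,
                     "angular_range_deg": 180.0},
            "outside": "air", "background": "agarose",
            "depot": {"material": "vehicle_contrast",
                      "centre_voxel": [10, 26, 38],
                      "semi_axes_um": [100, 250, 250]}}
        ph = build_phantom(spec)
        scan = acquire_scan(ph, detector=DetectorConfig(k1=0.0, noise=False),
                            n_subscans=2, overlap_rows=8)
        corr = preprocess_scan(scan, ring_filter=False)
        stacks = reconstruct_volume(corr, "attenuation")
        (lo0, hi0), (lo1, hi1) = corr.row_ranges
        a = stacks[0].sections[lo1 - lo0:]
        b = stacks[1].sections[:hi0 - lo1]
        assert np.abs(a - b).max() < 1e-9
        combined = combine_vertical(stacks, [scan.overlap_rows])
        assert combined.n_sections == 20
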