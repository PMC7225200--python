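"""Shared fixtures: simulated scans reconstructed once per session.

The expensive fixtures (full simulate -> preprocess -> reconstruct
chains on the standard 160-px phantom) are session-scoped and shared
between the detection, quantification and acceptance tests.
"""

from __future__ import annotations

import pytest

from depotscope import (DetectionParams, acquire_scan, build_phantom,
                        combine_vertical, preprocess_scan, reconstruct_volume)
from depotscope.detect import high_pass, tune_thresholds
from depotscope.presets import (noisy_detector, sparse_phantom_spec,
                                standard_detector, standard_phantom_spec)


def simulate_and_reconstruct(spec, detector, seed=1):
    """Run phantom -> scan -> preprocess -> both reconstruction branches."""
    ph = build_phantom(spec)
    scan = acquire_scan(ph, detector=detector, seed=seed)
    corrected = preprocess_scan(scan)
    vols = {}
    for branch in ("attenuation", "phase"):
        stacks = reconstruct_volume(corrected, branch=branch)
        vols[branch] = combine_vertical(stacks, [])
    return {
        "phantom": ph,
        "scan": scan,
        "corrected": corrected,
        "phase": vols["phase"].sections,
        "atten": vols["attenuation"].sections,
    }


def tuned_detection(recon, hp_sigma=1.5, n_grid=20):
    texture = high_pass(recon["atten"], hp_sigma)
    params, score = tune_thresholds(
        recon["phase"], texture, recon["phantom"].sphere_truth,
        DetectionParams(0.0, 0.0, hp_sigma_px=hp_sigma), n_grid=n_grid)
    return params, score, texture


@pytest.fixture(scope="session")
def contrast_recon():
    """Noise-free contrast-agent scan of the standard clustered phantom."""
    return simulate_and_reconstruct(standard_phantom_spec(contrast=True),
                                    standard_detector())


@pytest.fixture(scope="session")
def labelfree_recon():
    """Noise-free label-free (no contrast agent) scan, same geometry."""
    return simulate_and_reconstruct(standard_phantom_spec(contrast=False),
                                    standard_detector())


@pytest.fixture(scope="session")
def noisy_recon():
    """Contrast-agent scan with Poisson noise at the default flux."""
    return simulate_and_reconstruct(standard_phantom_spec(contrast=True),
                                    noisy_detector())


@pytest.fixture(scope="session")
def sparse_recon():
    """Isolated 60-90 um spheres for apparent-size measurements."""
    return simulate_and_reconstruct(sparse_phantom_spec(), standard_detector())


@pytest.fixture(scope="session")
def contrast_detection(contrast_recon):
    return tuned_detection(contrast_recon)


@pytest.fixture(scope="session")
def labelfree_detection(labelfree_recon):
    return tuned_detection(labelfree_recon)


@pytest.fixture(scope="session")
def noisy_detection(noisy_recon):
    return tuned_detection(noisy_recon)


@pytest.fixture(scope="session")
def sparse_detection(sparse_recon):
    return tuned_detection(sparse_recon)
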