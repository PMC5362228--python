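"""Shared fixtures.

Session-scoped fixtures hold the expensive phantom segmentations so the
unit suite and the acceptance suite measure the same runs instead of
recomputing them.
"""

from __future__ import annotations

import numpy as np
import pytest

from octfovea import (
    PhantomSpec,
    boundary_error,
    generate_bscan,
    profile_from_scan,
    segment_layers,
)


@pytest.fixture(scope="session")
def noiseless_case():
    """Default phantom without speckle, its ground truth and segmentation."""
    spec = PhantomSpec(noise_level=0.0, seed=1)
    scan, truth = generate_bscan(spec)
    estimate = segment_layers(scan)
    return spec, scan, truth, estimate


@pytest.fixture(scope="session")
def noisy_mae_batch():
    """Per-boundary MAE (pixels) over 20 seeded phantoms at speckle 0.15."""
    maes = []
    for seed in range(20):
        scan, truth = generate_bscan(PhantomSpec(noise_level=0.15, seed=seed))
        estimate = segment_layers(scan)
        maes.append(boundary_error(truth, estimate, 1.0)["mae_um"].to_numpy())
    return np.asarray(maes)


@pytest.fixture(scope="session")
def center_recovery_errors():
    """|detected - true| foveal-center column error over 20 seeded phantoms."""
    from octfovea import find_foveal_center

    errors = []
    for seed in range(20):
        rng = np.random.default_rng(seed + 1000)
        true_center = int(rng.integers(180, 332))
        spec = PhantomSpec(noise_level=0.1, seed=seed, pit_center_column=true_center)
        scan, _ = generate_bscan(spec)
        profile = profile_from_scan(scan, segment_layers(scan))
        errors.append(abs(find_foveal_center(profile) - true_center))
    return errors
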