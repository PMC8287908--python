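"""Shared fixtures: synthetic datasets and trained detector fixtures.

The expensive fixture is ``desk_model``: a reduced network trained for 20
epochs on 64 synthetic high-SNR fields.  It is session-scoped so the
learning, inference, and end-to-end metric tests all share one training
run.
"""

from __future__ import annotations

import numpy as np
import pytest

import gridspot as gs


def desk_scale_params(n_images: int = 80) -> list[gs.SpotFieldParams]:
    """High-SNR 128 px fields: 15 spots, peak SNR ~10, 8 px separation."""
    return [
        gs.SpotFieldParams(
            height=128, width=128, n_spots=15, psf_sigma=1.5,
            amplitude_range=(80.0, 120.0), background=100.0, noise_sd=10.0,
            min_separation=8.0,
        )
        for _ in range(n_images)
    ]


@pytest.fixture(scope="session")
def desk_archive() -> gs.DatasetArchive:
    """80 seeded synthetic fields split 64/8/8."""
    return gs.generate_dataset(desk_scale_params(80), (0.8, 0.1, 0.1), seed=7)


@pytest.fixture(scope="session")
def desk_model(desk_archive) -> gs.SpotDetector:
    """Reduced detector (16 filters, depth 2) trained 20 epochs on the
    64-image train split; the learning-rate is raised to 1e-3 to converge
    within the short schedule."""
    det = gs.SpotDetector(filters=16, unet_depth=2, epochs=20,
                          learning_rate=1e-3, seed=7)
    det.fit(desk_archive.x_train, desk_archive.y_train,
            X_valid=desk_archive.x_valid, y_valid=desk_archive.y_valid)
    return det
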