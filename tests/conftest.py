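import numpy as np
import pytest

import wormbend as wb
from wormbend.posture import build_kymograph


@pytest.fixture(scope="session")
def movie_and_truth():
    """Rendered noise-free synthetic movie (12 s at 5 Hz) plus ground truth."""
    params = wb.WaveParams(
        curvature_amplitude=3.0, duration=12.0, frame_rate=5.0, seed=1
    )
    frames, gt = wb.make_synthetic_movie(
        params, image_shape=(384, 384), mm_per_px=0.004
    )
    return frames, gt


@pytest.fixture(scope="session")
def recovered_kymograph(movie_and_truth):
    frames, _ = movie_and_truth
    kymo, centerlines = build_kymograph(frames)
    return kymo, centerlines


@pytest.fixture()
def straight_worm_frame():
    cl = wb.centerline_from_curvature(np.zeros(100), 1.0)
    return wb.render_worm_mask(
        cl, image_shape=(384, 384), mm_per_px=0.004
    ), cl


@pytest.fixture()
def noisy_wave_kymograph():
    """Irregular (noisy) wave so that cross-correlation lags are unambiguous."""
    params = wb.WaveParams(
        curvature_amplitude=3.0, duration=60.0, frame_rate=5.0,
        noise_sd=0.8, seed=3,
    )
    return wb.make_curvature_wave(params)
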