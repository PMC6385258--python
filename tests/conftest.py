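"""Shared fixtures: optics, PSF, and one expensive rendered scene.

The mixed-population scene (single and multi-QD emitters, blinking movie
plus volumetric stack) is rendered once per session and reused by the
pipeline and calibration-ratio tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from qdc3dm import deconv, pipeline, synthscope


@pytest.fixture(scope="session")
def optics() -> synthscope.OpticsConfig:
    return synthscope.OpticsConfig()


@pytest.fixture(scope="session")
def psf(optics) -> deconv.PSF3D:
    return deconv.gaussian_psf(optics.psf_sigma_xy_px, optics.psf_sigma_z_planes)


def make_blinking_trace(
    n_qd: int,
    seed: int,
    n_frames: int = 4000,
    level: float = 680.0,
    noise: float = 31.0,
    baseline: float = 180.0,
):
    """Trace of a spot with ``n_qd`` independently blinking QDs.

    ``level`` is the per-QD 3x3-window intensity step; ``noise`` the
    frame-to-frame Gaussian noise (SNR = level / noise).
    """
    from qdc3dm import blinkfit

    states = synthscope.simulate_blinking_states(n_qd, n_frames, seed=seed)
    rng = np.random.default_rng(seed + 991)
    values = baseline + states.sum(axis=0) * level + rng.normal(0, noise, n_frames)
    return blinkfit.TimeTrace(values)


@pytest.fixture(scope="session")
def mixed_scene(optics):
    """30 isolated emitters (20x1, 6x2, 4x3 QDs): movie + stack + truth."""
    n_qd = np.array([1] * 20 + [2] * 6 + [3] * 4)
    scene = synthscope.make_spot_field(
        30, (96, 96), n_planes=40, n_qd=n_qd, seed=11
    )
    rng = np.random.default_rng(53)
    movie = synthscope.render_timeseries(scene, optics, 600, seed=rng)
    for em in scene.emitters:  # independent blinking during the z-scan
        em.states = None
    stack = synthscope.render_stack3d(scene, optics, 40, seed=rng)
    return {"scene": scene, "movie": movie, "stack": stack, "n_qd": n_qd}


@pytest.fixture(scope="session")
def mixed_scene_result(mixed_scene, psf):
    return pipeline.run_arrays(
        mixed_scene["movie"], mixed_scene["stack"], psf, seed=1
    )
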