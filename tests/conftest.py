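"""Shared fixtures: phantom populations and the atlases built from them.

The expensive groupwise registrations are session-scoped so the atlas
convergence, diffeomorphism, mode-recovery and discrimination checks all
reuse the same runs.
"""

from __future__ import annotations

import numpy as np
import pytest

import odatlas as od
from odatlas.descriptor import pca_modes, variance_field


def reps_of(subjects):
    return [
        od.compose_four_cluster(s.disc_mask, s.cup_mask, s.vessel_mask).scalar_encoding
        for s in subjects
    ]


@pytest.fixture(scope="session")
def phantom96():
    """Noise-free template phantom on a 96×96 grid."""
    return od.render_phantom(od.PhantomSpec(patch_size=96, noise_sd=0.0))


@pytest.fixture(scope="session")
def rep96(phantom96):
    p = phantom96
    return od.compose_four_cluster(p.disc_mask, p.cup_mask, p.vessel_mask).scalar_encoding


@pytest.fixture(scope="session")
def atlas192():
    """20 subjects, 192×192, free smooth deformations of amplitude <= 5 px."""
    spec = od.PhantomSpec(patch_size=192)
    subjects = od.sample_population(spec, None, 20, seed=42, field_amplitude=5.0)
    model = od.build_average_model(reps_of(subjects))
    return {"spec": spec, "subjects": subjects, "model": model}


@pytest.fixture(scope="session")
def mode_population96():
    """30 subjects, 96×96, two planted orthogonal modes; atlas + statistics."""
    spec = od.PhantomSpec(patch_size=96)
    modes = od.make_default_modes(spec)
    subjects = od.sample_population(spec, modes, 30, seed=42)
    model = od.build_average_model(reps_of(subjects))
    return {
        "spec": spec,
        "modes": modes,
        "subjects": subjects,
        "model": model,
        "variance": variance_field(model.velocities),
        "pca": pca_modes(model.velocities),
    }


@pytest.fixture(scope="session")
def vessel_population():
    """10 vessel masks sharing 3 branches; average model and probability map."""
    masks, disc = od.sample_vessel_population(10, patch_size=192, seed=42)
    prob, model = od.build_vessel_average_model(masks, disc)
    return {"masks": masks, "disc": disc, "prob": prob, "model": model}


def rk4_flow(v: np.ndarray, n_steps: int = 32) -> np.ndarray:
    """Independent oracle for the exponential map: classic 4th-order
    Runge–Kutta integration of dφ/dt = v(φ) from t=0 to 1 with bilinear
    velocity interpolation."""
    from scipy.ndimage import map_coordinates

    def sample(pos):
        return np.stack([
            map_coordinates(v[c], pos, order=1, mode="nearest") for c in range(2)
        ])

    h = 1.0 / n_steps
    pos = np.stack(np.meshgrid(np.arange(v.shape[1]), np.arange(v.shape[2]),
                               indexing="ij")).astype(float)
    start = pos.copy()
    for _ in range(n_steps):
        k1 = sample(pos)
        k2 = sample(pos + 0.5 * h * k1)
        k3 = sample(pos + 0.5 * h * k2)
        k4 = sample(pos + h * k3)
        pos = pos + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return pos - start


def rms(a: np.ndarray) -> float:
    return float(np.sqrt((a**2).mean()))
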