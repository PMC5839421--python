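"""2-D log-demons diffeomorphic registration on stationary velocity fields.

A deformation is parameterized by a stationary velocity field ``v`` whose
flow at unit time, ``exp(v)``, is a diffeomorphism.  Registration alternates
a demons force update (intensity-difference driven, pixelwise normalized)
with two Gaussian regularizations — a *fluid* smoothing of the update and a
*diffusion* smoothing of the accumulated velocity — inside a coarse-to-fine
multiresolution scheme.  Because all statistics downstream (atlas averaging,
variance, PCA) live in the velocity-field vector space, every function here
takes and returns velocity or displacement fields as plain ndarrays of shape
``(2, H, W)`` where axis 0 is ordered ``(y, x)`` to match numpy indexing.

Deformations act by *backward* warping: ``warp(img, phi)[p] = img[p + phi[p]]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.transform import resize


@dataclass
class DemonsConfig:
    """Tunable parameters of the log-demons registration.

    sigma_fluid, sigma_diff
        Standard deviations (pixels) of the fluid kernel applied to the
        update field and the diffusion kernel applied to the velocity field.
    levels / iterations_per_level
        Multiresolution pyramid depth (downsampling factor 2 per level) and
        iteration budget per level, coarse to fine.
    step_cap
        Maximum magnitude (pixels) of a single demons update vector; guards
        against instability at sharp label edges.
    convergence_tol
        Mean update magnitude (pixels) below which a level stops early.
    squaring_steps
        Number of scaling-and-squaring steps; ``None`` chooses per field so
        the scaled half-step displacement stays below 0.5 px.
    """

    sigma_fluid: float = 1.5
    sigma_diff: float = 1.5
    levels: int = 3
    iterations_per_level: tuple[int, ...] = (30, 30, 20)
    step_cap: float = 2.0
    convergence_tol: float = 0.01
    squaring_steps: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_fluid <= 0 or self.sigma_diff <= 0:
            raise ValueError("demons sigmas must be positive")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if len(self.iterations_per_level) != self.levels:
            raise ValueError("iterations_per_level must have one entry per level")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["iterations_per_level"] = list(self.iterations_per_level)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DemonsConfig":
        d = dict(d)
        if "iterations_per_level" in d:
            d["iterations_per_level"] = tuple(d["iterations_per_level"])
        return cls(**d)


def _sample_field(f: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Bilinearly sample a (2,H,W) field at (2,H,W) coordinates (y,x)."""
    return np.stack(
        [map_coordinates(f[c], coords, order=1, mode="nearest") for c in range(2)]
    )


def _identity_grid(shape: tuple[int, int]) -> np.ndarray:
    return np.stack(
        np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    ).astype(float)


def compose_displacements(d_outer: np.ndarray, d_inner: np.ndarray) -> np.ndarray:
    """Displacement of (id+d_outer) ∘ (id+d_inner): d_inner + d_outer(x+d_inner)."""
    grid = _identity_grid(d_inner.shape[1:])
    return d_inner + _sample_field(d_outer, grid + d_inner)


def field_exponential(v: np.ndarray, config: DemonsConfig | None = None) -> np.ndarray:
    """Exponential map exp(v) by scaling and squaring.

    The velocity is halved n times until the maximum displacement of the
    scaled field is below 0.5 px, taken as a small deformation, and composed
    with itself n times.  Returns the displacement field of the resulting
    diffeomorphism (same (2,H,W) layout as ``v``).
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity field contains non-finite values")
    if config is not None and config.squaring_steps is not None:
        n = int(config.squaring_steps)
    else:
        max_norm = float(np.sqrt((v**2).sum(axis=0)).max())
        n = 0 if max_norm == 0.0 else max(0, int(np.ceil(np.log2(max_norm / 0.5))))
    d = v / (2.0**n)
    for _ in range(n):
        d = compose_displacements(d, d)
    return d


def warp(image: np.ndarray, phi: np.ndarray, cval: float = 0.0) -> np.ndarray:
    """Backward-warp an image by a displacement field.

    ``image`` may be 2-D (scalar) or 3-D with channels last (RGB); sampling
    is bilinear with constant padding outside the grid.
    """
    image = np.asarray(image, dtype=float)
    coords = _identity_grid(phi.shape[1:]) + phi
    if image.ndim == 2:
        return map_coordinates(image, coords, order=1, mode="constant", cval=cval)
    if image.ndim == 3:
        return np.stack(
            [
                map_coordinates(image[..., c], coords, order=1, mode="constant", cval=cval)
                for c in range(image.shape[2])
            ],
            axis=-1,
        )
    raise ValueError("expected a 2-D scalar or 3-D channel-last image")


def demons_update(fixed: np.ndarray, moving_warped: np.ndarray,
                  step_cap: float = 2.0) -> np.ndarray:
    """Demons force: u = ∇R̃ (R−R̃) / ((R−R̃)² + |∇R̃|²), pixelwise.

    The normalization uses the pixelwise squared intensity difference and
    squared gradient magnitude; where both vanish the update is zero.  Update
    vectors longer than ``step_cap`` are rescaled onto the cap.
    """
    if fixed.shape != moving_warped.shape:
        raise ValueError("fixed and moving images must share a grid")
    diff = fixed - moving_warped
    gy, gx = np.gradient(moving_warped)
    denom = diff**2 + gy**2 + gx**2
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    u = np.stack([gy * scale, gx * scale])
    mag = np.sqrt((u**2).sum(axis=0))
    over = mag > step_cap
    if np.any(over):
        u[:, over] *= step_cap / mag[over]
    return u


def regularize(v: np.ndarray, u: np.ndarray, config: DemonsConfig) -> np.ndarray:
    """Fluid-smooth the update, add it, then diffusion-smooth the velocity.

    v' = (v + u ⊛ K_fluid) ⊛ K_diff.  The additive accumulation is the
    first-order Baker–Campbell–Hausdorff approximation
    exp(v)∘exp(u) ≈ exp(v+u), valid for small updates.  Kernels use
    reflective boundaries truncated at 4σ.
    """
    u_s = np.stack(
        [gaussian_filter(u[c], config.sigma_fluid, mode="reflect", truncate=4.0)
         for c in range(2)]
    )
    v_new = v + u_s
    return np.stack(
        [gaussian_filter(v_new[c], config.sigma_diff, mode="reflect", truncate=4.0)
         for c in range(2)]
    )


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    shape = (img.shape[0] // factor, img.shape[1] // factor)
    return resize(img, shape, order=1, anti_aliasing=True, preserve_range=True)


def _upsample_field(v: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    scale = shape[0] / v.shape[1]
    return np.stack(
        [resize(v[c], shape, order=1, preserve_range=True) * scale for c in range(2)]
    )


def log_demons_register(
    fixed: np.ndarray,
    moving: np.ndarray,
    config: DemonsConfig | None = None,
    return_trace: bool = False,
):
    """Register ``moving`` onto ``fixed``; returns the stationary velocity v.

    The returned field satisfies moving∘exp(v) ≈ fixed.  Iterates demons
    update + regularization per pyramid level, coarse to fine; a level stops
    early when the mean update magnitude drops below ``convergence_tol``.
    If the SSD energy increases for 5 consecutive iterations the best field
    seen so far at that level is kept and the level aborts with a warning.
    """
    if config is None:
        config = DemonsConfig()
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving images must share a grid")

    v: np.ndarray | None = None
    trace: list[float] = []
    for li, level in enumerate(range(config.levels - 1, -1, -1)):
        factor = 2**level
        f_l = _downsample(fixed, factor)
        m_l = _downsample(moving, factor)
        if v is None:
            v = np.zeros((2,) + f_l.shape)
        elif v.shape[1:] != f_l.shape:
            v = _upsample_field(v, f_l.shape)

        best_v, best_ssd = v, np.inf
        rising = 0
        for _ in range(config.iterations_per_level[li]):
            phi = field_exponential(v, config)
            warped = warp(m_l, phi)
            ssd = float(((f_l - warped) ** 2).sum())
            trace.append(ssd)
            if ssd < best_ssd:
                best_ssd, best_v = ssd, v
                rising = 0
            else:
                rising += 1
                if rising >= 5:
                    warnings.warn("demons energy diverging; keeping best field")
                    v = best_v
                    break
            u = demons_update(f_l, warped, config.step_cap)
            if float(np.sqrt((u**2).sum(axis=0)).mean()) < config.convergence_tol:
                break
            v = regularize(v, u, config)
        else:
            # budget exhausted: keep the best field observed at this level
            phi = field_exponential(v, config)
            if float(((f_l - warp(m_l, phi)) ** 2).sum()) > best_ssd:
                v = best_v
    if return_trace:
        return v, trace
    return v


def jacobian_determinant(phi: np.ndarray) -> np.ndarray:
    """Determinant of the spatial Jacobian of id + displacement.

    Central differences; meaningful on interior pixels (border rows/columns
    use one-sided differences from np.gradient).
    """
    dy_y, dy_x = np.gradient(phi[0])
    dx_y, dx_x = np.gradient(phi[1])
    return (1.0 + dy_y) * (1.0 + dx_x) - dy_x * dx_y


def field_norm(v: np.ndarray) -> np.ndarray:
    """Pixelwise Euclidean magnitude of a (2,H,W) field."""
    return np.sqrt((np.asarray(v) ** 2).sum(axis=0))
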