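"""Atlas statistics (variance field, PCA modes) and the atlas-based shape
descriptor (ASD) for new images.

The atlas velocity fields live in a vector space, so ordinary statistics
apply.  The variance field is the per-pixel second moment of the velocity
magnitude about zero (the atlas construction drives the mean field to ≈ 0).
The principal modes are computed with the Gram-matrix (eigenfaces) trick:
for N subjects on an m×m grid each field flattens to M = 2m² numbers, and
the eigenvectors of the M×M covariance are obtained from those of the small
N×N Gram matrix Γ = VᵀV as VE.

A new image is characterized by registering its representation onto the
average model, normalizing the resulting velocity field by the atlas
variability (deviation map) and projecting it onto the modes:

    ASD = [d_avg, d_max, p_0, …, p_{N-1}]
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .atlas import AtlasModel
from .registration import DemonsConfig, field_norm, log_demons_register


@dataclass
class VarianceField:
    """Per-pixel velocity variance σ² (px²) and its square root σ (px)."""

    sigma_sq: np.ndarray

    @property
    def sigma(self) -> np.ndarray:
        return np.sqrt(self.sigma_sq)


@dataclass
class PcaModes:
    """Principal modes of the atlas velocity fields.

    modes: (k, 2, H, W) unit-L2-norm velocity-field-shaped eigenvectors,
    sorted by descending eigenvalue; mean_field is the population mean used
    for centering.
    """

    modes: np.ndarray
    eigenvalues: np.ndarray
    mean_field: np.ndarray

    @property
    def explained_fraction(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]


@dataclass
class DeviationMap:
    """Velocity-to-atlas field normalized pixelwise by atlas variability."""

    values: np.ndarray        # (2, H, W), dimensionless
    magnitude: np.ndarray     # (H, W)


@dataclass
class ShapeDescriptor:
    mean_deviation: float
    max_deviation: float
    projections: np.ndarray

    def as_vector(self) -> np.ndarray:
        return np.concatenate(
            [[self.mean_deviation, self.max_deviation], self.projections]
        )


def variance_field(velocities: list[np.ndarray]) -> VarianceField:
    """Mean squared velocity magnitude per pixel, σ²(x) = (1/N) Σ |v_i(x)|²."""
    if len(velocities) == 0:
        raise ValueError("empty velocity population")
    sq = np.mean([(np.asarray(v) ** 2).sum(axis=0) for v in velocities], axis=0)
    return VarianceField(sigma_sq=sq)


def pca_modes(velocities: list[np.ndarray], rank_tol: float = 1e-10) -> PcaModes:
    """Principal modes via the N×N Gram matrix of mean-centered fields.

    Eigenvectors are lifted to field space (VE), L2-normalized, sorted by
    descending eigenvalue, and sign-fixed so the largest-|component| entry of
    each mode is positive.  At most N−1 modes have nonzero eigenvalue.
    """
    n = len(velocities)
    if n < 2:
        raise ValueError("PCA needs at least 2 velocity fields")
    shape = np.asarray(velocities[0]).shape
    flat = np.stack([np.asarray(v).ravel() for v in velocities], axis=1)  # M×N
    mean = flat.mean(axis=1, keepdims=True)
    centered = flat - mean
    gram = centered.T @ centered
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > rank_tol * max(evals.max(), 1e-300)
    if not np.any(keep):
        warnings.warn("all velocity fields identical; no variation modes")
        return PcaModes(
            modes=np.zeros((0,) + shape),
            eigenvalues=np.zeros(0),
            mean_field=mean.reshape(shape),
        )
    evals, evecs = evals[keep], evecs[:, keep]
    lifted = centered @ evecs                      # M×k, unnormalized VE
    norms = np.linalg.norm(lifted, axis=0)
    lifted = lifted / norms
    # deterministic sign: largest-|entry| component positive
    idx = np.abs(lifted).argmax(axis=0)
    signs = np.sign(lifted[idx, np.arange(lifted.shape[1])])
    lifted = lifted * signs
    # eigenvalues of the covariance (1/(N-1) convention)
    return PcaModes(
        modes=lifted.T.reshape((-1,) + shape),
        eigenvalues=evals / (n - 1),
        mean_field=mean.reshape(shape),
    )


def deviation_map(v_new: np.ndarray, variance: VarianceField,
                  epsilon: float = 0.05) -> DeviationMap:
    """d(x) = v(x)/σ(x) where σ > ε, zero where the atlas has no variability.

    Where the atlas variance is high a large velocity is unremarkable; where
    it is low even a small velocity is significant.  ε (px) guards the
    division in regions the atlas population never deforms.
    """
    sigma = variance.sigma
    if v_new.shape[1:] != sigma.shape:
        raise ValueError("velocity field and variance field must share a grid")
    safe = sigma > epsilon
    d = np.where(safe[None], v_new / np.where(safe, sigma, 1.0)[None], 0.0)
    return DeviationMap(values=d, magnitude=field_norm(d))


def project_onto_modes(v_new: np.ndarray, modes: PcaModes) -> np.ndarray:
    """Projections p_j = (v_new − mean) · mode_j, in pixels (unit-norm modes)."""
    if modes.n_modes and v_new.shape != modes.modes.shape[1:]:
        raise ValueError("velocity field and modes must share a grid")
    centered = (v_new - modes.mean_field).ravel()
    return np.array([centered @ m.ravel() for m in modes.modes])


def compute_asd(
    rep_new: np.ndarray,
    atlas: AtlasModel,
    variance: VarianceField | None = None,
    modes: PcaModes | None = None,
    config: DemonsConfig | None = None,
    epsilon: float = 0.05,
    region: np.ndarray | None = None,
) -> tuple[ShapeDescriptor, DeviationMap]:
    """Atlas-based shape descriptor of a new (already represented) image.

    Registers the four-cluster representation onto the average model, builds
    the local deviation map and takes its mean/max over ``region`` (default:
    whole patch), plus the projections onto all retained modes.
    """
    if rep_new.shape != atlas.average_rep.shape:
        raise ValueError(
            f"grid mismatch: new image {rep_new.shape} vs atlas {atlas.average_rep.shape}"
        )
    if variance is None:
        variance = variance_field(atlas.velocities)
    if modes is None:
        modes = pca_modes(atlas.velocities)
    v_new = log_demons_register(atlas.average_rep, rep_new,
                                config or atlas.config)
    dev = deviation_map(v_new, variance, epsilon)
    mag = dev.magnitude if region is None else dev.magnitude[region]
    descriptor = ShapeDescriptor(
        mean_deviation=float(mag.mean()),
        max_deviation=float(mag.max()),
        projections=project_onto_modes(v_new, modes),
    )
    return descriptor, dev
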