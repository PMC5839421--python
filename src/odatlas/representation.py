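"""Four-cluster representation of the OD region: rim, cup, vessels, background.

The representation keeps exactly the structures whose deformation carries
clinical signal — the neuroretinal rim, the cup (fitted as the ellipse
maximizing image gradients along its boundary) and the statistically
significant vessels — and discards everything else.  Registering these
piecewise-constant label images instead of raw intensities keeps the
demons forces on anatomically meaningful edges.

Vessel pixels come from a K-means clustering in RGB space inside the
(dilated) disc; vessels that only a minority of the population exhibits are
removed by building a vessels average model over the population and
thresholding its per-pixel vessel frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import minimize
from sklearn.cluster import KMeans

from . import atlas as atlas_mod
from .registration import DemonsConfig, field_exponential, log_demons_register, warp

#: scalar intensity assigned to each label in the registration encoding;
#: evenly spaced so every boundary carries a comparable gradient
DEFAULT_LEVELS = {"background": 0.0, "rim": 1.0 / 3.0, "cup": 2.0 / 3.0, "vessel": 1.0}

LABEL_BACKGROUND, LABEL_RIM, LABEL_CUP, LABEL_VESSEL = 0, 1, 2, 3


@dataclass
class CupEllipse:
    center: tuple[float, float]
    semi_axes: tuple[float, float]    # (a, b) with b <= a
    orientation: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
        dx, dy = xx - self.center[0], yy - self.center[1]
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        u = (dx * c + dy * s) / self.semi_axes[0]
        v = (-dx * s + dy * c) / self.semi_axes[1]
        return u**2 + v**2 <= 1.0

    def boundary_points(self, n: int = 90) -> np.ndarray:
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        x = self.center[0] + self.semi_axes[0] * np.cos(t) * c \
            - self.semi_axes[1] * np.sin(t) * s
        y = self.center[1] + self.semi_axes[0] * np.cos(t) * s \
            + self.semi_axes[1] * np.sin(t) * c
        return np.column_stack([x, y])


@dataclass
class FourClusterImage:
    labels: np.ndarray            # (m, m) in {0..3}
    levels: dict

    @property
    def scalar_encoding(self) -> np.ndarray:
        return encode_labels(self.labels, self.levels)


def encode_labels(labels: np.ndarray, levels: dict = DEFAULT_LEVELS) -> np.ndarray:
    lut = np.array([levels["background"], levels["rim"],
                    levels["cup"], levels["vessel"]])
    return lut[labels]


def decode_levels(scalar: np.ndarray, levels: dict = DEFAULT_LEVELS) -> np.ndarray:
    """Inverse of encode_labels by nearest level (lossless on exact encodings)."""
    lut = np.array([levels["background"], levels["rim"],
                    levels["cup"], levels["vessel"]])
    return np.abs(scalar[..., None] - lut).argmin(axis=-1)


def _patch_intensity(patch: np.ndarray) -> np.ndarray:
    if patch.ndim == 3:
        return patch.mean(axis=2)
    return patch


def _boundary_gradient_score(ellipse_params: np.ndarray,
                             grad_y: np.ndarray, grad_x: np.ndarray,
                             n_samples: int = 90) -> float:
    """Mean outward-normal gradient magnitude along the candidate boundary."""
    cx, cy, a, b, theta = ellipse_params
    if a <= 2 or b <= 2:
        return 0.0
    e = CupEllipse((cx, cy), (a, b), theta)
    pts = e.boundary_points(n_samples)
    coords = np.stack([pts[:, 1], pts[:, 0]])       # (row, col)
    gy = ndi.map_coordinates(grad_y, coords, order=1, mode="nearest")
    gx = ndi.map_coordinates(grad_x, coords, order=1, mode="nearest")
    # outward normal of the ellipse at each sample
    t = np.linspace(0, 2 * np.pi, n_samples, endpoint=False)
    c, s = np.cos(theta), np.sin(theta)
    nx_l, ny_l = np.cos(t) / a, np.sin(t) / b
    nx = nx_l * c - ny_l * s
    ny = nx_l * s + ny_l * c
    norm = np.hypot(nx, ny)
    # signed outward radial gradient: the cup is brighter than the rim, so a
    # true cup boundary has intensity falling outward; vessel crossings give
    # alternating signs and cancel instead of attracting the fit
    return float(-(gx * nx / norm + gy * ny / norm).mean())


def fit_cup_ellipse(patch: np.ndarray, disc_mask: np.ndarray,
                    center_search: float = 20.0) -> CupEllipse:
    """Fit the cup as the ellipse maximizing gradients along its border.

    Coarse grid over axes/orientation about the disc centroid followed by
    Nelder–Mead refinement of (center, axes, orientation); the result is
    clipped to lie strictly inside the disc.
    """
    if not disc_mask.any():
        raise ValueError("empty disc mask")
    intensity = ndi.gaussian_filter(_patch_intensity(patch), 2.0)
    grad_y, grad_x = np.gradient(intensity)
    if float(np.hypot(grad_y, grad_x).max()) < 1e-12:
        raise ValueError("flat patch: cup ellipse cannot be fitted")

    cy0, cx0 = ndi.center_of_mass(disc_mask)
    ys, xs = np.nonzero(disc_mask)
    disc_r = 0.5 * max(np.ptp(xs), np.ptp(ys))
    radii = np.linspace(0.25 * disc_r, 0.85 * disc_r, 10)
    thetas = np.deg2rad(np.arange(0, 180, 15))

    best, best_score = None, -np.inf
    for a in radii:
        for b in radii:
            if b > a:
                continue
            for th in (thetas if a != b else [0.0]):
                p = np.array([cx0, cy0, a, b, th])
                sc = _boundary_gradient_score(p, grad_y, grad_x)
                if sc > best_score:
                    best_score, best = sc, p

    res = minimize(
        lambda p: -_boundary_gradient_score(p, grad_y, grad_x),
        best, method="Nelder-Mead",
        options={"xatol": 0.2, "fatol": 1e-5, "maxiter": 600},
    )
    cx, cy, a, b, th = res.x if res.fun < -best_score else best
    if abs(cx - cx0) > center_search or abs(cy - cy0) > center_search:
        cx, cy = best[0], best[1]
    if b > a:
        a, b = b, a
        th += np.pi / 2
    th = (th + np.pi / 2) % np.pi - np.pi / 2
    ell = CupEllipse((float(cx), float(cy)), (float(a), float(b)), float(th))
    if np.any(ell.mask(disc_mask.shape) & ~disc_mask):
        warnings.warn("fitted cup exceeds the disc; it will be clipped")
    return ell


def segment_vessels_kmeans(patch: np.ndarray, disc_mask: np.ndarray,
                           seed: int = 0, dilate_frac: float = 0.1,
                           n_retries: int = 3) -> np.ndarray:
    """Vessels inside the (dilated) disc by 3-class K-means in RGB space.

    The cluster with the lowest mean green intensity is labelled vessel —
    vessels have maximal contrast in the green channel and are the darkest,
    reddest structure in the OD.
    """
    ys, xs = np.nonzero(disc_mask)
    if len(ys) == 0:
        raise ValueError("empty disc mask")
    disc_r = 0.5 * max(np.ptp(xs), np.ptp(ys))
    region = ndi.binary_dilation(disc_mask,
                                 iterations=max(1, int(round(dilate_frac * disc_r))))
    colors = patch[region]
    if np.unique(colors.reshape(len(colors), -1), axis=0).shape[0] < 3:
        raise ValueError("disc region has fewer than 3 distinct colors")
    for attempt in range(n_retries):
        km = KMeans(n_clusters=3, n_init=4, random_state=seed + attempt)
        labels = km.fit_predict(colors)
        if len(np.unique(labels)) == 3:
            break
    else:
        raise RuntimeError("K-means kept collapsing clusters")
    green = km.cluster_centers_[:, 1] if colors.ndim == 2 else km.cluster_centers_[:, 0]
    vessel_cluster = int(np.argmin(green))
    mask = np.zeros(disc_mask.shape, dtype=bool)
    mask[region] = labels == vessel_cluster
    return mask


def build_vessel_average_model(
    vessel_masks: list[np.ndarray],
    disc_mask: np.ndarray,
    config: DemonsConfig | None = None,
    **atlas_kwargs,
):
    """Per-pixel vessel frequency after groupwise registration.

    Each subject's two-structure scalar encoding (disc 0.5, vessels 1.0) is
    fed to the average-model construction; the subjects' binary vessel masks
    are then warped by their final velocity fields and averaged, giving the
    empirical probability of finding a vessel at each atlas location.
    Returns (probability map, AtlasModel).
    """
    if len(vessel_masks) < 2:
        raise ValueError("vessel average model needs >= 2 subjects")
    reps = [0.5 * disc_mask + 0.5 * m.astype(float) * disc_mask
            for m in vessel_masks]
    model = atlas_mod.build_average_model(reps, config, **atlas_kwargs)
    warped = [warp(m.astype(float), field_exponential(v)) > 0.5
              for m, v in zip(vessel_masks, model.velocities)]
    prob = np.mean(warped, axis=0)
    return prob, model


def simplify_vessel_model(prob: np.ndarray, threshold: float = 0.75) -> np.ndarray:
    """Keep pixels whose registered-vessel probability is strictly above threshold."""
    return np.asarray(prob) > threshold


def register_model_to_subject(simplified: np.ndarray, subject_vessels: np.ndarray,
                              config: DemonsConfig | None = None) -> np.ndarray:
    """Warp the simplified vessel model onto a subject's K-means vessels."""
    if simplified.shape != subject_vessels.shape:
        raise ValueError("masks must share a grid")
    if not subject_vessels.any():
        warnings.warn("empty subject vessel mask; returning model unchanged")
        return simplified.copy()
    v = log_demons_register(subject_vessels.astype(float),
                            simplified.astype(float), config)
    return warp(simplified.astype(float), field_exponential(v)) > 0.5


def compose_four_cluster(disc_mask: np.ndarray, cup, vessels: np.ndarray,
                         levels: dict = DEFAULT_LEVELS) -> FourClusterImage:
    """Label priority vessel > cup > rim > background, cup clipped to the disc."""
    cup_mask = cup.mask(disc_mask.shape) if isinstance(cup, CupEllipse) else cup
    if np.any(cup_mask & ~disc_mask):
        warnings.warn("cup extends outside disc; clipping")
        cup_mask = cup_mask & disc_mask
    labels = np.zeros(disc_mask.shape, dtype=np.uint8)
    labels[disc_mask] = LABEL_RIM
    labels[cup_mask] = LABEL_CUP
    labels[vessels & disc_mask] = LABEL_VESSEL
    return FourClusterImage(labels=labels, levels=dict(levels))
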