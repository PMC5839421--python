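"""Synthetic optic-disc phantoms with known geometry and deformation modes.

The generator renders the anatomy the pipeline analyses — an elliptical
disc containing a smaller, slightly temporal elliptical cup, dark-red
vessel branches converging on the disc, and a macula landmark — with exact
ground-truth masks, then samples populations by warping one template with
diffeomorphic deformations drawn from known low-dimensional modes (cup
enlargement, nasal vessel displacement) or from free smooth random fields.
Ground truth is stored as stationary velocity fields so recovery
comparisons live in the same space as the atlas statistics.

Coordinates are (x, y) with x rightward and y downward; after the left-eye
flip convention the macula sits at x greater than the disc center, so the
nasal side of the disc is toward negative x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .preprocess import Landmarks
from .registration import field_exponential, field_norm, jacobian_determinant, warp


@dataclass
class EllipseParams:
    center: tuple[float, float]        # (x, y) pixels
    semi_axes: tuple[float, float]     # (along x, along y) before rotation
    orientation: float = 0.0           # radians, counterclockwise in (x, y-down)


@dataclass
class PhantomSpec:
    """Geometry, colors and noise of one rendered OD-region phantom."""

    patch_size: int = 192
    disc: EllipseParams | None = None
    cup: EllipseParams | None = None
    vessels: list[tuple[np.ndarray, float]] | None = None   # (polyline Kx2 (x,y), width)
    colors: dict | None = None
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        m = self.patch_size
        if self.disc is None:
            self.disc = EllipseParams((0.50 * m, 0.50 * m), (0.30 * m, 0.33 * m))
        if self.cup is None:
            self.cup = EllipseParams((0.53 * m, 0.50 * m), (0.155 * m, 0.145 * m))
        if self.vessels is None:
            self.vessels = _default_vessels(m)
        if self.colors is None:
            self.colors = {
                "background": (0.80, 0.40, 0.12),
                "disc": (0.93, 0.72, 0.40),
                "cup": (0.97, 0.88, 0.62),
                "vessel": (0.40, 0.08, 0.06),
            }


def _default_vessels(m: int) -> list[tuple[np.ndarray, float]]:
    """Three main branches: superior/inferior arcades and a nasal trunk."""
    cx, cy = 0.46 * m, 0.50 * m
    w = max(2.0, 0.028 * m)
    sup = np.array([[cx, cy], [0.42 * m, 0.30 * m], [0.30 * m, 0.10 * m]])
    inf = np.array([[cx, cy], [0.42 * m, 0.70 * m], [0.30 * m, 0.90 * m]])
    nas = np.array([[cx, cy], [0.25 * m, 0.52 * m], [0.05 * m, 0.55 * m]])
    return [(sup, w), (inf, w), (nas, 0.8 * w)]


@dataclass
class Phantom:
    """One rendered subject with exact masks and ground-truth provenance.

    The continuous level maps (normalized ellipse radius for disc and cup,
    signed centerline distance for vessels) are kept alongside the binary
    masks so that deformed subjects can be produced with subpixel-accurate
    boundaries: warping the level map and re-thresholding is exact up to
    interpolation, whereas warping a binary mask quantizes the boundary.
    """

    patch: np.ndarray                  # (H, W, 3) in [0, 1]
    disc_mask: np.ndarray
    cup_mask: np.ndarray
    vessel_mask: np.ndarray
    landmarks: Landmarks
    disc_level: np.ndarray | None = None
    cup_level: np.ndarray | None = None
    vessel_signed: np.ndarray | None = None
    true_field: np.ndarray | None = None     # (2, H, W) velocity, if warped
    amplitudes: np.ndarray | None = None     # mode amplitudes, if mode-sampled
    pathological: bool = False


def _ellipse_level(m: int, e: EllipseParams) -> np.ndarray:
    """Normalized radius sqrt(f) of the ellipse implicit function on the grid."""
    yy, xx = np.mgrid[0:m, 0:m].astype(float)
    dx, dy = xx - e.center[0], yy - e.center[1]
    c, s = np.cos(e.orientation), np.sin(e.orientation)
    u = (dx * c + dy * s) / e.semi_axes[0]
    v = (-dx * s + dy * c) / e.semi_axes[1]
    return np.sqrt(u**2 + v**2)


def _ellipse_alpha(m: int, e: EllipseParams) -> np.ndarray:
    g = _ellipse_level(m, e)
    r_eff = min(e.semi_axes)
    return np.clip(0.5 + (1.0 - g) * r_eff, 0.0, 1.0)


def _segment_distance(px: np.ndarray, py: np.ndarray,
                      p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    d = p1 - p0
    length_sq = float(d @ d)
    if length_sq == 0:
        return np.hypot(px - p0[0], py - p0[1])
    t = np.clip(((px - p0[0]) * d[0] + (py - p0[1]) * d[1]) / length_sq, 0.0, 1.0)
    return np.hypot(px - (p0[0] + t * d[0]), py - (p0[1] + t * d[1]))


def _vessel_distance(m: int, vessels: list[tuple[np.ndarray, float]]) -> np.ndarray:
    """Distance to nearest vessel centerline minus half its width (signed)."""
    yy, xx = np.mgrid[0:m, 0:m].astype(float)
    signed = np.full((m, m), np.inf)
    for poly, width in vessels:
        poly = np.asarray(poly, dtype=float)
        for k in range(len(poly) - 1):
            dist = _segment_distance(xx, yy, poly[k], poly[k + 1])
            signed = np.minimum(signed, dist - width / 2.0)
    return signed


def vessel_polyline_area(vessels: list[tuple[np.ndarray, float]]) -> float:
    """Analytic length×width area of the branches (ignores overlaps/caps)."""
    area = 0.0
    for poly, width in vessels:
        poly = np.asarray(poly, dtype=float)
        length = float(np.sqrt(((poly[1:] - poly[:-1]) ** 2).sum(axis=1)).sum())
        area += length * width
    return area


def render_phantom(spec: PhantomSpec) -> Phantom:
    """Render the phantom with anti-aliased structures and exact masks."""
    m = spec.patch_size
    cup_level = _ellipse_level(m, spec.cup)
    disc_level = _ellipse_level(m, spec.disc)
    if np.any((cup_level <= 1.0) & (disc_level > 1.0)):
        raise ValueError("cup extends outside the disc")

    img = np.empty((m, m, 3))
    img[:] = spec.colors["background"]
    # faint macula for landmark plausibility
    mac = (0.93 * m, 0.55 * m)
    yy, xx = np.mgrid[0:m, 0:m].astype(float)
    mac_alpha = 0.35 * np.exp(-((xx - mac[0]) ** 2 + (yy - mac[1]) ** 2)
                              / (2 * (0.05 * m) ** 2))
    img *= (1.0 - mac_alpha[..., None] * 0.5)

    for name, ell in (("disc", spec.disc), ("cup", spec.cup)):
        alpha = _ellipse_alpha(m, ell)[..., None]
        img = img * (1 - alpha) + np.asarray(spec.colors[name]) * alpha
    signed = _vessel_distance(m, spec.vessels)
    v_alpha = np.clip(0.5 - signed, 0.0, 1.0)[..., None]
    img = img * (1 - v_alpha) + np.asarray(spec.colors["vessel"]) * v_alpha

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)

    landmarks = Landmarks(
        od_center=(spec.disc.center[0], spec.disc.center[1]),
        macula_center=mac,
        image_size=(m, m),
    )
    return Phantom(
        patch=img,
        disc_mask=disc_level <= 1.0,
        cup_mask=cup_level <= 1.0,
        vessel_mask=signed < 0.0,
        landmarks=landmarks,
        disc_level=disc_level,
        cup_level=cup_level,
        vessel_signed=signed,
    )


# ---------------------------------------------------------------------------
# deformation modes


@dataclass
class ModeSpec:
    """Known low-dimensional deformation modes of a phantom population.

    basis: (k, 2, H, W) mutually orthogonal fields, each scaled to unit
    maximum magnitude so amplitudes are in pixels.  pathology is an extra
    field (same normalization) whose positive amplitudes enlarge the cup
    and push the vessels nasally.
    """

    basis: np.ndarray
    amplitude_sds: np.ndarray
    pathology: np.ndarray | None = None


def _global_radial_mode(m: int, center: tuple[float, float],
                        sigma: float) -> np.ndarray:
    """Gaussian-windowed linear expansion about ``center`` (disc+cup growth)."""
    yy, xx = np.mgrid[0:m, 0:m].astype(float)
    dx, dy = xx - center[0], yy - center[1]
    g = np.exp(-(dx**2 + dy**2) / (2 * sigma**2))
    return np.stack([g * dy, g * dx])


def _ring_radial_mode(m: int, center: tuple[float, float], r0: float,
                      width: float, inward: bool = False) -> np.ndarray:
    """Radial field concentrated in a ring of radius r0 (local cup dilation)."""
    yy, xx = np.mgrid[0:m, 0:m].astype(float)
    dx, dy = xx - center[0], yy - center[1]
    r = np.hypot(dx, dy)
    g = np.exp(-(r - r0) ** 2 / (2 * width**2))
    with np.errstate(invalid="ignore"):
        ux = np.where(r > 0, dx / np.where(r > 0, r, 1.0), 0.0)
        uy = np.where(r > 0, dy / np.where(r > 0, r, 1.0), 0.0)
    sign = -1.0 if inward else 1.0
    return sign * np.stack([g * uy, g * ux])


def _shift_mode(m: int, center: tuple[float, float], s: float,
                direction: tuple[float, float]) -> np.ndarray:
    """Gaussian-windowed uniform shift, |v| max 1, direction in (x, y)."""
    yy, xx = np.mgrid[0:m, 0:m].astype(float)
    g = np.exp(-((xx - center[0]) ** 2 + (yy - center[1]) ** 2) / (2 * s**2))
    dx, dy = direction
    norm = np.hypot(dx, dy)
    return np.stack([g * dy / norm, g * dx / norm])


def _orthonormalize_maxnorm(fields: list[np.ndarray]) -> np.ndarray:
    """Gram–Schmidt in the flattened space, then rescale to max |v| = 1."""
    out = []
    for f in fields:
        g = f.astype(float).copy()
        for prev in out:
            g -= (g.ravel() @ prev.ravel()) / (prev.ravel() @ prev.ravel()) * prev
        g /= field_norm(g).max()
        out.append(g)
    return np.stack(out)


def make_default_modes(spec: PhantomSpec,
                       amplitude_sds: tuple[float, ...] = (2.5, 1.8)) -> ModeSpec:
    """Two orthogonal healthy modes plus the pathology direction.

    Mode 0: simultaneous enlargement of disc and cup — a broad Gaussian-
    windowed expansion about the disc center, the dominant healthy variation.
    Mode 1: nasal displacement of the vessels and OD content — a broad
    horizontal shift windowed slightly nasal of the disc center.
    Both are smooth at the scale of the disc, so the deformation they induce
    is observable at the representation's boundaries everywhere.

    Pathology: a cup-boundary-localized enlargement ring plus a tighter
    nasal shift over the vessel trunk.  Warping a subject by
    exp(a·pathology), a > 0, enlarges the cup and pushes the vessels
    nasally under backward warping — deformations a healthy population
    only shows in milder, more global form.

    Default amplitude standard deviations are in pixels of peak displacement
    per unit amplitude (each basis field has unit maximum magnitude).
    """
    m = spec.patch_size
    basis = _orthonormalize_maxnorm([
        _global_radial_mode(m, spec.disc.center, 0.29 * m),
        _shift_mode(m, (0.45 * m, 0.50 * m), 0.31 * m, (1.0, 0.0)),
    ])
    path = _ring_radial_mode(m, spec.cup.center, 1.05 * max(spec.cup.semi_axes),
                             0.08 * m, inward=True) \
        + 0.6 * _shift_mode(m, (0.30 * m, 0.52 * m), 0.16 * m, (1.0, 0.0))
    path = path / field_norm(path).max()
    return ModeSpec(basis=basis, amplitude_sds=np.asarray(amplitude_sds),
                    pathology=path)


def random_smooth_field(shape: tuple[int, int], amplitude: float,
                        sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean random field scaled to maximum magnitude `amplitude`."""
    noise = rng.normal(size=(2,) + shape)
    smooth = np.stack([gaussian_filter(noise[c], sigma, mode="reflect")
                       for c in range(2)])
    peak = field_norm(smooth).max()
    return smooth * (amplitude / peak)


def _warp_phantom(template: Phantom, v: np.ndarray, *,
                  amplitudes: np.ndarray | None = None,
                  pathological: bool = False) -> Phantom:
    """Deform a phantom by exp(v), keeping subpixel-accurate boundaries.

    Continuous level maps are warped and re-thresholded (far-field padding
    keeps structures from leaking in at the border); binary masks are only
    warped directly when a template lacks level maps.
    """
    phi = field_exponential(v)
    if template.disc_level is not None:
        disc_lv = warp(template.disc_level, phi, cval=10.0)
        cup_lv = warp(template.cup_level, phi, cval=10.0)
        ves_sd = warp(template.vessel_signed, phi, cval=1e3)
        masks = [disc_lv <= 1.0, cup_lv <= 1.0, ves_sd < 0.0]
        levels = (disc_lv, cup_lv, ves_sd)
    else:
        masks = [
            warp(mk.astype(float), phi) > 0.5
            for mk in (template.disc_mask, template.cup_mask, template.vessel_mask)
        ]
        levels = (None, None, None)
    prev = template.true_field
    return Phantom(
        patch=np.clip(warp(template.patch, phi), 0.0, 1.0),
        disc_mask=masks[0],
        cup_mask=masks[1],
        vessel_mask=masks[2],
        landmarks=template.landmarks,
        disc_level=levels[0],
        cup_level=levels[1],
        vessel_signed=levels[2],
        true_field=v if prev is None else prev + v,
        amplitudes=amplitudes if amplitudes is not None else template.amplitudes,
        pathological=pathological or template.pathological,
    )


def _diffeomorphic(v: np.ndarray) -> bool:
    return float(jacobian_determinant(field_exponential(v)).min()) > 0.0


def sample_population(
    template: PhantomSpec,
    modes: ModeSpec | None,
    n: int,
    seed: int = 0,
    field_sigma: float = 8.0,
    field_amplitude: float = 5.0,
    max_tries: int = 20,
) -> list[Phantom]:
    """Render ``n`` subjects by warping the template with random deformations.

    With ``modes`` given, subject i is warped by exp(Σ_j a_ij mode_j) with
    a_ij ~ N(0, sd_j²); otherwise free smooth random fields (Gaussian
    smoothing ``field_sigma`` px, maximum magnitude uniform in
    (0.3, 1]·``field_amplitude``) are used.  Non-diffeomorphic draws are
    rejected and resampled.  The template's per-subject rendering noise is
    reseeded per subject so intensity noise is independent across subjects.
    """
    if n < 2:
        raise ValueError("population needs n >= 2")
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        spec_i = replace(template, seed=int(rng.integers(2**31)))
        base = render_phantom(spec_i)
        for attempt in range(max_tries):
            if modes is not None:
                a = rng.normal(0.0, modes.amplitude_sds)
                v = np.tensordot(a, modes.basis, axes=1)
            else:
                a = None
                amp = rng.uniform(0.3, 1.0) * field_amplitude
                v = random_smooth_field(base.patch.shape[:2], amp, field_sigma, rng)
            if _diffeomorphic(v):
                break
            warnings.warn("non-diffeomorphic draw rejected; resampling")
        subjects.append(_warp_phantom(base, v, amplitudes=a))
    return subjects


def make_pathological(subject: Phantom, pathology_mode: np.ndarray,
                      amplitude: float, max_tries: int = 20) -> Phantom:
    """Apply the pathology deformation on top of a subject's own warp."""
    if amplitude < 0:
        raise ValueError("pathology amplitude must be non-negative")
    if amplitude == 0:
        return subject
    v = amplitude * pathology_mode
    if not _diffeomorphic(v):
        raise ValueError("requested pathology amplitude folds the deformation")
    return _warp_phantom(subject, v, pathological=True)


# ---------------------------------------------------------------------------
# vessel-only populations (for the simplified-vessel-model experiments)


def sample_vessel_population(
    n: int,
    patch_size: int = 192,
    extra_branch_fraction: float = 0.3,
    jitter_amplitude: float = 2.0,
    seed: int = 0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Binary vessel masks sharing 3 main branches, plus rare extra branches.

    Each subject carries the template's three branches under a small smooth
    diffeomorphic jitter; a fraction of subjects (at most
    ``extra_branch_fraction``) additionally shows a cilioretinal-style
    temporal branch.  Returns (vessel masks, shared disc mask).
    """
    rng = np.random.default_rng(seed)
    m = patch_size
    spec = PhantomSpec(patch_size=m, noise_sd=0.0)
    base = render_phantom(spec)
    extra = (np.array([[0.46 * m, 0.50 * m], [0.62 * m, 0.40 * m],
                       [0.80 * m, 0.32 * m]]), max(2.0, 0.022 * m))
    n_extra = int(np.floor(extra_branch_fraction * n))
    has_extra = np.zeros(n, dtype=bool)
    has_extra[rng.choice(n, size=n_extra, replace=False)] = True

    masks = []
    for i in range(n):
        vessels = list(spec.vessels) + ([extra] if has_extra[i] else [])
        signed = _vessel_distance(m, vessels)
        v = random_smooth_field((m, m), jitter_amplitude, 8.0, rng)
        masks.append(warp(signed, field_exponential(v), cval=1e3) < 0.0)
    return masks, base.disc_mask
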