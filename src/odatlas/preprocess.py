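"""Landmark-driven pose normalization of fundus images.

Every image is brought into a common OD-centered frame in three steps:
(1) right eyes are mirrored into left eyes about the vertical axis through
the image center, so the macula always lies at x ≥ the OD center;
(2) the pose of each image is summarized by the angle α between the
horizontal and the macula–OD axis and by the macula–OD distance d;
(3) a similarity transform (scale d_avg/d_i, rotation α_i − α_avg,
translation fixing the OD onto the population-mean OD center) maps every
image into the mean pose, and an m×m patch centered on the mean OD center
is extracted.

Coordinates are 0-based pixel-centered (x right, y down); angles follow
α = arctan((y_OD − y_mac)/(x_mac − x_OD)), so a macula below the OD gives a
negative angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp as sk_warp


@dataclass
class Landmarks:
    od_center: tuple[float, float]
    macula_center: tuple[float, float]
    image_size: tuple[int, int]          # (width, height)

    def __post_init__(self) -> None:
        if tuple(self.od_center) == tuple(self.macula_center):
            raise ValueError("degenerate landmarks: OD and macula coincide")
        w, h = self.image_size
        for x, y in (self.od_center, self.macula_center):
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError("landmark outside image bounds")

    @property
    def image_center(self) -> tuple[float, float]:
        w, h = self.image_size
        return ((w - 1) / 2.0, (h - 1) / 2.0)


@dataclass
class Pose:
    angle: float       # radians in [-pi/2, pi/2]
    distance: float    # pixels, > 0


@dataclass
class PoseStats:
    mean_distance: float
    mean_angle: float
    mean_od_center: tuple[float, float]


@dataclass
class AffineParams:
    scale: float
    rotation: float
    translation: tuple[float, float]
    flipped: bool

    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        a = self.scale * np.array([[c, -s], [s, c]])
        m = np.eye(3)
        m[:2, :2] = a
        m[:2, 2] = self.translation
        return m

    def apply(self, xy: tuple[float, float]) -> tuple[float, float]:
        v = self.matrix() @ np.array([xy[0], xy[1], 1.0])
        return (float(v[0]), float(v[1]))


@dataclass
class FundusPatch:
    """Pose-normalized m×m RGB patch with its provenance transform."""

    pixels: np.ndarray                 # (m, m, 3) in [0, 1]
    patch_size: int
    source_affine: AffineParams
    pad_mask: np.ndarray               # True where padded (outside source)


def flip_to_left_eye(image: np.ndarray, landmarks: Landmarks):
    """Mirror right eyes about the vertical axis through the image center.

    Returns (image, landmarks, flipped).  Output always satisfies
    x_mac − x_OD ≥ 0.
    """
    xod, yod = landmarks.od_center
    xmac, ymac = landmarks.macula_center
    if xmac - xod >= 0:
        return image, landmarks, False
    w = landmarks.image_size[0]
    two_xc = 2.0 * landmarks.image_center[0]   # = w - 1 with 0-based centers
    flipped_lm = Landmarks(
        od_center=(two_xc - xod, yod),
        macula_center=(two_xc - xmac, ymac),
        image_size=landmarks.image_size,
    )
    return image[:, ::-1].copy(), flipped_lm, True


def compute_pose(landmarks: Landmarks) -> Pose:
    """Angle α = arctan((y_OD − y_mac)/(x_mac − x_OD)) and macula–OD distance."""
    xod, yod = landmarks.od_center
    xmac, ymac = landmarks.macula_center
    dx = xmac - xod
    if dx == 0:
        raise ValueError("macula and OD share x coordinate; angle undefined")
    angle = float(np.arctan((-ymac + yod) / dx))
    distance = float(np.hypot(dx, ymac - yod))
    return Pose(angle=angle, distance=distance)


def population_pose_stats(poses: list[Pose],
                          od_centers: list[tuple[float, float]]) -> PoseStats:
    """Arithmetic means of distances, angles and OD centers over the population."""
    if len(poses) == 0:
        raise ValueError("empty population")
    if len(poses) != len(od_centers):
        raise ValueError("poses and OD centers must align")
    centers = np.asarray(od_centers, dtype=float)
    return PoseStats(
        mean_distance=float(np.mean([p.distance for p in poses])),
        mean_angle=float(np.mean([p.angle for p in poses])),
        mean_od_center=(float(centers[:, 0].mean()), float(centers[:, 1].mean())),
    )


def affine_params(pose: Pose, od_center: tuple[float, float],
                  stats: PoseStats, flipped: bool = False) -> AffineParams:
    """Similarity transform mapping a subject into the population mean pose.

    A x = s R(α − α_avg) x + T with s = d_avg/d and T chosen so the OD
    center lands exactly on the mean OD center.
    """
    s = stats.mean_distance / pose.distance
    beta = pose.angle - stats.mean_angle
    c, si = np.cos(beta), np.sin(beta)
    rot = s * np.array([[c, -si], [si, c]])
    t = np.asarray(stats.mean_od_center) - rot @ np.asarray(od_center)
    return AffineParams(scale=s, rotation=beta,
                        translation=(float(t[0]), float(t[1])), flipped=flipped)


def affine_normalize(image: np.ndarray, landmarks: Landmarks,
                     stats: PoseStats, m: int = 384) -> FundusPatch:
    """Resample a flipped image into the mean pose and crop the OD patch.

    The m×m window is centered on the mean OD center; pixels whose source
    coordinates fall outside the image are padded with 0 and flagged in the
    pad mask.  Bilinear interpolation.
    """
    pose = compute_pose(landmarks)
    params = affine_params(pose, landmarks.od_center, stats)
    # patch pixel (u, v) corresponds to warped-image point (u, v) + offset
    ox = stats.mean_od_center[0] - (m - 1) / 2.0
    oy = stats.mean_od_center[1] - (m - 1) / 2.0
    full = AffineTransform(matrix=params.matrix())
    crop = AffineTransform(translation=(ox, oy))
    tform = crop + full.inverse    # maps patch coords -> source coords

    img = np.asarray(image, dtype=float)
    if img.max() > 1.0:
        img = img / 255.0
    patch = sk_warp(img, tform, output_shape=(m, m) + img.shape[2:],
                    order=1, mode="constant", cval=0.0, preserve_range=True)

    uu, vv = np.meshgrid(np.arange(m), np.arange(m), indexing="xy")
    src = tform(np.column_stack([uu.ravel(), vv.ravel()]))
    w, h = landmarks.image_size
    outside = ((src[:, 0] < 0) | (src[:, 0] > w - 1)
               | (src[:, 1] < 0) | (src[:, 1] > h - 1))
    pad_mask = outside.reshape(m, m)
    return FundusPatch(pixels=patch, patch_size=m,
                       source_affine=params, pad_mask=pad_mask)
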