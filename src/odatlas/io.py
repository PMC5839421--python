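"""Readers/writers and pipeline configuration.

Formats: masks and four-cluster label images as single-channel PNG
(labels stored at {0, 85, 170, 255} with a JSON sidecar mapping), velocity
fields and atlases as HDF5 (separate ``vx``/``vy`` datasets with grid
metadata), descriptors as CSV/JSON, configuration as YAML.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import yaml
from PIL import Image

from .atlas import AtlasModel
from .registration import DemonsConfig

ATLAS_FORMAT_VERSION = 1

#: PNG grey values for the four labels, index = label id
LABEL_PNG_VALUES = (0, 85, 170, 255)


@dataclass
class PipelineConfig:
    """All pipeline parameters in one validated, YAML-serializable object."""

    patch_size: int = 384
    demons: DemonsConfig = field(default_factory=DemonsConfig)
    vessel_threshold: float = 0.75
    encoding_levels: dict = field(default_factory=lambda: {
        "background": 0.0, "rim": 1.0 / 3.0, "cup": 2.0 / 3.0, "vessel": 1.0,
    })
    deviation_epsilon: float = 0.05
    atlas_max_iters: int = 10
    atlas_mean_field_tol: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.demons, dict):
            self.demons = DemonsConfig.from_dict(self.demons)
        if self.patch_size < 16:
            raise ValueError("patch_size must be >= 16")
        if not 0.0 < self.vessel_threshold < 1.0:
            raise ValueError("vessel_threshold must lie in (0, 1)")
        expected = {"background", "rim", "cup", "vessel"}
        if set(self.encoding_levels) != expected:
            raise ValueError(f"encoding_levels must define exactly {expected}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["demons"] = self.demons.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# images and masks


def save_image(path, image: np.ndarray) -> None:
    """Write an RGB or grey float image in [0,1] (or bool mask) as 8-bit PNG."""
    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    elif arr.dtype.kind == "f":
        arr = (np.clip(arr, 0, 1) * 255).round().astype(np.uint8)
    Image.fromarray(arr).save(path)


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF as float in [0,1] (RGB kept, alpha dropped)."""
    img = np.asarray(Image.open(path))
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[..., :3]
    scale = 65535.0 if img.dtype == np.uint16 else 255.0
    return img.astype(float) / scale


def load_mask(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def save_labels(path, labels: np.ndarray) -> None:
    """Four-cluster label PNG plus a JSON sidecar mapping grey values to labels."""
    lut = np.array(LABEL_PNG_VALUES, dtype=np.uint8)
    Image.fromarray(lut[labels]).save(path)
    sidecar = {str(v): name for v, name in
               zip(LABEL_PNG_VALUES, ("background", "rim", "cup", "vessel"))}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_labels(path) -> np.ndarray:
    grey = np.asarray(Image.open(path).convert("L")).astype(int)
    lut = np.asarray(LABEL_PNG_VALUES)
    return np.abs(grey[..., None] - lut).argmin(axis=-1).astype(np.uint8)


# ---------------------------------------------------------------------------
# velocity fields and atlases (HDF5)


def _write_field(group: h5py.Group, name: str, v: np.ndarray) -> None:
    g = group.create_group(name)
    g.create_dataset("vy", data=v[0], compression="gzip")
    g.create_dataset("vx", data=v[1], compression="gzip")
    g.attrs["grid_shape"] = v.shape[1:]


def _read_field(group: h5py.Group) -> np.ndarray:
    return np.stack([group["vy"][()], group["vx"][()]])


def save_field(path, v: np.ndarray) -> None:
    with h5py.File(path, "w") as f:
        _write_field(f, "field", v)


def load_field(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return _read_field(f["field"])


def save_atlas(path, model: AtlasModel) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = ATLAS_FORMAT_VERSION
        f.attrs["population_size"] = model.population_size
        f.attrs["converged"] = model.converged
        f.attrs["config"] = json.dumps(model.config.to_dict())
        f.create_dataset("average_rep", data=model.average_rep, compression="gzip")
        if model.average_rgb is not None:
            f.create_dataset("average_rgb", data=model.average_rgb,
                             compression="gzip")
        vel = f.create_group("velocities")
        for i, v in enumerate(model.velocities):
            _write_field(vel, f"{i:04d}", v)
        trace = f.create_group("iteration_trace")
        for key in ("mean_field_norm", "mean_residual"):
            trace.create_dataset(
                key, data=np.array([t[key] for t in model.iteration_trace]))
        if model.subject_ids is not None:
            f.create_dataset("subject_ids",
                             data=np.array(model.subject_ids, dtype="S"))


def load_atlas(path) -> AtlasModel:
    with h5py.File(path, "r") as f:
        version = int(f.attrs["format_version"])
        if version > ATLAS_FORMAT_VERSION:
            raise ValueError(f"atlas format version {version} is newer than supported")
        n = int(f.attrs["population_size"])
        vel = [_read_field(f["velocities"][k]) for k in sorted(f["velocities"])]
        trace = [
            {"iteration": i, "mean_field_norm": float(a), "mean_residual": float(b)}
            for i, (a, b) in enumerate(zip(f["iteration_trace"]["mean_field_norm"],
                                           f["iteration_trace"]["mean_residual"]))
        ]
        ids = None
        if "subject_ids" in f:
            ids = [s.decode() for s in f["subject_ids"][()]]
        return AtlasModel(
            average_rep=f["average_rep"][()],
            average_rgb=f["average_rgb"][()] if "average_rgb" in f else None,
            velocities=vel,
            iteration_trace=trace,
            population_size=n,
            converged=bool(f.attrs["converged"]),
            config=DemonsConfig.from_dict(json.loads(f.attrs["config"])),
            subject_ids=ids,
        )


# ---------------------------------------------------------------------------
# landmarks, descriptors, overlays


def save_landmarks(path, landmarks) -> None:
    Path(path).write_text(json.dumps({
        "od_x": landmarks.od_center[0], "od_y": landmarks.od_center[1],
        "mac_x": landmarks.macula_center[0], "mac_y": landmarks.macula_center[1],
        "width": landmarks.image_size[0], "height": landmarks.image_size[1],
    }, indent=1))


def load_landmarks(path):
    from .preprocess import Landmarks

    d = json.loads(Path(path).read_text())
    return Landmarks(od_center=(d["od_x"], d["od_y"]),
                     macula_center=(d["mac_x"], d["mac_y"]),
                     image_size=(d["width"], d["height"]))


def save_descriptor_csv(path, rows: list[dict]) -> None:
    """One row per image: id, mean_deviation, max_deviation, p0..p_{k-1}."""
    if not rows:
        raise ValueError("no descriptor rows to write")
    n_proj = len(rows[0]["projections"])
    header = ["id", "mean_deviation", "max_deviation"] + \
        [f"p{j}" for j in range(n_proj)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for r in rows:
            w.writerow([r["id"], r["mean_deviation"], r["max_deviation"],
                        *r["projections"]])


def save_deviation_overlay(path, patch: np.ndarray, magnitude: np.ndarray,
                           vmax: float | None = None) -> None:
    """Heatmap of the local deviation magnitude over the input patch."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4), dpi=120)
    base = patch if patch.ndim == 3 else np.stack([patch] * 3, axis=-1)
    ax.imshow(np.clip(base, 0, 1))
    im = ax.imshow(magnitude, cmap="inferno", alpha=0.55, vmax=vmax)
    fig.colorbar(im, ax=ax, fraction=0.046)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
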