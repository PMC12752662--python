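"""File interchange: TIFF stacks for volumes and SEM fields, JSON sidecars
for planted truth and masks, two-column text for diffraction profiles."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .diffraction import DiffractionProfile
from .phantom import PhantomVolume, SEMField

__all__ = [
    "save_volume",
    "load_volume",
    "save_sem_field",
    "load_sem_field",
    "save_profile",
    "load_profile",
]


def _truth_to_json(truth: dict) -> dict:
    out = {}
    for k, v in truth.items():
        if k == "spec":
            d = dataclasses.asdict(v)
            # profiles may be callables; persist their sampled values instead
            for key in ("septum_width_profile", "septum_length_profile"):
                if callable(d.get(key)):
                    d[key] = [d[key](h) for h in np.linspace(0, 1, 11)]
            out[k] = d
        elif isinstance(v, np.ndarray):
            out[k] = v.tolist()
        else:
            out[k] = v
    return out


def save_volume(volume: PhantomVolume, basepath: str | Path) -> dict[str, Path]:
    """Write gray (16-bit), labels and septum labels (8-bit) TIFF stacks plus
    a JSON truth sidecar; returns the paths written."""
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "gray": basepath.with_suffix(".gray.tif"),
        "labels": basepath.with_suffix(".labels.tif"),
        "septa": basepath.with_suffix(".septa.tif"),
        "truth": basepath.with_suffix(".truth.json"),
    }
    gray = np.clip(np.round(volume.gray), 0, 65535).astype(np.uint16)
    # store as z-major pages
    tifffile.imwrite(paths["gray"], np.moveaxis(gray, 2, 0))
    tifffile.imwrite(paths["labels"], np.moveaxis(volume.labels, 2, 0))
    tifffile.imwrite(paths["septa"], np.moveaxis(volume.septum_labels, 2, 0))
    sidecar = {"voxel_size_um": volume.voxel_size, "truth": _truth_to_json(volume.truth)}
    paths["truth"].write_text(json.dumps(sidecar, indent=2))
    return paths


def load_volume(basepath: str | Path) -> PhantomVolume:
    basepath = Path(basepath)
    gray = np.moveaxis(tifffile.imread(basepath.with_suffix(".gray.tif")), 0, 2)
    labels = np.moveaxis(tifffile.imread(basepath.with_suffix(".labels.tif")), 0, 2)
    septa = np.moveaxis(tifffile.imread(basepath.with_suffix(".septa.tif")), 0, 2)
    sidecar = json.loads(basepath.with_suffix(".truth.json").read_text())
    truth = {
        k: (np.asarray(v) if isinstance(v, list) else v)
        for k, v in sidecar["truth"].items()
    }
    return PhantomVolume(
        gray=gray.astype(float),
        labels=labels.astype(np.uint8),
        septum_labels=septa.astype(np.uint8),
        voxel_size=float(sidecar["voxel_size_um"]),
        truth=truth,
    )


def save_sem_field(fieldobj: SEMField, basepath: str | Path) -> dict[str, Path]:
    """SEM image as TIFF plus a JSON manifest of run-length-free full masks
    (stored as nested 0/1 lists; fields are small)."""
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": basepath.with_suffix(".sem.tif"),
        "masks": basepath.with_suffix(".masks.json"),
    }
    tifffile.imwrite(paths["image"], fieldobj.image.astype(np.float32))
    manifest = {name: np.argwhere(m).tolist() for name, m in fieldobj.masks.items()}
    manifest["_shape"] = list(fieldobj.image.shape)
    paths["masks"].write_text(json.dumps(manifest))
    return paths


def load_sem_field(basepath: str | Path) -> SEMField:
    basepath = Path(basepath)
    image = tifffile.imread(basepath.with_suffix(".sem.tif")).astype(float)
    manifest = json.loads(basepath.with_suffix(".masks.json").read_text())
    shape = tuple(manifest.pop("_shape"))
    masks = {}
    for name, idx in manifest.items():
        m = np.zeros(shape, dtype=bool)
        if idx:
            arr = np.asarray(idx)
            m[arr[:, 0], arr[:, 1]] = True
        masks[name] = m
    return SEMField(image=image, masks=masks)


def save_profile(profile: DiffractionProfile, path: str | Path) -> Path:
    """Two-column whitespace-delimited text: 2-theta [deg], intensity [counts]."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(
        path,
        np.column_stack([profile.two_theta, profile.intensity]),
        header="two_theta_deg intensity_counts",
    )
    return path


def load_profile(path: str | Path) -> DiffractionProfile:
    data = np.loadtxt(path)
    return DiffractionProfile(two_theta=data[:, 0], intensity=data[:, 1])
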