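"""Reading and writing of sinograms, datasets, images and configs.

Arrays travel as HDF5 (with geometry/profile recorded as JSON attributes) or
32-bit float TIFF for quick inspection; configs are plain YAML mappings.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import tifffile
import yaml

from .classic import IterativeConfig
from .geometry import GeometryConfig, SensitivityProfile
from .phantoms import TrainingSet
from .projector import Sinogram

__all__ = [
    "save_image",
    "load_image",
    "save_sinogram",
    "load_sinogram",
    "save_training_set",
    "load_training_set",
    "load_config",
    "save_config",
]

PathLike = Union[str, Path]


def save_image(path: PathLike, image: np.ndarray) -> None:
    """Write a 2-D image as 32-bit float TIFF (or HDF5 if suffix is .h5)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("image", data=np.asarray(image, dtype=np.float32))
    else:
        tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def load_image(path: PathLike) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return f["image"][...].astype(float)
    return tifffile.imread(path).astype(float)


def save_sinogram(path: PathLike, sinogram: Sinogram,
                  profile: Optional[SensitivityProfile] = None) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("sinogram", data=sinogram.values)
        d.attrs["geometry"] = json.dumps(sinogram.geometry.to_dict())
        f.create_dataset("angles", data=sinogram.angles)
        if profile is not None:
            d.attrs["profile"] = json.dumps(profile.to_dict())


def load_sinogram(path: PathLike):
    """Returns ``(Sinogram, SensitivityProfile | None)``."""
    with h5py.File(path, "r") as f:
        d = f["sinogram"]
        geometry = GeometryConfig.from_dict(json.loads(d.attrs["geometry"]))
        profile = None
        if "profile" in d.attrs:
            profile = SensitivityProfile.from_dict(json.loads(d.attrs["profile"]))
        return Sinogram(d[...], geometry), profile


def save_training_set(path: PathLike, ds: TrainingSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=ds.images.astype(np.float32))
        f.create_dataset("sinograms", data=ds.sinograms.astype(np.float32))
        f.create_dataset("fbp", data=ds.fbp.astype(np.float32))
        f.create_dataset("train_idx", data=ds.train_idx)
        f.create_dataset("val_idx", data=ds.val_idx)
        f.attrs["geometry"] = json.dumps(ds.geometry.to_dict())
        f.attrs["profile"] = json.dumps(ds.profile.to_dict())
        f.attrs["master_seed"] = ds.master_seed


def load_training_set(path: PathLike) -> TrainingSet:
    with h5py.File(path, "r") as f:
        return TrainingSet(
            images=f["images"][...].astype(float),
            sinograms=f["sinograms"][...].astype(float),
            fbp=f["fbp"][...].astype(float),
            train_idx=f["train_idx"][...],
            val_idx=f["val_idx"][...],
            geometry=GeometryConfig.from_dict(json.loads(f.attrs["geometry"])),
            profile=SensitivityProfile.from_dict(json.loads(f.attrs["profile"])),
            master_seed=int(f.attrs["master_seed"]),
        )


def save_config(path: PathLike, geometry: GeometryConfig,
                profile: SensitivityProfile,
                iterative: Optional[IterativeConfig] = None) -> None:
    doc = {"geometry": geometry.to_dict(), "profile": profile.to_dict()}
    if iterative is not None:
        doc["iterative"] = asdict(iterative)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def load_config(path: PathLike):
    """Returns ``(GeometryConfig, SensitivityProfile, IterativeConfig)``.

    Missing sections fall back to defaults.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    geometry = GeometryConfig.from_dict(doc.get("geometry", {}))
    profile = SensitivityProfile.from_dict(doc.get("profile", {}))
    iterative = IterativeConfig(**doc.get("iterative", {}))
    return geometry, profile, iterative
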