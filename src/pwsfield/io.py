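"""File formats: HDF5/TIFF image cubes, CSV tables, YAML configuration."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .forward import ImageCube

__all__ = [
    "write_cube_h5",
    "read_cube_h5",
    "write_cube_tiff",
    "read_cube_tiff",
    "write_json",
    "read_json",
    "load_yaml",
    "dump_yaml",
]


def write_cube_h5(cube: ImageCube, path: str | Path) -> None:
    """HDF5 layout: /reflectance (nx, ny, n_wl), /wavelengths_nm, root attrs."""
    with h5py.File(path, "w") as f:
        f.create_dataset("reflectance", data=cube.reflectance)
        f.create_dataset("wavelengths_nm", data=cube.wavelengths)
        for key, val in cube.metadata.items():
            f.attrs[key] = val


def read_cube_h5(path: str | Path) -> ImageCube:
    with h5py.File(path, "r") as f:
        return ImageCube(
            reflectance=f["reflectance"][()],
            wavelengths=f["wavelengths_nm"][()],
            metadata={k: _attr_to_py(v) for k, v in f.attrs.items()},
        )


def _attr_to_py(v):
    if isinstance(v, np.generic):
        return v.item()
    return v


def write_cube_tiff(cube: ImageCube, path: str | Path) -> None:
    """Multi-page TIFF (one page per wavelength) plus a sidecar wavelength CSV."""
    path = Path(path)
    # pages are (x, y) images indexed by wavelength
    stack = np.moveaxis(cube.reflectance, 2, 0).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack", metadata={"axes": "ZYX"})
    sidecar = path.with_suffix(path.suffix + ".wavelengths.csv")
    pd.DataFrame({"wavelength_nm": cube.wavelengths}).to_csv(sidecar, index=False)


def read_cube_tiff(path: str | Path) -> ImageCube:
    path = Path(path)
    stack = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".wavelengths.csv")
    if not sidecar.exists():
        raise FileNotFoundError(f"wavelength sidecar not found: {sidecar}")
    wl = pd.read_csv(sidecar)["wavelength_nm"].to_numpy(float)
    return ImageCube(
        reflectance=np.moveaxis(np.asarray(stack, float), 0, 2),
        wavelengths=wl,
        metadata={"source": str(path)},
    )


def write_json(obj: dict, path: str | Path) -> None:
    """Pretty-printed, key-sorted JSON for diff-stable outputs."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def dump_yaml(obj: dict, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(obj, sort_keys=True, default_flow_style=False)
    if path is not None:
        Path(path).write_text(text)
    return text
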