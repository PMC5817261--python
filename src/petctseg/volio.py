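"""Standard-format I/O: NIfTI-1 volumes, HDF5 sinograms, YAML run configs."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .phantom import VoxelGrid


def write_volume(data: np.ndarray, grid: VoxelGrid, path: str | Path) -> Path:
    """Write a 3D field as NIfTI-1; integer arrays are stored as int16."""
    path = Path(path)
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer) or data.dtype == bool:
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float32)
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a NIfTI-1 volume; returns (data, VoxelGrid)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D payload, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    grid = VoxelGrid(shape=data.shape, spacing=spacing, origin=origin)
    return data, grid


def load_case(ct_path, pet_path, labels_path):
    """Load a co-registered (ct, pet, labels) case, validating shapes."""
    ct, grid = read_volume(ct_path)
    pet, pgrid = read_volume(pet_path)
    labels, lgrid = read_volume(labels_path)
    if not (grid.shape == pgrid.shape == lgrid.shape):
        raise ValueError(
            f"shape mismatch between case volumes: ct {grid.shape}, "
            f"pet {pgrid.shape}, labels {lgrid.shape}"
        )
    return ct, pet, labels.astype(np.int16), grid


def write_sinogram(sino, path: str | Path, expectation=None) -> Path:
    """Store a sinogram stack (and optionally its expectation) as HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=sino.data)
        f.attrs["bin_width_mm"] = sino.bin_width_mm
        f.create_dataset("angles", data=sino.angles)
        if expectation is not None:
            f.create_dataset("expectation", data=expectation.data)
    return path


def read_sinogram(path: str | Path):
    from .petsim import Sinogram

    with h5py.File(path, "r") as f:
        return Sinogram(
            data=f["counts"][...],
            bin_width_mm=float(f.attrs["bin_width_mm"]),
            angles=f["angles"][...],
        )


@dataclass
class RunConfig:
    """Parameters of a pipeline run; every seed is recorded in outputs."""

    output_dir: str = "runs"
    grid_shape: tuple = (96, 96, 192)
    spacing_mm: float = 4.0
    n_phantoms: int = 70
    phantom_seed: int = 0
    noise_seed: int = 1
    training_seed: int = 2
    sampling_seed: int = 3
    scatter_fraction: float = 0.30
    randoms_fraction: float = 0.30
    total_counts: float = 1.0e6
    mlem_iterations: int = 20
    depth: int = 3
    in_channels: int = 2
    base_width: int = 16
    learning_rate: float = 0.001
    momentum: float = 0.95
    pretrain_iterations: int = 1000
    patch_size: int = 64
    patch_overlap: int = 5
    top_k_patches: int = 30
    baseline_method: str = "rf"
    extras: dict = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "grid_shape" in raw:
        raw["grid_shape"] = tuple(raw["grid_shape"])
    return RunConfig(**raw)
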