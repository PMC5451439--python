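"""Volumetric and tabular I/O.

Masks and density fields travel as NIfTI-1 volumes with voxel spacing in
the header; imaging series are described by small YAML configs pointing at
the per-day mask files; fit results are JSON. Structured writers attach a
provenance block (tool version, seed, config hash) so any artifact can be
traced back to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .geometry import BrainGeometry, Grid3D, ImagingSeries

logger = logging.getLogger(__name__)

__all__ = [
    "read_mask_volume",
    "write_mask_volume",
    "read_field_volume",
    "write_field_volume",
    "load_series",
    "write_series_config",
    "provenance_block",
    "write_json",
]


def _grid_from_header(img: nib.Nifti1Image, path: Path) -> Grid3D:
    data_shape = img.shape
    if len(data_shape) != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data_shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing {zooms}")
    return Grid3D(shape=tuple(int(n) for n in data_shape), spacing=zooms)


def read_mask_volume(path: str | Path) -> tuple[np.ndarray, Grid3D]:
    """Read a NIfTI volume as a boolean mask (nonzero -> True).

    Axis order is taken as stored, (x, y, z); no interpolation is ever
    applied to masks.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    grid = _grid_from_header(img, path)
    data = np.asanyarray(img.dataobj)
    return data != 0, grid


def write_mask_volume(mask: np.ndarray, grid: Grid3D, path: str | Path) -> None:
    """Write a boolean mask as a NIfTI-1 volume with header spacing."""
    mask = np.asarray(mask)
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} != grid shape {grid.shape}")
    _write_nifti(mask.astype(np.uint8), grid, path)


def read_field_volume(path: str | Path) -> tuple[np.ndarray, Grid3D]:
    """Read a real-valued NIfTI volume (e.g. a density field)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    grid = _grid_from_header(img, path)
    return np.asanyarray(img.dataobj).astype(float), grid


def write_field_volume(values: np.ndarray, grid: Grid3D, path: str | Path) -> None:
    values = np.asarray(values, dtype=np.float64)
    if values.shape != grid.shape:
        raise ValueError(f"field shape {values.shape} != grid shape {grid.shape}")
    _write_nifti(values, grid, path)


def _write_nifti(data: np.ndarray, grid: Grid3D, path: str | Path) -> None:
    affine = np.diag(list(grid.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(grid.spacing)
    img.header["descrip"] = f"gliomafit {__version__}".encode()[:80]
    nib.save(img, str(path))


def load_series(config_path: str | Path) -> ImagingSeries:
    """Build an :class:`ImagingSeries` from a YAML config.

    The config names the brain/ventricle geometry volumes and one mask
    volume per imaging day::

        geometry:
          brain: brain.nii.gz
          ventricles: ventricles.nii.gz
        days:
          11: day11.nii.gz
          15: day15.nii.gz

    Mask voxels falling outside the computational domain (skull or
    ventricles) are dropped with a logged warning count. Days are sorted,
    so file order in the config is irrelevant.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = config_path.parent

    def _resolve(p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    brain, grid = read_mask_volume(_resolve(cfg["geometry"]["brain"]))
    vent_path = cfg["geometry"].get("ventricles")
    if vent_path is not None:
        vent, vgrid = read_mask_volume(_resolve(vent_path))
        if vgrid != grid:
            raise ValueError("ventricle grid does not match brain grid")
    else:
        vent = np.zeros_like(brain)
    geometry = BrainGeometry(grid=grid, brain_mask=brain, ventricle_mask=vent)

    entries = sorted((int(day), path) for day, path in cfg["days"].items())
    days = [d for d, _ in entries]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError(f"days must be strictly increasing, got {days}")
    masks = []
    for day, mask_path in entries:
        mask, mgrid = read_mask_volume(_resolve(mask_path))
        if mgrid != grid:
            raise ValueError(f"day {day}: mask grid does not match geometry grid")
        clipped = mask & geometry.domain_mask
        n_dropped = int(mask.sum() - clipped.sum())
        if n_dropped:
            logger.warning(
                "day %d: dropped %d mask voxel(s) outside the domain",
                day,
                n_dropped,
            )
        masks.append(clipped)
    return ImagingSeries(geometry=geometry, days=tuple(days), masks=tuple(masks))


def write_series_config(
    out_dir: str | Path,
    geometry: BrainGeometry,
    days: tuple[int, ...],
    masks: tuple[np.ndarray, ...],
    *,
    seed: int | None = None,
) -> Path:
    """Write geometry + per-day masks as NIfTI plus a series YAML.

    Returns the path of the YAML config, consumable by :func:`load_series`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_mask_volume(geometry.brain_mask, geometry.grid, out_dir / "brain.nii.gz")
    write_mask_volume(
        geometry.ventricle_mask, geometry.grid, out_dir / "ventricles.nii.gz"
    )
    day_files = {}
    for day, mask in zip(days, masks):
        name = f"day{day:02d}.nii.gz"
        write_mask_volume(mask, geometry.grid, out_dir / name)
        day_files[int(day)] = name
    cfg: dict[str, Any] = {
        "geometry": {"brain": "brain.nii.gz", "ventricles": "ventricles.nii.gz"},
        "days": day_files,
        "provenance": provenance_block({"days": list(map(int, days))}, seed=seed),
    }
    path = out_dir / "series.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path


def config_hash(obj: Any) -> str:
    """Stable short hash of a JSON-serialisable config object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def provenance_block(config: Any, *, seed: int | None = None) -> dict[str, Any]:
    return {
        "tool": "gliomafit",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
    }


def write_json(obj: dict[str, Any], path: str | Path, *, seed: int | None = None) -> None:
    """Write a JSON artifact with an attached provenance block."""
    obj = dict(obj)
    obj.setdefault("provenance", provenance_block(obj, seed=seed))
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o: Any) -> Any:
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serialisable: {type(o)}")
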