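"""Core geometric data types: voxel grids, masked brain domains, density
fields, imaging series, and the (D, rho) parameter pair.

Conventions
-----------
Voxel indexing is 0-based with axis order (x, y, z); voxel (i, j, k) is
centred at world coordinate ((i + 0.5) hx, (j + 0.5) hy, (k + 0.5) hz) mm.
The computational domain Omega is the brain with the ventricles removed;
tumour cell density u is a dimensionless fraction of the carrying capacity
(normalised to 1) and is identically zero outside Omega.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .units import day_to_hours

__all__ = [
    "Grid3D",
    "BrainGeometry",
    "DensityField",
    "ImagingSeries",
    "Params",
    "DEFAULT_SPACING_MM",
    "DEFAULT_IMAGING_DAYS",
]

#: In-plane 0.1 mm, through-plane 0.5 mm: the T2-weighted acquisition grid.
DEFAULT_SPACING_MM = (0.1, 0.1, 0.5)

#: Imaging sessions in days post-implantation.
DEFAULT_IMAGING_DAYS = (11, 15, 18, 22, 25)


@dataclass(frozen=True)
class Grid3D:
    """A uniform voxel grid: integer shape and per-axis spacing in mm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = DEFAULT_SPACING_MM

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(h) for h in self.spacing)
        if len(shape) != 3 or len(spacing) != 3:
            raise ValueError("Grid3D is three-dimensional")
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(h <= 0 for h in spacing):
            raise ValueError(f"all spacings must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (mm) of voxel centres along each axis."""
        return tuple(
            (np.arange(n) + 0.5) * h for n, h in zip(self.shape, self.spacing)
        )

    def center_mm(self) -> tuple[float, float, float]:
        """World coordinate of the grid's geometric centre."""
        return tuple(n * h / 2.0 for n, h in zip(self.shape, self.spacing))


@dataclass(frozen=True)
class BrainGeometry:
    """Brain, ventricle, and computational-domain masks on one grid.

    ``domain_mask`` (Omega) is derived: brain AND NOT ventricles. The
    ventricles are excluded cavities; no diffusion or growth occurs there,
    consistent with the no-flux boundary condition.
    """

    grid: Grid3D
    brain_mask: np.ndarray
    ventricle_mask: np.ndarray
    domain_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        brain = np.asarray(self.brain_mask, dtype=bool)
        vent = np.asarray(self.ventricle_mask, dtype=bool)
        if brain.shape != self.grid.shape or vent.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid shape")
        if np.any(vent & ~brain):
            raise ValueError("ventricle_mask must be contained in brain_mask")
        domain = brain & ~vent
        if not domain.any():
            raise ValueError("computational domain is empty")
        object.__setattr__(self, "brain_mask", brain)
        object.__setattr__(self, "ventricle_mask", vent)
        object.__setattr__(self, "domain_mask", domain)


@dataclass
class DensityField:
    """Normalised tumour cell density u(t, x) on a masked brain domain."""

    geometry: BrainGeometry
    time: float  # hours since implantation
    values: np.ndarray

    _BOUND_SLACK = 1e-6

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.geometry.grid.shape:
            raise ValueError("values shape does not match grid shape")
        if vals.min() < -self._BOUND_SLACK or vals.max() > 1.0 + self._BOUND_SLACK:
            raise ValueError(
                "density out of [0, 1] beyond tolerance: "
                f"min={vals.min():g}, max={vals.max():g}"
            )
        if np.any(vals[~self.geometry.domain_mask] != 0.0):
            raise ValueError("density must vanish outside the domain")
        self.values = vals

    @property
    def grid(self) -> Grid3D:
        return self.geometry.grid


@dataclass
class ImagingSeries:
    """Ordered imaging days with per-day visible-tumour masks B(t_k)."""

    geometry: BrainGeometry
    days: tuple[int, ...]
    masks: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.days)
        if len(days) != len(self.masks):
            raise ValueError("days and masks must have equal length")
        if len(days) < 2:
            raise ValueError("an imaging series needs at least 2 days")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"days must be strictly increasing, got {days}")
        masks = []
        for m in self.masks:
            m = np.asarray(m, dtype=bool)
            if m.shape != self.geometry.grid.shape:
                raise ValueError("mask shape does not match geometry grid")
            if np.any(m & ~self.geometry.domain_mask):
                raise ValueError(
                    "mask extends outside the computational domain; "
                    "clip it first (see io.load_series)"
                )
            masks.append(m)
        self.days = days
        self.masks = tuple(masks)

    @property
    def times_hours(self) -> tuple[float, ...]:
        return tuple(day_to_hours(d) for d in self.days)

    def truncated(self, start_index: int) -> "ImagingSeries":
        """Sub-series starting at ``days[start_index]`` (late-start fits)."""
        return ImagingSeries(
            self.geometry, self.days[start_index:], self.masks[start_index:]
        )


@dataclass(frozen=True)
class Params:
    """The Fisher-KPP parameter pair: D in um^2/h, rho in 1/h."""

    D: float
    rho: float

    def __post_init__(self) -> None:
        if not (self.D > 0 and self.rho > 0):
            raise ValueError(f"D and rho must be positive, got {self}")

    def as_tuple(self) -> tuple[float, float]:
        return (float(self.D), float(self.rho))


def ensure_days(days: Sequence[int] | None) -> tuple[int, ...]:
    """Default imaging schedule if ``days`` is None."""
    return DEFAULT_IMAGING_DAYS if days is None else tuple(int(d) for d in days)
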