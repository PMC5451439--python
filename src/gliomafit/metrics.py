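"""Scalar error measures and derived quantities.

Jaccard distance between visible-tumour masks, the per-series error
functional (mean or sum over imaging days), traveling-wave speed
2 sqrt(D rho), boundary-distance error z_d for the 2D moving-boundary fits,
the weighted total error E2 = z_d + 10 sum d_J, unit conversions, visible
volumes, relative invasiveness log10(D/rho), and percent changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import Grid3D, ImagingSeries, Params
from .units import umh_to_cmyr as _umh_to_cmyr

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorReport",
    "jaccard_distance",
    "series_error",
    "wave_speed",
    "umh_to_cmyr",
    "visible_volume",
    "relative_invasiveness",
    "percent_decrease",
    "boundary_distance_error",
    "point_to_polygon_distances",
    "total_error_E2",
]


@dataclass(frozen=True)
class ErrorReport:
    """Per-timepoint Jaccard distances plus their aggregate.

    ``mode='mean'`` is the time-averaged error functional used for the
    whole-series (Hypothesis 1) fits; ``mode='sum'`` is the convention for
    reporting sequential per-interval (Hypothesis 2/3) fits.
    """

    per_day: tuple[float, ...]
    mode: str  # 'mean' | 'sum'

    def __post_init__(self) -> None:
        if self.mode not in ("mean", "sum"):
            raise ValueError(f"unknown aggregation mode {self.mode!r}")
        if any(not (0.0 <= d <= 1.0) for d in self.per_day):
            raise ValueError("each Jaccard distance must lie in [0, 1]")
        object.__setattr__(self, "per_day", tuple(float(d) for d in self.per_day))

    @property
    def n(self) -> int:
        return len(self.per_day)

    @property
    def aggregate(self) -> float:
        if self.mode == "mean":
            return float(np.mean(self.per_day))
        return float(np.sum(self.per_day))


def jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - |A n B| / |A u B| for boolean arrays on the same grid.

    Two empty sets are a perfect match (distance 0, the 0/0 case of the
    formula); exactly one empty set is a total mismatch (distance 1).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        logger.debug("jaccard_distance of two empty sets -> 0 by convention")
        return 0.0
    inter = int(np.count_nonzero(a & b))
    return 1.0 - inter / union


def series_error(
    sim_masks: Sequence[np.ndarray],
    obs: ImagingSeries,
    mode: str = "mean",
) -> ErrorReport:
    """Per-day Jaccard distances of simulated vs observed masks.

    ``sim_masks`` holds one predicted mask per follow-up day (the
    initialisation day is excluded from the comparison, so n = number of
    follow-up days).
    """
    follow_up = obs.masks[1:]
    if len(sim_masks) != len(follow_up):
        raise ValueError(
            f"{len(sim_masks)} simulated masks for {len(follow_up)} follow-up days"
        )
    per_day = tuple(jaccard_distance(s, o) for s, o in zip(sim_masks, follow_up))
    return ErrorReport(per_day=per_day, mode=mode)


def wave_speed(params: Params) -> float:
    """Asymptotic Fisher-KPP front speed 2 sqrt(D rho), in um/h."""
    return 2.0 * float(np.sqrt(params.D * params.rho))


def umh_to_cmyr(speed_um_per_h: float) -> float:
    """Convert a front speed from um/h to cm/yr (factor 0.876)."""
    return _umh_to_cmyr(speed_um_per_h)


def visible_volume(mask: np.ndarray, grid: Grid3D) -> float:
    """Visible-tumour volume in mm^3: voxel count times voxel volume."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} != grid shape {grid.shape}")
    return float(np.count_nonzero(mask)) * grid.voxel_volume_mm3


def relative_invasiveness(params: Params) -> float:
    """log10(D / rho): small values are nodular, large values diffuse."""
    return float(np.log10(params.D / params.rho))


def percent_decrease(reference: float, value: float) -> float:
    """100 (reference - value) / reference."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (reference - value) / reference


def point_to_polygon_distances(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance from each point to a closed polygon.

    ``polygon`` is an (M, 2) vertex array; closure is implicit (the last
    vertex connects back to the first). Fully vectorised point-to-segment
    distance over all vertex/segment pairs.
    """
    points = np.asarray(points, dtype=float)
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise ValueError("polygon needs at least 3 (x, y) vertices")
    a = poly
    b = np.roll(poly, -1, axis=0)
    ab = b - a  # (M, 2)
    ab2 = np.einsum("ij,ij->i", ab, ab)
    ab2 = np.where(ab2 == 0.0, 1.0, ab2)  # degenerate segments -> point distance
    ap = points[:, None, :] - a[None, :, :]  # (N, M, 2)
    t = np.clip(np.einsum("nmj,mj->nm", ap, ab) / ab2[None, :], 0.0, 1.0)
    closest = a[None, :, :] + t[..., None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - closest, axis=2)
    return d.min(axis=1)


def boundary_distance_error(
    sim_boundaries: Sequence[np.ndarray],
    data_boundaries: Sequence[np.ndarray],
) -> float:
    """Boundary-position error z_d (mm) between per-day closed polylines.

    For each compared day, the RMS of the minimum distances from every
    simulated-boundary vertex to the data polygon; z_d is the sum of those
    per-day RMS values. The measure is deliberately one-directional
    (simulated vertices against the data polygon).
    """
    if len(sim_boundaries) != len(data_boundaries):
        raise ValueError("day lists do not match")
    if len(sim_boundaries) == 0:
        raise ValueError("no boundaries to compare")
    z = 0.0
    for sim, data in zip(sim_boundaries, data_boundaries):
        sim = np.asarray(sim, dtype=float)
        if sim.ndim != 2 or sim.shape[0] < 3:
            raise ValueError("each simulated boundary needs >= 3 vertices")
        d = point_to_polygon_distances(sim, data)
        z += float(np.sqrt(np.mean(d * d)))
    return z


def total_error_E2(z_d: float, jaccards: Sequence[float]) -> float:
    """Weighted 2D fit error: z_d + 10 sum of per-day Jaccard distances.

    The factor of 10 puts the overlap term on the same order as the
    boundary-position term.
    """
    z_d = float(z_d)
    j = np.asarray(jaccards, dtype=float)
    if not np.isfinite(z_d) or not np.isfinite(j).all():
        raise ValueError("inputs must be finite")
    return z_d + 10.0 * float(j.sum())
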