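"""Practical-identifiability analysis of the (D, rho) pair.

The Jaccard error surface E(D, rho) of a whole-series fit typically shows
a long flat valley along curves of constant front speed c = 2 sqrt(D rho):
many parameter pairs are consistent with the imaging data, so D and rho
are practically nonidentifiable even though c is well constrained. This
module maps the surface over a parameter grid, overlays the constant-speed
arc rho(D) = c^2 / (4 D), and quantifies the valley flatness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import FitConfig, objective_h1
from .geometry import ImagingSeries, Params
from .io import config_hash

__all__ = [
    "ErrorSurface",
    "compute_error_surface",
    "wavespeed_arc",
    "valley_flatness",
    "FlatnessRecord",
    "default_grids",
]


def default_grids(n: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced default grids bracketing published murine estimates:
    D in [50, 2000] um^2/h, rho in [0.005, 0.06] 1/h."""
    return (
        np.geomspace(50.0, 2000.0, n),
        np.geomspace(0.005, 0.06, n),
    )


def valley_analysis_grids(
    params: Params,
    n: int = 15,
    *,
    d_factor: float = 1.25,
    rho_factor: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Selected parameter intervals for exhibiting the valley structure.

    Like the published error-surface figures, the D interval is chosen
    inside the valley's flat section (narrow, centred on the reference
    estimate) while the rho interval is wide, so the surface shows how
    the error stays low along the constant-c arc but climbs quickly when
    the front speed changes. Symmetric log grids around ``params``.
    """
    return (
        np.geomspace(params.D / d_factor, params.D * d_factor, n),
        np.geomspace(params.rho / rho_factor, params.rho * rho_factor, n),
    )


@dataclass(frozen=True)
class ErrorSurface:
    """E(D, rho) sampled on a rectangular parameter grid.

    ``E[i, j]`` is the mean-mode Jaccard error at (D_axis[i], rho_axis[j]);
    NaN marks nodes where the forward solve failed.
    """

    D_axis: np.ndarray  # um^2/h, sorted ascending
    rho_axis: np.ndarray  # 1/h, sorted ascending
    E: np.ndarray
    meta: str = ""

    def __post_init__(self) -> None:
        D = np.asarray(self.D_axis, dtype=float)
        r = np.asarray(self.rho_axis, dtype=float)
        E = np.asarray(self.E, dtype=float)
        if D.ndim != 1 or r.ndim != 1 or np.any(D <= 0) or np.any(r <= 0):
            raise ValueError("axes must be 1D and positive")
        if np.any(np.diff(D) <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("axes must be strictly increasing")
        if E.shape != (D.size, r.size):
            raise ValueError("E shape must be (len(D_axis), len(rho_axis))")
        finite = E[np.isfinite(E)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("mean-mode errors must lie in [0, 1]")
        object.__setattr__(self, "D_axis", D)
        object.__setattr__(self, "rho_axis", r)
        object.__setattr__(self, "E", E)


_SURFACE_CACHE: dict[tuple, ErrorSurface] = {}


def compute_error_surface(
    series: ImagingSeries,
    D_grid: np.ndarray,
    rho_grid: np.ndarray,
    cfg: FitConfig | None = None,
) -> ErrorSurface:
    """Evaluate the whole-series mean-mode Jaccard error at every node.

    Node evaluations are independent of one another and of evaluation
    order; solver failures are recorded as NaN rather than aborting the
    sweep. Results are cached on (series identity, grids, config).
    """
    cfg = cfg or FitConfig()
    D_grid = np.asarray(D_grid, dtype=float)
    rho_grid = np.asarray(rho_grid, dtype=float)
    key = (
        id(series),
        D_grid.tobytes(),
        rho_grid.tobytes(),
        config_hash(repr(cfg)),
    )
    cached = _SURFACE_CACHE.get(key)
    if cached is not None:
        return cached
    E = np.full((D_grid.size, rho_grid.size), np.nan)
    for i, D in enumerate(D_grid):
        for j, rho in enumerate(rho_grid):
            try:
                E[i, j] = objective_h1(Params(D, rho), series, cfg)
            except RuntimeError:
                pass  # left as NaN
    surface = ErrorSurface(
        D_axis=D_grid, rho_axis=rho_grid, E=E, meta=config_hash(repr(cfg))
    )
    if len(_SURFACE_CACHE) > 16:
        _SURFACE_CACHE.clear()
    _SURFACE_CACHE[key] = surface
    return surface


def wavespeed_arc(
    c: float, D_interval: tuple[float, float], n: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """The constant-front-speed curve rho(D) = c^2 / (4 D).

    Every sampled (D, rho) pair satisfies 2 sqrt(D rho) = c exactly (to
    roundoff). ``c`` is in um/h, D in um^2/h.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    lo, hi = D_interval
    if not (0 < lo < hi):
        raise ValueError("D interval must be positive and increasing")
    D = np.geomspace(lo, hi, n)
    rho = c * c / (4.0 * D)
    return D, rho


@dataclass(frozen=True)
class FlatnessRecord:
    """Valley-flatness statistic of an error surface along a speed arc."""

    arc_range: float  # spread of E along the constant-c arc
    overall_range: float  # spread of E over the whole grid
    ratio: float
    nonidentifiable: bool
    n_arc_samples: int


def _interp_log_bilinear(surface: ErrorSurface, D: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of E in (log D, log rho) coordinates."""
    lx = np.log(surface.D_axis)
    ly = np.log(surface.rho_axis)
    x = np.log(D)
    y = np.log(rho)
    i = np.clip(np.searchsorted(lx, x) - 1, 0, lx.size - 2)
    j = np.clip(np.searchsorted(ly, y) - 1, 0, ly.size - 2)
    tx = (x - lx[i]) / (lx[i + 1] - lx[i])
    ty = (y - ly[j]) / (ly[j + 1] - ly[j])
    E = surface.E
    return (
        E[i, j] * (1 - tx) * (1 - ty)
        + E[i + 1, j] * tx * (1 - ty)
        + E[i, j + 1] * (1 - tx) * ty
        + E[i + 1, j + 1] * tx * ty
    )


def valley_flatness(
    surface: ErrorSurface,
    c: float,
    *,
    flatness_threshold: float = 0.25,
    n_samples: int = 200,
) -> FlatnessRecord:
    """Spread of E along the constant-c arc vs over the whole grid.

    The parameters are flagged practically nonidentifiable when the error
    varies along the arc by less than ``flatness_threshold`` times its
    overall range — i.e. when an entire one-parameter family of (D, rho)
    pairs fits the data about equally well. A degenerate all-constant
    surface is flagged with ratio 0.
    """
    D_arc, rho_arc = wavespeed_arc(
        c, (float(surface.D_axis[0]), float(surface.D_axis[-1])), n_samples
    )
    inside = (rho_arc >= surface.rho_axis[0]) & (rho_arc <= surface.rho_axis[-1])
    if not inside.any():
        raise ValueError("the constant-c arc does not intersect the grid")
    e_arc = _interp_log_bilinear(surface, D_arc[inside], rho_arc[inside])
    e_arc = e_arc[np.isfinite(e_arc)]
    finite = surface.E[np.isfinite(surface.E)]
    arc_range = float(e_arc.max() - e_arc.min()) if e_arc.size else 0.0
    overall_range = float(finite.max() - finite.min()) if finite.size else 0.0
    if overall_range == 0.0:
        return FlatnessRecord(0.0, 0.0, 0.0, True, int(e_arc.size))
    ratio = arc_range / overall_range
    return FlatnessRecord(
        arc_range,
        overall_range,
        ratio,
        ratio < flatness_threshold,
        int(e_arc.size),
    )
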