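"""Forward integration of the Fisher-KPP equation on a masked 3D domain.

The model is du/dt = div(D grad u) + rho u (1 - u) with no-flux boundaries
(the tumour penetrates neither the skull nor the ventricles). Space is
discretised with flux-form centred finite differences on the voxel grid;
faces adjoining non-domain voxels carry zero flux, which makes the discrete
diffusion operator exactly mass-conserving. Time integration uses an
adaptive explicit embedded Runge-Kutta 4(5) (Dormand-Prince) scheme.

D is spatially uniform in 3D; it is accepted in um^2/h and converted to
mm^2/h internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .geometry import BrainGeometry, DensityField, Grid3D, Params
from .units import um2h_to_mm2h

__all__ = [
    "SolverConfig",
    "reaction_diffusion_rhs",
    "integrate",
    "integrate_series",
    "threshold_to_mask",
    "measure_front_speed",
    "build_domain_laplacian",
]

#: Hypothesised T2 detection threshold: densities at and above this fraction
#: of carrying capacity are "visible tumour". Inclusive comparison (>=).
DEFAULT_THRESHOLD = 0.16


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings for the forward solver."""

    rtol: float = 1e-6
    atol: float = 1e-9
    max_step: float = np.inf  # hours
    threshold: float = DEFAULT_THRESHOLD
    # Bound-violation tolerance. RK45 at rtol=1e-6 legitimately overshoots
    # the u=1 equilibrium by a few parts in 1e6, so the check tolerance
    # sits one order above the relative tolerance; anything larger signals
    # genuine instability.
    clamp_check: float = 1e-5

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.clamp_check <= 0:
            raise ValueError("clamp_check must be positive")


_LAPLACIAN_CACHE: dict[int, tuple[sp.csr_matrix, np.ndarray]] = {}


def build_domain_laplacian(geometry: BrainGeometry) -> tuple[sp.csr_matrix, np.ndarray]:
    """Flux-form discrete Laplacian restricted to domain voxels.

    Returns ``(L, index)`` where ``L`` acts on the vector of domain-voxel
    values (unit diffusivity, 1/mm^2) and ``index`` maps voxel -> position
    in that vector (-1 outside the domain). Zero-flux faces at the domain
    boundary are implemented by simply omitting the corresponding
    conductances, so every row of ``L`` sums to zero exactly.
    """
    key = id(geometry)
    cached = _LAPLACIAN_CACHE.get(key)
    if cached is not None:
        return cached
    domain = geometry.domain_mask
    n = int(domain.sum())
    index = np.full(domain.shape, -1, dtype=np.int64)
    index[domain] = np.arange(n)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for axis, h in enumerate(geometry.grid.spacing):
        w = 1.0 / (h * h)
        # faces between voxel pairs (i, i+1) along this axis
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        both = domain[tuple(sl_lo)] & domain[tuple(sl_hi)]
        a = index[tuple(sl_lo)][both]
        b = index[tuple(sl_hi)][both]
        rows.extend([a, b])
        cols.extend([b, a])
        vals.extend([np.full(a.size, w), np.full(a.size, w)])
        np.add.at(diag, a, -w)
        np.add.at(diag, b, -w)
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    L = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    if len(_LAPLACIAN_CACHE) > 32:  # keep the cache bounded
        _LAPLACIAN_CACHE.clear()
    _LAPLACIAN_CACHE[key] = (L, index)
    return L, index


def reaction_diffusion_rhs(field: DensityField, params: Params) -> np.ndarray:
    """Rate of change (1/h) of the density field at its current state.

    Returns div(D grad u) + rho u (1 - u) per voxel, zero outside the
    domain.
    """
    L, _ = build_domain_laplacian(field.geometry)
    domain = field.geometry.domain_mask
    u = field.values[domain]
    d_mm = um2h_to_mm2h(params.D)
    rate_domain = d_mm * (L @ u) + params.rho * u * (1.0 - u)
    rate = np.zeros_like(field.values)
    rate[domain] = rate_domain
    return rate


def _check_bounds(y: np.ndarray, clamp_check: float) -> None:
    lo, hi = float(y.min()), float(y.max())
    if lo < -clamp_check or hi > 1.0 + clamp_check:
        raise RuntimeError(
            f"density left [0, 1] beyond clamp_check ({clamp_check:g}): "
            f"min={lo:g}, max={hi:g}; the integration is unstable"
        )


def integrate_series(
    field: DensityField,
    params: Params,
    times: list[float] | tuple[float, ...],
    config: SolverConfig | None = None,
) -> list[DensityField]:
    """Advance a field through a sequence of output times (hours).

    A single adaptive integration produces all outputs via the solver's
    dense interpolant, so the result is independent of how many output
    times are requested.
    """
    config = config or SolverConfig()
    times = [float(t) for t in times]
    if any(t <= field.time for t in times):
        raise ValueError("all output times must exceed the field's time")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("output times must be strictly increasing")
    geometry = field.geometry
    L, _ = build_domain_laplacian(geometry)
    domain = geometry.domain_mask
    y0 = field.values[domain]
    d_mm = um2h_to_mm2h(params.D)
    rho = params.rho

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        return d_mm * (L @ y) + rho * y * (1.0 - y)

    sol = solve_ivp(
        rhs,
        (field.time, times[-1]),
        y0,
        method="RK45",
        t_eval=times,
        rtol=config.rtol,
        atol=config.atol,
        max_step=config.max_step,
    )
    if not sol.success:
        raise RuntimeError(f"forward integration failed: {sol.message}")
    out = []
    for k, t in enumerate(times):
        y = sol.y[:, k]
        _check_bounds(y, config.clamp_check)
        values = np.zeros(geometry.grid.shape)
        values[domain] = np.clip(y, 0.0, 1.0)  # shave roundoff inside tolerance
        out.append(DensityField(geometry=geometry, time=t, values=values))
    return out


def integrate(
    field: DensityField,
    params: Params,
    t_end: float,
    config: SolverConfig | None = None,
) -> DensityField:
    """Advance a density field to ``t_end`` (hours)."""
    return integrate_series(field, params, [t_end], config)[-1]


def threshold_to_mask(field: DensityField, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Visible-tumour mask: domain voxels with u >= threshold (inclusive)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    return (field.values >= threshold) & field.geometry.domain_mask


def _front_position(u: np.ndarray, x: np.ndarray, threshold: float) -> float:
    """Rightmost threshold crossing, linearly interpolated; NaN if none."""
    above = u >= threshold
    if not above.any():
        return np.nan
    i = int(np.max(np.nonzero(above)[0]))
    if i == u.size - 1:
        return float(x[-1])
    # interpolate between the last voxel above and the first below
    u0, u1 = u[i], u[i + 1]
    frac = (u0 - threshold) / (u0 - u1) if u0 != u1 else 0.0
    return float(x[i] + frac * (x[i + 1] - x[i]))


def measure_front_speed(
    params: Params,
    channel_length_mm: float = 16.0,
    config: SolverConfig | None = None,
    *,
    dx_mm: float = 0.025,
    seed_length_mm: float = 1.0,
    u0: float = 0.5,
    allow_zero_rho: bool = False,
    rho_override: float | None = None,
) -> float:
    """Empirical traveling-wave speed (um/h) on a quasi-1D channel.

    A long n x 1 x 1 channel with no-flux walls is seeded at one end and
    integrated until the front has crossed most of the channel; the
    threshold-contour position (linear interpolation between voxels) is
    then regressed on time. Fisher-KPP fronts started from compact data
    approach their asymptotic speed with a slowly decaying logarithmic
    transient, so the regression model is x(t) = c t + a ln t + b over the
    post-transient window and c is returned.

    If the visible contour has vanished by the end of the run (possible
    only without growth, when diffusion spreads the seed below the
    detection threshold), the front has collapsed rather than travelled
    and the speed is reported as 0. ``rho_override`` (with
    ``allow_zero_rho=True``) permits probing exactly that rho = 0 case,
    which the :class:`Params` invariant otherwise excludes.
    """
    config = config or SolverConfig()
    rho = params.rho if rho_override is None else float(rho_override)
    if rho < 0 or (rho == 0 and not allow_zero_rho):
        raise ValueError("rho must be positive (pass allow_zero_rho for rho=0)")
    d_mm = um2h_to_mm2h(params.D)
    c_analytic_mm = 2.0 * np.sqrt(d_mm * rho)  # mm/h

    nx = int(round(channel_length_mm / dx_mm))
    grid = Grid3D((nx, 1, 1), (dx_mm, 0.1, 0.1))
    geom = BrainGeometry(
        grid=grid,
        brain_mask=np.ones(grid.shape, dtype=bool),
        ventricle_mask=np.zeros(grid.shape, dtype=bool),
    )
    x = (np.arange(nx) + 0.5) * dx_mm
    values = np.zeros(grid.shape)
    values[x < seed_length_mm, 0, 0] = u0
    field = DensityField(geometry=geom, time=0.0, values=values)

    if c_analytic_mm > 0:
        t_end = (0.85 * channel_length_mm - seed_length_mm) / c_analytic_mm
    else:
        # no growth: run long enough for diffusion to either spread the
        # seed below the detection threshold (front collapse) or reveal
        # any residual drift of the contour
        t_end = 15000.0
    times = np.linspace(t_end / 200.0, t_end, 200)
    if rho > 0:
        fields = integrate_series(field, Params(params.D, rho), list(times), config)
    else:
        fields = _integrate_pure_diffusion(field, d_mm, list(times), config)

    positions = np.array(
        [_front_position(f.values[:, 0, 0], x, config.threshold) for f in fields]
    )
    if np.isnan(positions[-1]):
        return 0.0  # front collapsed: no sustained wave
    valid = ~np.isnan(positions)
    window = valid & (times >= 0.4 * t_end)
    if np.nanmax(positions) > channel_length_mm - 5 * dx_mm:
        raise RuntimeError("front reached the channel end; channel too short")
    tw, xw = times[window], positions[window]
    if (xw.max() - xw.min()) < 20 * dx_mm and c_analytic_mm > 0:
        raise RuntimeError(
            "front travelled fewer than 20 voxels in the measurement window"
        )
    design = np.column_stack([tw, np.log(tw), np.ones_like(tw)])
    coef, *_ = np.linalg.lstsq(design, xw, rcond=None)
    return float(coef[0] * 1e3)  # mm/h -> um/h


def _integrate_pure_diffusion(
    field: DensityField, d_mm: float, times: list[float], config: SolverConfig
) -> list[DensityField]:
    """Diffusion-only integration (rho = 0), same scheme as integrate_series."""
    geometry = field.geometry
    L, _ = build_domain_laplacian(geometry)
    domain = geometry.domain_mask
    y0 = field.values[domain]
    sol = solve_ivp(
        lambda _t, y: d_mm * (L @ y),
        (field.time, times[-1]),
        y0,
        method="RK45",
        t_eval=times,
        rtol=config.rtol,
        atol=config.atol,
    )
    if not sol.success:
        raise RuntimeError(f"forward integration failed: {sol.message}")
    out = []
    for k, t in enumerate(times):
        values = np.zeros(geometry.grid.shape)
        values[domain] = np.clip(sol.y[:, k], 0.0, 1.0)
        out.append(DensityField(geometry=geometry, time=t, values=values))
    return out
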