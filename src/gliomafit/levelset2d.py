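"""2D moving-boundary (Stefan) solver for the tumour front.

Inside the tumour region Omega_1 the density obeys the Fisher-KPP
equation with a Dirichlet condition u = u_bar (the detection threshold,
0.16) on the interface; the interface itself moves with the Stefan
condition

    v . n = -(D / u_bar) grad(u) . n,

the Darcy-law closure with mobility mu = D and pressure p = ln(u) (an
arbitrarily large stress can stretch or compress the tissue, and taking
the mobility equal to D avoids an extra parameter). The host region obeys
a no-flux condition on the brain and ventricle boundaries, and the host
geometry can be swapped out on later imaging days to emulate mass effect.

The front is tracked as the zero contour of a signed distance function phi
(negative inside the tumour), advected with first-order Godunov upwinding
under a CFL restriction and reinitialised every few steps: exact distance
to the marching-squares contour in a narrow band, Euclidean distance
transform beyond it. The interface speed is extended off the front by
constant extrapolation along normals (nearest-front-pixel lookup). The
diffusivity may be a scalar or a per-axis (Dx, Dy) pair of pixel fields
for anisotropic runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure

from .geometry import Params
from .io import config_hash
from .metrics import boundary_distance_error, jaccard_distance, total_error_E2
from .units import day_to_hours, um2h_to_mm2h

logger = logging.getLogger(__name__)

__all__ = [
    "PlanarDomain",
    "LevelSetState",
    "BoundaryCurve",
    "PlanarSeries",
    "LevelSetFitResult",
    "init_state",
    "interface_velocity",
    "evolve",
    "extract_boundary",
    "rasterize_tumor",
    "simulate_planar_truth",
    "fit_levelset",
]

DEFAULT_U_BAR = 0.16


@dataclass(frozen=True)
class PlanarDomain:
    """2D host geometry: brain and ventricle masks with optional per-day
    replacement masks (applied at the start of the update day)."""

    shape: tuple[int, int]
    spacing: tuple[float, float]  # mm
    brain_mask: np.ndarray
    ventricle_mask: np.ndarray
    updates: tuple[tuple[int, np.ndarray, np.ndarray], ...] = ()  # (day, brain, vent)

    def __post_init__(self) -> None:
        brain = np.asarray(self.brain_mask, dtype=bool)
        vent = np.asarray(self.ventricle_mask, dtype=bool)
        if brain.shape != tuple(self.shape) or vent.shape != tuple(self.shape):
            raise ValueError("mask shape does not match domain shape")
        if np.any(vent & ~brain):
            raise ValueError("ventricles must lie inside the brain")
        if any(h <= 0 for h in self.spacing):
            raise ValueError("spacing must be positive")
        days = [d for d, *_ in self.updates]
        if days != sorted(days):
            raise ValueError("update days must be sorted")
        object.__setattr__(self, "brain_mask", brain)
        object.__setattr__(self, "ventricle_mask", vent)

    @property
    def domain_mask(self) -> np.ndarray:
        return self.brain_mask & ~self.ventricle_mask

    def at_day(self, day: float) -> "PlanarDomain":
        """Geometry in force at ``day`` (latest update with day' <= day)."""
        out = self
        for d, brain, vent in self.updates:
            if day >= d:
                out = PlanarDomain(self.shape, self.spacing, brain, vent)
        return out


@dataclass
class LevelSetState:
    """Signed distance phi (mm, negative in the tumour), interior density
    u, time in hours, and the interface density u_bar."""

    phi: np.ndarray
    u: np.ndarray
    time: float
    u_bar: float = DEFAULT_U_BAR
    spacing: tuple[float, float] = (0.1, 0.1)

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.phi < 0


@dataclass(frozen=True)
class BoundaryCurve:
    """Ordered closed polyline (mm); closure is implicit (first != last)."""

    vertices: np.ndarray  # (L, 2)
    day: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
            raise ValueError("a boundary curve needs at least 3 (x, y) vertices")
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise ValueError("degenerate boundary curve")
        object.__setattr__(self, "vertices", v)

    def perimeter(self) -> float:
        v = self.vertices
        return float(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1).sum())

    def area(self) -> float:
        """Enclosed (shoelace) area, mm^2."""
        v = self.vertices
        x, y = v[:, 0], v[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


# ---------------------------------------------------------------------------
# distance helpers


def _signed_edt(mask: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    """Signed distance approximation from a binary mask (negative inside)."""
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return np.where(mask, -inside + min(spacing) / 2.0, outside - min(spacing) / 2.0)


def _contours_mm(phi: np.ndarray, spacing: tuple[float, float]) -> list[np.ndarray]:
    """Marching-squares zero contours of phi in mm coordinates."""
    hx, hy = spacing
    out = []
    for c in measure.find_contours(phi, 0.0):
        v = np.empty_like(c)
        v[:, 0] = (c[:, 0] + 0.5) * hx
        v[:, 1] = (c[:, 1] + 0.5) * hy
        out.append(v)
    return out


def _dist_to_polylines(points: np.ndarray, polylines: list[np.ndarray]) -> np.ndarray:
    """Min distance from points to a set of closed polylines (vectorised)."""
    seg_a, seg_b = [], []
    for poly in polylines:
        a = poly
        b = np.roll(poly, -1, axis=0)
        seg_a.append(a)
        seg_b.append(b)
    a = np.concatenate(seg_a)
    b = np.concatenate(seg_b)
    ab = b - a
    ab2 = np.einsum("ij,ij->i", ab, ab)
    ab2 = np.where(ab2 == 0.0, 1.0, ab2)
    ap = points[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("nmj,mj->nm", ap, ab) / ab2[None, :], 0.0, 1.0)
    closest = a[None, :, :] + t[..., None] * ab[None, :, :]
    return np.linalg.norm(points[:, None, :] - closest, axis=2).min(axis=1)


def reinitialize(phi: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    """Restore the signed-distance property of phi.

    Pixels within a narrow band of the front get the exact Euclidean
    distance to the marching-squares zero contour (sub-pixel accurate, so
    repeated reinitialisation does not drift the front); the far field
    falls back to a distance transform of the sign pattern.
    """
    contours = _contours_mm(phi, spacing)
    far = _signed_edt(phi < 0, spacing)
    if not contours:
        return far
    hmax = max(spacing)
    band = np.abs(far) <= 4.0 * hmax
    idx = np.argwhere(band)
    pts = (idx + 0.5) * np.asarray(spacing)
    d = _dist_to_polylines(pts, contours)
    out = far.copy()
    out[band] = np.where(phi[band] < 0, -d, d)
    return out


# ---------------------------------------------------------------------------
# state construction and interface speed


def init_state(
    tumor_mask: np.ndarray,
    domain: PlanarDomain,
    u0: float = 0.5,
    u_bar: float = DEFAULT_U_BAR,
    *,
    day: int = 11,
) -> LevelSetState:
    """Initialise phi and u from the day-one visible-tumour mask.

    u is u0 on the tumour pixels and u_bar on the one-pixel exterior
    ring, matching a tumour at half carrying capacity whose rim sits at
    the detection threshold: the threshold value is attained on the
    interface itself (enforced by the solver's ghost values), not over a
    pixel-wide annulus.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if not tumor_mask.any():
        raise ValueError("empty tumour mask")
    if np.any(tumor_mask & ~domain.domain_mask):
        raise ValueError("tumour mask extends outside the host domain")
    phi = _signed_edt(tumor_mask, domain.spacing)
    phi = reinitialize(phi, domain.spacing)
    ring = ndimage.binary_dilation(tumor_mask) & ~tumor_mask
    u = np.zeros(domain.shape)
    u[tumor_mask] = u0
    u[ring] = u_bar
    return LevelSetState(
        phi=phi, u=u, time=day_to_hours(day), u_bar=u_bar, spacing=domain.spacing
    )


def _axis_fields(
    D: float | np.ndarray | tuple[np.ndarray, np.ndarray], shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Normalise the diffusivity argument to per-axis fields in um^2/h."""
    if isinstance(D, tuple):
        dx, dy = D
        return np.asarray(dx, dtype=float), np.asarray(dy, dtype=float)
    arr = np.asarray(D, dtype=float)
    if arr.ndim == 0:
        arr = np.full(shape, float(arr))
    return arr, arr


def interface_velocity(
    state: LevelSetState,
    D: float | np.ndarray | tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """Extended normal front speed (mm/h) from the Stefan condition.

    For each interior pixel hugging the front, the interface point is
    located along the outward normal at distance |phi|; the normal
    density derivative there is evaluated with a second-order one-sided
    formula using u = u_bar on the interface and two interior samples
    taken along the normal (bilinear interpolation). The resulting speed
    is extended to the whole grid by constant extrapolation along normals
    via a nearest-front-pixel lookup.

    With a per-axis (Dx, Dy) pair the mobility is the diagonal tensor and
    the density gradient is taken normal to the front (u is constant
    along it), giving v = -(Dx nx^2 + Dy ny^2) (du/dn) / u_bar.
    """
    phi, u = state.phi, state.u
    hx, hy = state.spacing
    h = min(hx, hy)
    Dx_um, Dy_um = _axis_fields(D, phi.shape)
    Dx, Dy = um2h_to_mm2h(1.0) * Dx_um, um2h_to_mm2h(1.0) * Dy_um

    inside = phi < 0
    front = inside & ndimage.binary_dilation(~inside)
    if not front.any():
        return np.zeros_like(phi)
    gpx, gpy = _central_gradient(phi, hx, hy)
    norm = np.hypot(gpx, gpy)
    if float(norm[front].min()) < 1e-8:
        raise RuntimeError("degenerate level-set gradient on the interface")
    nx = gpx / np.maximum(norm, 1e-12)
    ny = gpy / np.maximum(norm, 1e-12)

    u_eff = np.where(inside, u, state.u_bar)
    idx = np.argwhere(front)
    px = (idx[:, 0] + 0.5) * hx
    py = (idx[:, 1] + 0.5) * hy
    nfx = nx[front]
    nfy = ny[front]
    pphi = phi[front]  # negative: distance from pixel to interface is |phi|
    ix = px - pphi * nfx  # interface points (outward by |phi|)
    iy = py - pphi * nfy
    delta = 1.25 * h
    samples = []
    for k in (1, 2):
        sx = ix - k * delta * nfx
        sy = iy - k * delta * nfy
        coords = np.vstack([sx / hx - 0.5, sy / hy - 0.5])
        samples.append(
            ndimage.map_coordinates(u_eff, coords, order=1, mode="nearest")
        )
    u1, u2 = samples
    dudn = (3.0 * state.u_bar - 4.0 * u1 + u2) / (2.0 * delta)

    v = np.zeros_like(phi)
    v[front] = -(Dx[front] * nfx**2 + Dy[front] * nfy**2) * dudn / state.u_bar
    _, (ii, jj) = ndimage.distance_transform_edt(
        ~front, sampling=state.spacing, return_indices=True
    )
    return v[ii, jj]


def _central_gradient(f: np.ndarray, hx: float, hy: float) -> tuple[np.ndarray, np.ndarray]:
    gx = (np.roll(f, -1, axis=0) - np.roll(f, 1, axis=0)) / (2 * hx)
    gy = (np.roll(f, -1, axis=1) - np.roll(f, 1, axis=1)) / (2 * hy)
    return gx, gy


def _godunov_gradient_norm(phi: np.ndarray, F: np.ndarray, hx: float, hy: float) -> np.ndarray:
    """Upwind |grad phi| for the advection phi_t + F |grad phi| = 0."""
    a = (phi - np.roll(phi, 1, axis=0)) / hx  # backward x
    b = (np.roll(phi, -1, axis=0) - phi) / hx  # forward x
    c = (phi - np.roll(phi, 1, axis=1)) / hy
    d = (np.roll(phi, -1, axis=1) - phi) / hy
    pos = np.sqrt(
        np.maximum(a, 0) ** 2 + np.minimum(b, 0) ** 2
        + np.maximum(c, 0) ** 2 + np.minimum(d, 0) ** 2
    )
    neg = np.sqrt(
        np.minimum(a, 0) ** 2 + np.maximum(b, 0) ** 2
        + np.minimum(c, 0) ** 2 + np.maximum(d, 0) ** 2
    )
    return np.where(F > 0, pos, neg)


# ---------------------------------------------------------------------------
# time stepping


def _diffusion_update(
    u: np.ndarray,
    phi: np.ndarray,
    allowed: np.ndarray,
    Dx: np.ndarray,
    Dy: np.ndarray,
    rho: float,
    u_bar: float,
    dt: float,
    hx: float,
    hy: float,
) -> np.ndarray:
    """One forward-Euler step of Fisher-KPP on Omega_1.

    The interface Dirichlet condition u = u_bar is imposed at the exact
    zero crossing of phi: an exterior neighbour contributes a linearly
    extrapolated ghost value chosen so that u passes through u_bar at the
    interface location on the connecting segment (the interface fraction
    is read off the signed distances). Faces leaving the host domain
    (skull, ventricles) carry zero flux.
    """
    inside = (phi < 0) & allowed
    div = np.zeros_like(u)
    # Cut fractions below this are clamped: the ghost extrapolation then
    # behaves like an amplified conductance (factor 1/theta_min), which
    # the time-step safety factor in `evolve` is sized to cover.
    theta_min = 0.3
    for axis, (h, Dax) in enumerate(((hx, Dx), (hy, Dy))):
        for shift in (1, -1):
            nb_u = np.roll(u, shift, axis=axis)
            nb_phi = np.roll(phi, shift, axis=axis)
            nb_inside = np.roll(inside, shift, axis=axis)
            nb_allowed = np.roll(allowed, shift, axis=axis)
            nb_D = np.roll(Dax, shift, axis=axis)
            d_face = 0.5 * (Dax + nb_D) * um2h_to_mm2h(1.0)
            # exterior neighbour: ghost value with u = u_bar at the cut
            denom = phi - nb_phi
            theta = np.divide(
                phi, denom, out=np.ones_like(phi), where=np.abs(denom) > 1e-12
            )
            theta = np.clip(np.abs(theta), theta_min, 1.0)
            ghost = u_bar + (u_bar - u) * (1.0 - theta) / theta
            nb_val = np.where(nb_inside, nb_u, ghost)
            cond = np.where(allowed & nb_allowed, d_face / (h * h), 0.0)
            div += np.where(inside, cond * (nb_val - u), 0.0)
    u_new = u + dt * (div + rho * u * (1.0 - u))
    return np.where(inside, u_new, 0.0)


def evolve(
    state: LevelSetState,
    params: Params,
    domain: PlanarDomain,
    t_end: float,
    *,
    D_field: np.ndarray | tuple[np.ndarray, np.ndarray] | None = None,
    speed_override: float | None = None,
    output_times: list[float] | None = None,
    reinit_every: int = 6,
    cfl: float = 0.5,
    max_dt: float = 6.0,
) -> list[LevelSetState]:
    """Advance the Stefan problem to ``t_end`` hours.

    Alternates (i) an interior Fisher-KPP step with interface Dirichlet
    u = u_bar and no-flux host boundaries, (ii) upwind advection of phi by
    the extended Stefan speed under the CFL restriction
    dt <= cfl * min(h) / max|v|, and (iii) reinitialisation every
    ``reinit_every`` advection steps. Host geometry replacements attached
    to ``domain`` are swapped in at the start of their day and the tumour
    clipped out of the new ventricles.

    ``speed_override`` is a test hook that moves the front at a prescribed
    constant normal speed (mm/h), bypassing the Stefan condition and the
    interior density update. ``D_field`` (um^2/h; scalar array or per-axis
    pair) overrides the scalar ``params.D``.

    Returns the state history at ``output_times`` (hours; default just
    ``t_end``).
    """
    if t_end <= state.time:
        raise ValueError("t_end must exceed the state's time")
    hx, hy = state.spacing
    hmin = min(hx, hy)
    D = D_field if D_field is not None else float(params.D)
    Dx, Dy = _axis_fields(D, state.phi.shape)
    d_mm_max = um2h_to_mm2h(1.0) * max(float(Dx.max()), float(Dy.max()))
    # explicit-diffusion stability with margin for the ghost-value
    # conductance amplification (up to 1/theta_min ~ 3.3)
    dt_diff = 0.28 / (2.0 * um2h_to_mm2h(1.0) * (Dx.max() / hx**2 + Dy.max() / hy**2))
    out_times = sorted(output_times) if output_times else [t_end]
    if any(t <= state.time or t > t_end + 1e-9 for t in out_times):
        raise ValueError("output times must lie in (state.time, t_end]")

    phi = state.phi.copy()
    u = state.u.copy()
    t = state.time
    u_bar = state.u_bar
    current_domain = domain.at_day(t / 24.0)
    pending_updates = [
        (d, b, v) for d, b, v in domain.updates if day_to_hours(d) > t
    ]
    history: list[LevelSetState] = []
    next_out = 0
    step = 0
    while t < t_end - 1e-9:
        # geometry swap at the start of an update day (day boundary inclusive)
        while pending_updates and t >= day_to_hours(pending_updates[0][0]) - 1e-9:
            d, brain, vent = pending_updates.pop(0)
            current_domain = PlanarDomain(domain.shape, domain.spacing, brain, vent)
            blocked = ~current_domain.domain_mask
            phi[blocked] = np.maximum(phi[blocked], hmin)
            u[blocked] = 0.0
            phi = reinitialize(phi, state.spacing)
        allowed = current_domain.domain_mask
        inside = (phi < 0) & allowed

        if speed_override is not None:
            F = np.full_like(phi, float(speed_override))
        else:
            F = interface_velocity(
                LevelSetState(phi, u, t, u_bar, state.spacing), (Dx, Dy)
            )
        vmax = float(np.abs(F).max())
        dt = min(max_dt, dt_diff)
        if vmax > 0:
            dt = min(dt, cfl * hmin / vmax)
        if dt < 1e-6:
            raise RuntimeError(f"CFL time step collapsed (max speed {vmax:g} mm/h)")
        # land exactly on the next output time or geometry-update day
        t_next_event = out_times[next_out] if next_out < len(out_times) else t_end
        if pending_updates:
            t_next_event = min(t_next_event, day_to_hours(pending_updates[0][0]))
        dt = min(dt, t_next_event - t)

        if speed_override is None:
            u = _diffusion_update(
                u, phi, allowed, Dx, Dy, params.rho, u_bar, dt, hx, hy
            )
        phi = phi - dt * F * _godunov_gradient_norm(phi, F, hx, hy)
        # the tumour never enters ventricles or leaves the brain
        blocked = ~allowed
        phi[blocked] = np.maximum(phi[blocked], hmin / 2.0)
        if vmax > 0:  # reinitialise only after actual front motion
            step += 1
            if step % reinit_every == 0:
                phi = reinitialize(phi, state.spacing)
        # freshly swallowed pixels start at the interface density
        new_inside = (phi < 0) & allowed & ~inside
        u[new_inside] = u_bar
        u[(phi >= 0)] = 0.0
        t += dt

        if next_out < len(out_times) and t >= out_times[next_out] - 1e-9:
            history.append(
                LevelSetState(
                    reinitialize(phi, state.spacing).copy(),
                    u.copy(),
                    out_times[next_out],
                    u_bar,
                    state.spacing,
                )
            )
            next_out += 1
    if not history:
        history.append(LevelSetState(phi, u, t_end, u_bar, state.spacing))
    return history


# ---------------------------------------------------------------------------
# boundary extraction and fitting


def extract_boundary(state: LevelSetState, day: int | None = None) -> BoundaryCurve:
    """Largest closed zero contour of phi as a BoundaryCurve in mm."""
    contours = _contours_mm(state.phi, state.spacing)
    contours = [c for c in contours if len(c) >= 3]
    if not contours:
        raise ValueError("no zero contour: the tumour region is empty")
    if len(contours) > 1:
        logger.info("multiple contours found; returning the largest of %d", len(contours))
    areas = [BoundaryCurve(c).area() for c in contours]
    return BoundaryCurve(contours[int(np.argmax(areas))], day=day)


def rasterize_tumor(state: LevelSetState) -> np.ndarray:
    """Pixel mask of the tumour region Omega_1 = {phi < 0}."""
    return state.phi < 0


@dataclass(frozen=True)
class PlanarSeries:
    """Per-day 2D observations: visible masks and boundary polylines."""

    domain: PlanarDomain
    days: tuple[int, ...]
    masks: tuple[np.ndarray, ...]
    boundaries: tuple[np.ndarray, ...]  # (L, 2) vertex arrays, mm

    def __post_init__(self) -> None:
        if not (len(self.days) == len(self.masks) == len(self.boundaries) >= 2):
            raise ValueError("need aligned days, masks, and boundaries (>= 2 days)")


def simulate_planar_truth(
    domain: PlanarDomain,
    tumor0: np.ndarray,
    params: Params,
    days: tuple[int, ...],
    *,
    u0: float = 0.5,
    u_bar: float = DEFAULT_U_BAR,
    D_field: np.ndarray | tuple[np.ndarray, np.ndarray] | None = None,
) -> PlanarSeries:
    """Generate a synthetic 2D observation series with the Stefan solver
    itself (the 2D analogue of the 3D phantom's ground-truth series)."""
    state = init_state(tumor0, domain, u0=u0, u_bar=u_bar, day=days[0])
    times = [day_to_hours(d) for d in days[1:]]
    history = evolve(
        state, params, domain, times[-1], D_field=D_field, output_times=times
    )
    masks = [tumor0.astype(bool)] + [rasterize_tumor(s) for s in history]
    bounds = [extract_boundary(state).vertices] + [
        extract_boundary(s).vertices for s in history
    ]
    return PlanarSeries(
        domain=domain,
        days=tuple(days),
        masks=tuple(masks),
        boundaries=tuple(bounds),
    )


@dataclass(frozen=True)
class LevelSetFitResult:
    params: Params
    E2: float
    z_d: float
    jaccards: tuple[float, ...]
    evaluations: int
    converged: bool
    config_hash: str


def levelset_objective(
    params: Params,
    series: PlanarSeries,
    *,
    u0: float = 0.5,
    u_bar: float = DEFAULT_U_BAR,
    D_field: np.ndarray | tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, float, tuple[float, ...]]:
    """E2, z_d, and per-day Jaccards of a forward Stefan run vs the data."""
    sim = simulate_planar_truth(
        series.domain,
        series.masks[0],
        params,
        series.days,
        u0=u0,
        u_bar=u_bar,
        D_field=D_field,
    )
    z_d = boundary_distance_error(sim.boundaries[1:], series.boundaries[1:])
    jacc = tuple(
        jaccard_distance(a, b) for a, b in zip(sim.masks[1:], series.masks[1:])
    )
    return total_error_E2(z_d, jacc), z_d, jacc


def fit_levelset(
    series: PlanarSeries,
    initial_guess: Params = Params(500.0, 0.02),
    *,
    u0: float = 0.5,
    u_bar: float = DEFAULT_U_BAR,
    max_evaluations: int = 150,
    xtol_log: float = 1e-3,
    ftol: float = 1e-3,
) -> LevelSetFitResult:
    """Nelder-Mead minimisation of E2 over (log D, log rho)."""
    from scipy.optimize import minimize

    x0 = np.log(initial_guess.as_tuple())
    step = np.log(1.2)
    simplex = np.array([x0, x0 + [step, 0.0], x0 + [0.0, step]])
    best: dict = {"x": x0, "f": np.inf, "zd": np.nan, "jacc": ()}
    n_eval = 0

    def wrapped(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        p = Params(float(np.exp(x[0])), float(np.exp(x[1])))
        try:
            e2, zd, jacc = levelset_objective(p, series, u0=u0, u_bar=u_bar)
        except (RuntimeError, ValueError) as exc:
            logger.warning("level-set solve failed at %s: %s", p, exc)
            return 1e6
        if e2 < best["f"]:
            best.update(x=np.array(x), f=e2, zd=zd, jacc=jacc)
        return e2

    res = minimize(
        wrapped,
        x0,
        method="Nelder-Mead",
        options={
            "initial_simplex": simplex,
            "xatol": xtol_log,
            "fatol": ftol,
            "maxfev": max_evaluations,
        },
    )
    x = best["x"]
    return LevelSetFitResult(
        params=Params(float(np.exp(x[0])), float(np.exp(x[1]))),
        E2=float(best["f"]),
        z_d=float(best["zd"]),
        jaccards=tuple(best["jacc"]),
        evaluations=n_eval,
        converged=bool(res.success),
        config_hash=config_hash(
            {"guess": initial_guess.as_tuple(), "u0": u0, "u_bar": u_bar}
        ),
    )
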