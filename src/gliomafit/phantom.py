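"""Synthetic phantom generator: mouse-scale brain masks with ventricle
cavities, spherical day-11 tumour seeds, and forward-model-generated
visible-tumour series.

The phantom emulates the registered, segmented T2-weighted mask series the
pipeline is built for: an ellipsoidal brain with ellipsoidal ventricle
cavities on the anisotropic 0.1 x 0.1 x 0.5 mm imaging grid, a sub-mm^3
spherical seed initialised at half carrying capacity, and per-day masks
obtained by thresholding a forward Fisher-KPP run at the detection
threshold 0.16. Optional independent voxel flips on the mask's one-voxel
boundary shell emulate segmentation uncertainty; optional ventricle drift
emulates mass effect. Everything is reproducible from (seed, spec).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import (
    DEFAULT_IMAGING_DAYS,
    BrainGeometry,
    DensityField,
    Grid3D,
    ImagingSeries,
    Params,
)
from .solver3d import SolverConfig, integrate_series, threshold_to_mask
from .units import day_to_hours

__all__ = [
    "PhantomSpec",
    "DFieldSpec2D",
    "make_brain_phantom",
    "make_initial_field",
    "simulate_ground_truth",
    "drift_ventricles",
    "make_anisotropic_D_field",
    "extract_slice",
]

#: Default Fisher-KPP truth: a published whole-series murine GL261 estimate
#: (D in um^2/h, rho in 1/h), giving day-25 volumes on the tens-of-mm^3
#: scale observed in vivo.
DEFAULT_TRUE_PARAMS = Params(D=413.77, rho=0.0188)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic mask series.

    Geometry is mm-valued and rasterised voxel-centred on ``grid``. The
    default seed radius (0.55 mm, ~0.7 mm^3) matches the sub-mm^3 day-11
    visible volumes of the murine study conditions this phantom emulates.
    """

    grid: Grid3D = Grid3D((48, 48, 16))
    brain_semiaxes: tuple[float, float, float] = (2.3, 2.3, 3.7)
    brain_center: tuple[float, float, float] | None = None  # default: grid centre
    ventricles: tuple[tuple[tuple[float, float, float], tuple[float, float, float]], ...] = (
        ((-0.7, 0.0, 0.5), (0.2, 0.4, 0.9)),
        ((0.7, 0.6, 0.5), (0.2, 0.4, 0.9)),
    )  # (centre offset from brain centre, semi-axes), mm
    seed_center: tuple[float, float, float] | None = None  # mm; default offset seed
    seed_radius: float = 0.55  # mm
    u0: float = 0.5
    true_params: Params | tuple[Params, ...] = DEFAULT_TRUE_PARAMS
    days: tuple[int, ...] = DEFAULT_IMAGING_DAYS
    threshold: float = 0.16
    noise_p: float = 0.0
    ventricle_drift: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm/day
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if not (0.0 <= self.noise_p < 1.0):
            raise ValueError("noise_p must lie in [0, 1)")
        if not (0.0 <= self.u0 <= 1.0):
            raise ValueError("u0 must lie in [0, 1]")
        if self.seed_radius <= 0:
            raise ValueError("seed_radius must be positive")

    def resolved_brain_center(self) -> tuple[float, float, float]:
        return self.brain_center or self.grid.center_mm()

    def resolved_seed_center(self) -> tuple[float, float, float]:
        if self.seed_center is not None:
            return self.seed_center
        cx, cy, cz = self.resolved_brain_center()
        return (cx + 0.9, cy - 0.6, cz - 0.5)

    def params_per_interval(self) -> tuple[Params, ...]:
        n = len(self.days) - 1
        if isinstance(self.true_params, Params):
            return (self.true_params,) * n
        params = tuple(self.true_params)
        if len(params) != n:
            raise ValueError(f"need {n} per-interval Params, got {len(params)}")
        return params


@dataclass(frozen=True)
class DFieldSpec2D:
    """Quadrant-wise random 2D diffusion field specification.

    Per-pixel diffusivities are drawn uniformly from half-plane-specific
    intervals expressed as fractions of the base value ``eta`` (um^2/h).
    The default intervals and eta reproduce the anisotropic simulation
    conditions of the murine study: horizontal-direction D in [0, 0.2 eta]
    on the left half and [0, 0.05 eta] on the right; vertical-direction D
    in [0.1, 0.4] eta on the top half and [0.3, 0.5] eta on the bottom.
    """

    eta: float = 11120.0  # um^2/h
    left_horizontal: tuple[float, float] = (0.0, 0.2)
    right_horizontal: tuple[float, float] = (0.0, 0.05)
    top_vertical: tuple[float, float] = (0.1, 0.4)
    bottom_vertical: tuple[float, float] = (0.3, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("left_horizontal", "right_horizontal", "top_vertical", "bottom_vertical"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid interval {name}: ({lo}, {hi})")
        if self.eta <= 0:
            raise ValueError("eta must be positive")


def _ellipsoid_mask(
    grid: Grid3D,
    center: Sequence[float],
    semiaxes: Sequence[float],
) -> np.ndarray:
    xs, ys, zs = grid.voxel_centers()
    cx, cy, cz = center
    ax, ay, az = semiaxes
    q = (
        ((xs[:, None, None] - cx) / ax) ** 2
        + ((ys[None, :, None] - cy) / ay) ** 2
        + ((zs[None, None, :] - cz) / az) ** 2
    )
    return q <= 1.0


def _sphere_mask(grid: Grid3D, center: Sequence[float], radius: float) -> np.ndarray:
    return _ellipsoid_mask(grid, center, (radius, radius, radius))


def make_brain_phantom(spec: PhantomSpec) -> BrainGeometry:
    """Rasterise the ellipsoidal brain-minus-ventricles geometry."""
    grid = spec.grid
    bc = spec.resolved_brain_center()
    brain = _ellipsoid_mask(grid, bc, spec.brain_semiaxes)
    vent = np.zeros(grid.shape, dtype=bool)
    for offset, semiaxes in spec.ventricles:
        center = tuple(c + o for c, o in zip(bc, offset))
        v = _ellipsoid_mask(grid, center, semiaxes)
        if np.any(v & ~brain):
            raise ValueError(f"ventricle at {center} extends outside the brain")
        vent |= v
    geometry = BrainGeometry(grid=grid, brain_mask=brain, ventricle_mask=vent)
    seed = _sphere_mask(grid, spec.resolved_seed_center(), spec.seed_radius)
    if np.any(seed & vent):
        raise ValueError("seed sphere overlaps a ventricle")
    if not np.any(seed & geometry.domain_mask):
        raise ValueError("seed sphere lies outside the computational domain")
    return geometry


def make_initial_field(
    geometry: BrainGeometry,
    center: Sequence[float],
    radius: float,
    u0: float,
    *,
    day: int = 11,
) -> DensityField:
    """Initial density: u0 inside the seed sphere (within the domain), 0
    elsewhere, at t = 24 * day hours."""
    sphere = _sphere_mask(geometry.grid, center, radius) & geometry.domain_mask
    if u0 > 0 and not sphere.any():
        raise ValueError("seed sphere does not intersect the domain")
    values = np.zeros(geometry.grid.shape)
    values[sphere] = float(u0)
    return DensityField(geometry=geometry, time=day_to_hours(day), values=values)


def _boundary_shell(mask: np.ndarray, domain: np.ndarray) -> np.ndarray:
    """One-voxel shell straddling the mask boundary, clipped to the domain."""
    inner = mask & ~ndimage.binary_erosion(mask)
    outer = ndimage.binary_dilation(mask) & ~mask
    return (inner | outer) & domain


def simulate_ground_truth(
    spec: PhantomSpec,
    solver_config: SolverConfig | None = None,
) -> tuple[ImagingSeries, list[DensityField]]:
    """Forward-simulate the phantom and threshold to a visible-tumour series.

    Returns the (possibly noise-corrupted) imaging series together with
    the noiseless density history (one field per imaging day, including
    day one). With ``noise_p > 0``, voxels on each mask's one-voxel
    boundary shell are flipped independently with probability ``noise_p``
    using the spec's seed; the flips perturb segmentation without
    destroying topology.
    """
    solver_config = solver_config or SolverConfig(threshold=spec.threshold)
    geometry = make_brain_phantom(spec)
    field = make_initial_field(
        geometry, spec.resolved_seed_center(), spec.seed_radius, spec.u0, day=spec.days[0]
    )
    history = [field]
    params_seq = spec.params_per_interval()
    if len(set(params_seq)) == 1:
        # constant truth: one continuous integration through all days
        times = [day_to_hours(d) for d in spec.days[1:]]
        history.extend(integrate_series(field, params_seq[0], times, solver_config))
    else:
        current = field
        for params, day in zip(params_seq, spec.days[1:]):
            current = integrate_series(
                current, params, [day_to_hours(day)], solver_config
            )[-1]
            history.append(current)
    masks = [threshold_to_mask(f, spec.threshold) for f in history]

    if spec.noise_p > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = []
        for mask in masks:
            shell = _boundary_shell(mask, geometry.domain_mask)
            flips = shell & (rng.random(mask.shape) < spec.noise_p)
            noisy.append(mask ^ flips)
        masks = noisy

    series = ImagingSeries(geometry=geometry, days=spec.days, masks=tuple(masks))
    return series, history


def drift_ventricles(
    geometry: BrainGeometry,
    drift_mm_per_day: Sequence[float],
    day: int,
    *,
    baseline_day: int = 11,
) -> BrainGeometry:
    """Translate the ventricle mask by the nearest-voxel offset of
    drift * (day - baseline_day) and recompute the domain.

    Offsets are integer voxel shifts, so applying the reverse drift
    recovers the original mask exactly.
    """
    drift = np.asarray(drift_mm_per_day, dtype=float)
    shift_mm = drift * (int(day) - int(baseline_day))
    shift_vox = np.round(shift_mm / np.asarray(geometry.grid.spacing)).astype(int)
    if not shift_vox.any():
        return geometry
    vent = _integer_shift(geometry.ventricle_mask, shift_vox)
    if np.any(vent & ~geometry.brain_mask):
        raise ValueError("drift pushes a ventricle outside the brain")
    if int(vent.sum()) != int(geometry.ventricle_mask.sum()):
        raise ValueError("drift pushes a ventricle outside the grid")
    return BrainGeometry(
        grid=geometry.grid, brain_mask=geometry.brain_mask, ventricle_mask=vent
    )


def _integer_shift(mask: np.ndarray, shift: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mask)
    src = []
    dst = []
    for s, n in zip(shift, mask.shape):
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def make_anisotropic_D_field(
    domain2d: np.ndarray,
    spec: DFieldSpec2D,
    mode: str = "axiswise",
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Random half-plane-structured diffusion field(s) in um^2/h.

    ``mode='axiswise'`` (default) reads the half-plane intervals as
    direction-specific diffusivities and returns ``(Dx, Dy)``: Dx drawn
    from the left/right-half horizontal intervals, Dy from the top/bottom
    vertical intervals. ``mode='quadrant'`` returns a single scalar field
    whose per-quadrant interval averages the bounds of the two governing
    half-plane intervals. Both readings of the half-plane prescription are
    supported because the prescription itself does not fix one; see
    docs/methods.md.

    Pixels outside ``domain2d`` are 0. Axis convention: axis 0 is
    horizontal x (left half = lower indices), axis 1 is vertical y (top
    half = upper indices).
    """
    domain2d = np.asarray(domain2d, dtype=bool)
    if domain2d.ndim != 2 or not domain2d.any():
        raise ValueError("domain2d must be a nonempty 2D mask")
    nx, ny = domain2d.shape
    rng = np.random.default_rng(spec.seed)
    x_half = np.arange(nx)[:, None] < nx // 2  # True on the left
    y_half = np.arange(ny)[None, :] >= ny // 2  # True on the top

    def draw(interval: tuple[float, float], shape: tuple[int, int]) -> np.ndarray:
        lo, hi = (interval[0] * spec.eta, interval[1] * spec.eta)
        return rng.uniform(lo, hi, size=shape)

    if mode == "axiswise":
        dx = np.where(
            np.broadcast_to(x_half, (nx, ny)),
            draw(spec.left_horizontal, (nx, ny)),
            draw(spec.right_horizontal, (nx, ny)),
        )
        dy = np.where(
            np.broadcast_to(y_half, (nx, ny)),
            draw(spec.top_vertical, (nx, ny)),
            draw(spec.bottom_vertical, (nx, ny)),
        )
        dx[~domain2d] = 0.0
        dy[~domain2d] = 0.0
        return dx, dy
    if mode == "quadrant":
        out = np.zeros((nx, ny))
        for hx, h_int in ((True, spec.left_horizontal), (False, spec.right_horizontal)):
            for hy, v_int in ((True, spec.top_vertical), (False, spec.bottom_vertical)):
                quad = (x_half == hx) & (y_half == hy)
                lo = 0.5 * (h_int[0] + v_int[0])
                hi = 0.5 * (h_int[1] + v_int[1])
                out[quad] = rng.uniform(lo * spec.eta, hi * spec.eta, size=int(quad.sum()))
        out[~domain2d] = 0.0
        return out
    raise ValueError(f"unknown mode {mode!r}")


_SLICE_AXES = {"transverse": 2, "sagittal": 0, "coronal": 1}


def extract_slice(
    volume: np.ndarray,
    axis: str,
    index: int,
    grid: Grid3D | None = None,
) -> tuple[np.ndarray, tuple[float, float] | None]:
    """2D section of a volume: transverse fixes z, sagittal fixes x,
    coronal fixes y. Returns the plane and its in-plane spacing (mm), or
    None for the spacing if no grid is given."""
    try:
        ax = _SLICE_AXES[axis]
    except KeyError:
        raise ValueError(f"axis must be one of {sorted(_SLICE_AXES)}, got {axis!r}")
    volume = np.asarray(volume)
    if not (0 <= index < volume.shape[ax]):
        raise IndexError(f"slice index {index} out of range for axis {axis!r}")
    plane = np.take(volume, index, axis=ax)
    spacing = None
    if grid is not None:
        in_plane = [grid.spacing[i] for i in range(3) if i != ax]
        spacing = (in_plane[0], in_plane[1])
    return plane, spacing
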