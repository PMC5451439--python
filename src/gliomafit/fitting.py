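"""Parameter estimation (D, rho) against an imaging series.

The objective is the Jaccard-distance error between simulated and observed
visible-tumour masks, minimised with derivative-free Nelder-Mead over
(log D, log rho) — the log transform guarantees every evaluation sees
positive parameters. Three hypotheses about the time dependence of the
dynamics are supported:

* Hypothesis 1 — one constant (D, rho) pair fitted to all follow-up days,
  with the time-averaged (mean-mode) error functional;
* Hypothesis 2 — per-interval parameters fitted sequentially, carrying the
  continuous simulated field across interval boundaries;
* Hypothesis 3 — per-interval parameters with the initial condition reset
  from the *observed* mask at each imaging day ("predictor-corrector");
  errors are scored on the predictions made before each reset.

Hypothesis 2/3 aggregates are conventionally reported in sum mode, the
whole-series Hypothesis 1 error in mean mode; both are always stored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .geometry import BrainGeometry, DensityField, ImagingSeries, Params
from .io import config_hash
from .metrics import ErrorReport, jaccard_distance, series_error, wave_speed
from .solver3d import SolverConfig, integrate_series, threshold_to_mask
from .units import day_to_hours

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitResult",
    "objective_h1",
    "fit_hypothesis1",
    "fit_hypothesis2",
    "fit_hypothesis3",
    "sensitivity_initial_density",
]


@dataclass(frozen=True)
class FitConfig:
    """Optimiser and initialisation settings for the Jaccard fits."""

    initial_guess: Params = Params(D=500.0, rho=0.02)
    xtol_log: float = 1e-3  # simplex convergence in log-parameter space
    ftol: float = 1e-3  # simplex convergence on the error value
    max_evaluations: int = 300
    u0: float = 0.5  # density assigned to mask voxels when building ICs
    threshold: float = 0.16
    solver: SolverConfig = field(default_factory=SolverConfig)
    #: Hypothesis 3 reset style: 'observed' rebuilds each interval's IC at
    #: density u0 inside the observed mask; 'carry' keeps the simulated
    #: densities inside the observed mask instead.
    h3_reset: str = "observed"
    #: Penalty returned to the simplex when a forward solve fails.
    failure_penalty: float = 10.0

    def __post_init__(self) -> None:
        if self.xtol_log <= 0 or self.ftol <= 0:
            raise ValueError("tolerances must be positive")
        if not (0.0 < self.u0 <= 1.0):
            raise ValueError("u0 must lie in (0, 1]")
        if self.h3_reset not in ("observed", "carry"):
            raise ValueError("h3_reset must be 'observed' or 'carry'")


@dataclass(frozen=True)
class IntervalFit:
    """One fitted interval: (start day, end day), parameters, error."""

    start_day: int
    end_day: int
    params: Params
    jaccard: float
    evaluations: int
    converged: bool


@dataclass(frozen=True)
class FitResult:
    hypothesis: int
    intervals: tuple[IntervalFit, ...]
    report_mean: ErrorReport
    report_sum: ErrorReport
    evaluations: int
    converged: bool
    config_hash: str

    @property
    def params(self) -> Params:
        """The single parameter pair (Hypothesis 1 only)."""
        if self.hypothesis != 1:
            raise ValueError("per-interval fits have one Params per interval")
        return self.intervals[0].params

    @property
    def aggregate(self) -> float:
        """The conventional aggregate: mean mode for Hypothesis 1, sum
        mode for Hypotheses 2 and 3."""
        return (self.report_mean if self.hypothesis == 1 else self.report_sum).aggregate

    def wave_speeds(self) -> tuple[float, ...]:
        return tuple(wave_speed(iv.params) for iv in self.intervals)


def _field_from_mask(
    geometry: BrainGeometry, mask: np.ndarray, u0: float, time_hours: float
) -> DensityField:
    values = np.zeros(geometry.grid.shape)
    values[mask & geometry.domain_mask] = u0
    return DensityField(geometry=geometry, time=time_hours, values=values)


def _predicted_masks(
    field: DensityField,
    params: Params,
    times: Sequence[float],
    cfg: FitConfig,
) -> list[np.ndarray]:
    fields = integrate_series(field, params, list(times), cfg.solver)
    return [threshold_to_mask(f, cfg.threshold) for f in fields]


def objective_h1(params: Params, series: ImagingSeries, cfg: FitConfig | None = None) -> float:
    """Mean-mode Jaccard error of a constant-parameter forward run.

    The initial condition is built from the first observed mask at density
    ``cfg.u0``; the model is integrated through every follow-up day and
    each predicted visible mask compared with the observation.
    """
    cfg = cfg or FitConfig()
    ic = _field_from_mask(
        series.geometry, series.masks[0], cfg.u0, day_to_hours(series.days[0])
    )
    sim = _predicted_masks(ic, params, series.times_hours[1:], cfg)
    return series_error(sim, series, mode="mean").aggregate


def _minimize_log(
    fun: Callable[[Params], float],
    cfg: FitConfig,
) -> tuple[Params, float, int, bool]:
    """Nelder-Mead over log-parameters with a failure-penalised objective.

    The initial simplex perturbs each log coordinate by log(1.2), i.e.
    +/-20 percent multiplicative steps around the guess. The best point
    ever evaluated is returned, so the result is never worse than the
    initial guess.
    """
    x0 = np.log(cfg.initial_guess.as_tuple())
    step = np.log(1.2)
    simplex = np.array([x0, x0 + [step, 0.0], x0 + [0.0, step]])
    best: dict = {"x": None, "f": np.inf}
    n_eval = 0

    def wrapped(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        p = Params(float(np.exp(x[0])), float(np.exp(x[1])))
        try:
            f = fun(p)
        except RuntimeError as exc:  # unstable forward solve
            logger.warning("forward solve failed at %s: %s", p, exc)
            return cfg.failure_penalty
        if f < best["f"]:
            best["x"], best["f"] = np.array(x), f
        return f

    res = minimize(
        wrapped,
        x0,
        method="Nelder-Mead",
        options={
            "initial_simplex": simplex,
            "xatol": cfg.xtol_log,
            "fatol": cfg.ftol,
            "maxfev": cfg.max_evaluations,
            "disp": False,
        },
    )
    x = best["x"] if best["x"] is not None else res.x
    params = Params(float(np.exp(x[0])), float(np.exp(x[1])))
    return params, float(best["f"]), n_eval, bool(res.success)


def fit_hypothesis1(series: ImagingSeries, cfg: FitConfig | None = None) -> FitResult:
    """Constant (D, rho) fitted to the whole series (Hypothesis 1)."""
    cfg = cfg or FitConfig()
    params, err, n_eval, converged = _minimize_log(
        lambda p: objective_h1(p, series, cfg), cfg
    )
    ic = _field_from_mask(
        series.geometry, series.masks[0], cfg.u0, day_to_hours(series.days[0])
    )
    sim = _predicted_masks(ic, params, series.times_hours[1:], cfg)
    per_day = tuple(
        jaccard_distance(s, o) for s, o in zip(sim, series.masks[1:])
    )
    interval = IntervalFit(
        start_day=series.days[0],
        end_day=series.days[-1],
        params=params,
        jaccard=float(np.mean(per_day)),
        evaluations=n_eval,
        converged=converged,
    )
    return FitResult(
        hypothesis=1,
        intervals=(interval,),
        report_mean=ErrorReport(per_day, "mean"),
        report_sum=ErrorReport(per_day, "sum"),
        evaluations=n_eval,
        converged=converged,
        config_hash=config_hash(repr(cfg)),
    )


def _fit_sequential(
    series: ImagingSeries, cfg: FitConfig, hypothesis: int
) -> FitResult:
    geometry = series.geometry
    current = _field_from_mask(
        geometry, series.masks[0], cfg.u0, day_to_hours(series.days[0])
    )
    intervals: list[IntervalFit] = []
    per_day: list[float] = []
    total_evals = 0
    all_converged = True
    for k in range(len(series.days) - 1):
        start_day, end_day = series.days[k], series.days[k + 1]
        t_end = day_to_hours(end_day)
        obs = series.masks[k + 1]
        ic = current  # bind for the closure

        def single_interval(p: Params) -> float:
            sim = _predicted_masks(ic, p, [t_end], cfg)[0]
            return jaccard_distance(sim, obs)

        params, err, n_eval, converged = _minimize_log(single_interval, cfg)
        intervals.append(
            IntervalFit(start_day, end_day, params, err, n_eval, converged)
        )
        per_day.append(err)
        total_evals += n_eval
        all_converged &= converged
        # state carried into the next interval
        advanced = integrate_series(current, params, [t_end], cfg.solver)[-1]
        if hypothesis == 2:
            current = advanced
        elif cfg.h3_reset == "observed":
            current = _field_from_mask(geometry, obs, cfg.u0, t_end)
        else:  # hypothesis 3, 'carry': simulated densities on observed support
            values = np.where(obs & geometry.domain_mask, advanced.values, 0.0)
            current = DensityField(geometry=geometry, time=t_end, values=values)
    report = tuple(per_day)
    return FitResult(
        hypothesis=hypothesis,
        intervals=tuple(intervals),
        report_mean=ErrorReport(report, "mean"),
        report_sum=ErrorReport(report, "sum"),
        evaluations=total_evals,
        converged=all_converged,
        config_hash=config_hash(repr(cfg)),
    )


def fit_hypothesis2(series: ImagingSeries, cfg: FitConfig | None = None) -> FitResult:
    """Sequential per-interval fits carrying the continuous simulated
    field forward (Hypothesis 2)."""
    return _fit_sequential(series, cfg or FitConfig(), hypothesis=2)


def fit_hypothesis3(series: ImagingSeries, cfg: FitConfig | None = None) -> FitResult:
    """Sequential per-interval fits with observation-based initial-
    condition resets (Hypothesis 3). Errors are scored on the predictions
    made before each reset."""
    return _fit_sequential(series, cfg or FitConfig(), hypothesis=3)


def sensitivity_initial_density(
    series: ImagingSeries,
    cfg: FitConfig | None = None,
    densities: Sequence[float] = (0.3, 0.5, 0.7),
) -> list[tuple[float, FitResult, float]]:
    """Hypothesis-1 fits repeated across initial densities.

    Returns (density, fit, wave speed) rows. The fitted D and rho trade
    off against each other as the assumed starting density changes, but
    the implied front speeds 2 sqrt(D rho) stay approximately constant.
    """
    cfg = cfg or FitConfig()
    if any(not (0.0 < d < 1.0) for d in densities):
        raise ValueError("densities must lie in (0, 1)")
    rows = []
    for u0 in densities:
        fit = fit_hypothesis1(series, replace(cfg, u0=float(u0)))
        rows.append((float(u0), fit, wave_speed(fit.params)))
    return rows
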