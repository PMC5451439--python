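"""Estimate (D, rho) from a mask series under the three hypotheses.

Fits the default noiseless phantom with (1) constant parameters, (2)
per-interval parameters carrying the simulated state forward, and (3)
per-interval parameters with observation resets, then prints the
per-interval estimates and aggregate Jaccard errors.
"""

from gliomafit import PhantomSpec, simulate_ground_truth, wave_speed
from gliomafit.fitting import (
    FitConfig,
    fit_hypothesis1,
    fit_hypothesis2,
    fit_hypothesis3,
)

spec = PhantomSpec()
series, _ = simulate_ground_truth(spec)
cfg = FitConfig(max_evaluations=150)

print(f"truth: c = {wave_speed(spec.true_params):.4f} um/h\n")
for name, fitter in [("Hypothesis 1", fit_hypothesis1),
                     ("Hypothesis 2", fit_hypothesis2),
                     ("Hypothesis 3", fit_hypothesis3)]:
    fit = fitter(series, cfg)
    print(f"{name} (aggregate error {fit.aggregate:.4f}, "
          f"{fit.evaluations} evaluations):")
    for iv in fit.intervals:
        print(f"  days {iv.start_day:2d}-{iv.end_day:2d}: "
              f"D = {iv.params.D:7.1f} um^2/h  rho = {iv.params.rho:.4f} 1/h  "
              f"c = {wave_speed(iv.params):.3f} um/h  d_J = {iv.jaccard:.4f}")
    print()
print("On noiseless self-consistent data Hypotheses 1 and 2 reach near-zero")
print("error; Hypothesis 3 keeps a small residual because resetting the")
print("density to a uniform 0.5 inside each observed mask discards the")
print("interior structure the model had built up. On real masks the")
print("sequential hypotheses reduce the error by a few to ~20 percent.")
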