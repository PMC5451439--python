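"""Generate a synthetic mask series and inspect the forward simulation.

Builds the default mouse-brain phantom (ellipsoidal brain with ventricle
cavities on the 0.1 x 0.1 x 0.5 mm imaging grid), seeds a ~0.7 mm^3
tumour at half carrying capacity on day 11, runs the Fisher-KPP model to
day 25, and prints the visible-tumour volume per imaging day.
"""

from gliomafit import PhantomSpec, simulate_ground_truth, visible_volume, wave_speed

spec = PhantomSpec()
series, history = simulate_ground_truth(spec)

print(f"truth: D = {spec.true_params.D} um^2/h, rho = {spec.true_params.rho} 1/h")
print(f"implied front speed 2*sqrt(D*rho) = {wave_speed(spec.true_params):.4f} um/h\n")
print("day  visible volume (mm^3)   max density")
for day, mask, field in zip(series.days, series.masks, history):
    vol = visible_volume(mask, spec.grid)
    print(f"{day:3d}  {vol:10.3f}            {field.values.max():.3f}")
print(
    "\nThe visible volume is the count of voxels with u >= 0.16 times the"
    "\nvoxel volume (0.005 mm^3); growth from ~0.8 to ~23 mm^3 over two"
    "\nweeks matches the scale seen in GL261-bearing mice."
)
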