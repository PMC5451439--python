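# Methods

## The model

Tumour growth is modelled by the Fisher–KPP reaction–diffusion equation
for a normalised cell density u(t, x) ∈ [0, 1] (fraction of carrying
capacity):

    ∂u/∂t = ∇·(D ∇u) + ρ u (1 − u),

with no-flux conditions on the brain surface and the ventricle walls —
the tumour penetrates neither. D (µm²/h) is the diffusion (invasion)
coefficient, ρ (1/h) the proliferation rate; in 3D both are spatially
uniform. The model's key emergent quantity is the asymptotic front speed
c = 2√(Dρ) of its traveling-wave solutions.

A simulated tumour is compared with segmented T2-weighted MR masks by
declaring voxels with u ≥ 0.16 "visible" (the hypothesised detection
threshold; the comparison is inclusive at exactly 0.16) and measuring the
Jaccard distance d_J(A, B) = 1 − |A∩B| / |A∪B| per imaging day. The
whole-series error is the time average of the per-day Jaccard distances
over the follow-up days (the initialisation day is excluded). Two empty
masks compare at distance 0; exactly one empty mask at distance 1.

Initial conditions are built from the first imaging day's mask at a
uniform density u₀ = 0.5 (half carrying capacity); day d corresponds to
t = 24 d hours. Lengths are handled internally in mm (1 µm²/h = 10⁻⁶
mm²/h); D is accepted in µm²/h at every public interface.

## 3D forward solver

Space is discretised on the anisotropic imaging grid (0.1 × 0.1 × 0.5 mm
voxels by default) with flux-form centred differences restricted to the
domain voxels; faces adjoining skull or ventricle voxels carry zero flux,
so every row of the discrete diffusion operator sums to zero and mass is
conserved exactly when ρ = 0 — which the tests use as a sharp check.
Time integration is adaptive explicit embedded Runge–Kutta 4(5)
(Dormand–Prince) with rtol 10⁻⁶ and atol 10⁻⁹ by default; all imaging
days are produced from one integration via the dense interpolant, so
results do not depend on how many output days are requested. Densities
are never clamped during integration; output values outside
[−δ, 1 + δ] with δ = 10⁻⁵ abort the run as instability. δ sits one order
above rtol because the integrator legitimately overshoots the u = 1
equilibrium by a few parts in 10⁶ at the default tolerance.

### Empirical front speed

`measure_front_speed` builds a quasi-1D channel (n × 1 × 1, no-flux
walls), seeds the first 1 mm at u₀ = 0.5, and regresses the interpolated
threshold-contour position on time. Two numerical choices matter:

* the channel spacing is 0.025 mm — finer than the imaging grid — so the
  front width √(D/ρ) (≈ 46–550 µm over the published parameter range)
  stays resolved;
* fronts started from compact data approach c = 2√(Dρ) with a slowly
  decaying logarithmic (Bramson-type) transient, so the regression model
  is x(t) = c t + a ln t + b over the post-transient window (t ≥ 0.4 T)
  and c is reported. A plain linear slope would be biased low by several
  percent at these horizons.

Without growth (ρ = 0) there is no traveling wave; diffusion eventually
spreads the seed below the detection threshold and the visible front
vanishes. The measurement reports speed 0 in that case.

## Parameter estimation

(D, ρ) is estimated by derivative-free Nelder–Mead over (log D, log ρ) —
the log transform guarantees positivity at every evaluation — with the
initial simplex at ±20% multiplicative perturbations of the guess
(default D = 500 µm²/h, ρ = 0.02 1/h), convergence tolerances 10⁻³ on
both simplex size and error, and a cap of 300 evaluations. A failed
forward solve returns a large finite penalty instead of aborting the
simplex. The best point ever evaluated is returned, so a fit is never
worse than its initial guess, and identical inputs give bit-identical
results.

Three hypotheses about the time dependence of the dynamics:

1. **Constant parameters** — one pair fitted to all follow-up days,
   mean-mode error.
2. **Time-varying parameters** — sequential per-interval fits; the
   continuous (unthresholded) simulated field at each interval's end is
   carried forward as the next interval's initial state. The thresholded
   alternative would discard the sub-threshold invasion front, which is
   exactly the information the next interval needs.
3. **Time-varying parameters with observation resets** — as in 2, but
   each interval's initial condition is rebuilt from the *observed* mask
   at the interval's start (density u₀ inside, 0 outside); per-interval
   errors are scored on the predictions made before each reset. The
   reset density is u₀ = 0.5, consistent with the day-one
   initialisation; a variant that keeps the simulated densities on the
   observed support is available (`h3_reset="carry"`).

Sequential fits are conventionally summarised by the *sum* of their
per-interval errors, the whole-series fit by the *mean*; both are always
stored. Hypothesis comparisons ("percent decrease") divide a sequential
sum by the whole-series mean-mode baseline — a mixed-mode convention,
but the only one that reproduces the published 3.5%/18.8% (subject 1)
and 4%/20.3% (cross-subject average) improvements, so the reporting
module follows it and this note records the mix.

Truncated series (fits starting at a later imaging day, as needed when
early ventricle segmentations are unusable) are supported by slicing the
series before fitting.

## Identifiability

`compute_error_surface` evaluates the whole-series error at every node
of a (D, ρ) grid (independent evaluations, cached on inputs; per-node
failures become NaN). Along the arc ρ(D) = c²/(4D) the front speed is
constant, and the error surface typically shows a valley there.
`valley_flatness` quantifies this: the spread of E along the arc (bilinear
interpolation in log-parameter space) divided by the spread over the
whole grid, flagged "practically nonidentifiable" below 0.25. The 0.25
threshold is a package choice (config-exposed); the underlying finding
is qualitative.

Two grid constructors are provided. `default_grids` brackets the
published estimates (D 50–2000 µm²/h, ρ 0.005–0.06 1/h, log-spaced).
`valley_analysis_grids` mirrors how the published surfaces select their
parameter intervals: a narrow D interval inside the valley's flat
section (factor 1.25 around the reference estimate) against a wide ρ
interval (factor 4), which is the configuration that exhibits the
valley. On a noiseless self-consistent phantom the error at truth is
exactly 0 and the valley is much sharper than with real data — real
images carry an irreducible misfit floor (≈ 0.45 in the published fits)
that masks along-arc variation. Passing valley tests on the phantom
therefore demonstrates the *structure* (low-error set elongated along
constant c), not the magnitude of flatness seen in vivo.

## 2D level-set Stefan solver

In 2D the tumour is a region Ω₁ with a sharp interface: inside,
u obeys the Fisher–KPP equation with Dirichlet u = ū = 0.16 on the
interface; the interface moves with the Stefan condition
v·n = −(D/ū) ∇u·n, which follows from Darcy's law v = −µ∇p with
mobility µ = D and pressure p = ln u (log pressure admits arbitrarily
large stresses; equating µ with D avoids an extra parameter). The host
region obeys no-flux conditions on the brain and ventricle boundaries,
and host geometry can be replaced on later imaging days (mass-effect
emulation); the tumour is clipped out of newly placed ventricles at
each swap.

There is no single canonical discretisation for this moving-boundary
formulation, so the scheme here is the package's own, built from
standard components, each isolated behind an interface:

* φ is a signed distance function (negative inside), advected by
  φ_t + F|∇φ| = 0 with first-order Godunov upwinding under the CFL
  restriction dt ≤ 0.5 min(h)/max|F|;
* the interior density update is forward Euler on a flux-form stencil,
  with the interface Dirichlet condition imposed *at the zero crossing
  of φ* through linearly extrapolated ghost values on exterior
  neighbours (cut fractions below 0.3 are clamped; the diffusion step
  safety factor 0.28 covers the implied conductance amplification);
* the interface speed is evaluated at the φ = 0 crossing along each
  front pixel's outward normal with a second-order one-sided formula
  (u = ū on the interface plus two interior samples at spacing 1.25 h
  taken by bilinear interpolation), then extended to the grid by
  constant extrapolation along normals (nearest-front-pixel lookup);
* reinitialisation every 6 advection steps: exact Euclidean distance to
  the marching-squares zero contour in a ±4 h band (sub-pixel accurate,
  so repeated reinitialisation does not drift the front), Euclidean
  distance transform beyond the band. More frequent reinitialisation
  measurably drags wide fronts; less frequent lets |∇φ| drift — 6 is
  the balance point observed on the disk benchmarks.
* anisotropy: D may be a per-axis (Dx, Dy) pixel-field pair (diagonal
  mobility tensor); near the interface the density gradient is taken
  normal to the front, giving v = −(Dx n_x² + Dy n_y²)(∂u/∂n)/ū. A
  scalar D is the special case Dx = Dy and reproduces the isotropic
  path to rounding.

The initial state assigns u₀ to all tumour pixels and ū to the one-pixel
exterior ring: the threshold value is attained on the interface itself
(via the ghost values), not over a pixel-wide annulus — assigning ū to
the mask's boundary pixels instead measurably starves the initial
interface flux on coarse grids.

### Radial reference

`gliomafit.radial` integrates the same moving-boundary problem reduced
to polar coordinates on a fine fixed 1D grid (dr = 5–10 µm), with the
interface tracked continuously, a subcell Dirichlet ghost at the exact
interface position, and a second-order one-sided interface gradient. It
shares no code with the 2D solver and serves as the independent oracle
on disk benchmarks: the 2D interface radius agrees with it to within 2%
after 336 h for parameter sets spanning the published 2D magnitudes,
with the 2D pixel size chosen at roughly a third of the interface-layer
width √(D/ρ) (0.05–0.1 mm) so the density boundary layer stays resolved.
Sharper layers than ≈130 µm would need proportionally finer grids.

### 2D error and fitting

The 2D fit minimises E₂ = z_d + 10 Σ_t d_J,t, where z_d sums, over the
follow-up days, the RMS of the minimum distances from each simulated
boundary vertex to the data boundary polygon (exact point-to-segment
distances; deliberately one-directional, simulated → data, as the error
is defined), and the factor 10 puts the overlap term on the same order
as the boundary term. Boundaries are marching-squares contours of φ
(largest closed contour); regions are rasterised as {φ < 0}.

## Synthetic phantom

The phantom generator emulates the study conditions the pipeline was
built for: a mouse-scale ellipsoidal brain (semi-axes 2.3 × 2.3 × 3.7
mm) with two ellipsoidal ventricle cavities, rasterised voxel-centred on
a 48 × 48 × 16 grid at 0.1 × 0.1 × 0.5 mm spacing; a spherical day-11
seed of radius 0.55 mm (≈ 0.7 mm³, the sub-mm³ day-11 range measured in
vivo) at density 0.5; imaging days 11, 15, 18, 22, 25; detection
threshold 0.16. The default truth (D = 413.77 µm²/h, ρ = 0.0188 1/h) is
a published whole-series estimate and yields a day-25 volume of ≈ 23
mm³, inside the 12–62 mm³ range observed in vivo. Brain and ventricles
are ellipsoids because that is the simplest geometry with the features
the solver must respect (internal excluded cavities, curved no-flux
boundary); real anatomy, MR intensities, and partial-volume effects are
out of scope.

Optional realism knobs, all off by default and reproducible from
(seed, spec): independent voxel flips at probability p restricted to
each mask's one-voxel boundary shell (segmentation-noise emulation that
cannot destroy topology); ventricle drift in mm/day applied as
nearest-voxel integer shifts (exactly reversible); piecewise-constant
per-interval truth parameters.

The quadrant-structured random 2D diffusion field reproduces a published
anisotropic simulation setup whose half-plane prescription ("horizontal
direction on the left half…", base value η = 11120 µm²/h) is ambiguous
between a scalar and an axis-wise reading; both are implemented. The
axis-wise mode (Dx from the left/right-half horizontal intervals, Dy
from the top/bottom vertical intervals) is the default because the
bracketed per-half intervals hold exactly in it; the scalar quadrant
mode averages the bounds of the two governing half-plane intervals.

Because simulated "observations" and fitted forward runs share one code
path, a noiseless phantom yields fit error exactly 0 at the true
parameters — the end-to-end oracle the acceptance tests rely on. What
phantom tests do *not* show: performance under registration error, real
segmentation noise statistics, anatomy-driven growth asymmetry, or
mass-effect deformation beyond rigid ventricle shifts.

## Problem sizes and known limitations

Default problem sizes (48 × 48 × 16 voxel phantoms, 10 mm disk
benchmarks at 0.05–0.1 mm pixels, 15 × 15 error surfaces, 150-evaluation
fits) were chosen so each analysis runs in seconds to a couple of
minutes on a single core; all are configuration, not algorithmic limits.

Known limitations:

* Per-interval (Hypothesis 2/3) estimates from a single mask comparison
  are weakly constrained: on coarse masks many (D, ρ) pairs reproduce an
  interval's mask exactly (the Jaccard objective is piecewise constant),
  so per-interval recovery is only reliable when the tumour spans enough
  voxels — the piecewise-recovery test uses a 2.1 mm³ seed for this
  reason. This is the same practical nonidentifiability the surface
  analysis quantifies, concentrated in time.
* The wide-front corner of the parameter range (w = √(D/ρ) ≳ 0.5 mm
  combined with slow growth) can make a phantom's mask series exactly
  reproducible by a different (D, ρ), in which case the fitted front
  speed is genuinely unconstrained; the recovery suite is therefore
  judged on its median error.
* The 3D model is isotropic and uniform in D; tensor diffusion,
  density-dependent diffusion, and mechanical mass effect are not
  modelled. The 2D solver holds the scheme first-order accurate at the
  interface in time; its 2% radial-benchmark agreement is the measured,
  not the asymptotic, accuracy.
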