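# Methods

This note documents the models the package implements, the parameters that
matter, the numerical choices behind them, and what the synthetic fixtures
do and do not demonstrate.

## Physical setting and scope

During left-ventricular systole with a mitral paravalvular leak, the mitral
valve is closed and the aortic valve open; part of the stroke volume exits
through the aorta and part regurgitates through the leak channel into the
left atrium as a high-shear jet. Hemolysis is flagged by a threshold
criterion on the scalar effective shear stress: regions at or above a
critical stress `tau_c` (default 300 Pa) are considered at risk of
rupturing red blood cells. The threshold is a comparison device, not a
physiological constant — literature values span roughly 150–800 Pa
depending on exposure time, and the package exposes `tau_c` as a parameter
(the severity metrics are monotone in it, which the suite tests at 150,
300 and 400 Pa).

The package deliberately does **not** solve the flow. The RANS k–ω SST
solve, turbulence closure and moving-mesh solver coupling are upstream of
this artifact; the package consumes per-cell velocity-gradient fields and
turbulent viscosity from snapshot containers and produces everything
around them: boundary-condition waveforms, geometry, mesh kinematics,
stress post-processing, severity statistics and model comparison.

## Ventricular drivers

Systolic outflow is a parabola in time,

    Q(t) = -4 Qmax / tmax^2 (t - tmax/2)^2 + Qmax,

zero at the start and end of systole and peaking at `tmax/2`. Requiring
the integral over systole to equal the total ejected volume `dV` fixes
`Qmax = 3 dV / (2 tmax)`; the cumulative ejected volume has the closed
form `Qmax [t - 4/(3 tmax^2)((t - tmax/2)^3 + (tmax/2)^3)]`, used
everywhere instead of quadrature. Defaults: `tmax = 0.36 s` (systole at a
resting heart rate of 60 bpm); `dV` from the keyframe chamber volumes
(173,803 → 68,484 mm³ gives `Qmax = 4.388e-4 m³/s`).

Outlet pressures are trigonometric approximations of waveforms measured in
patients with a leak (the atrial c-wave is omitted). The atrial profile

    pLA(t) = 0.5 (pv - pa)(1 - cos(pi (t - ta)/(tmax - ta))) + pa

is applied over the whole systole: it is well defined for `t < ta` and
yields a physiological x-descent (minimum `pa_wave = 18 mmHg` at
`ta_wave = 0.2 s`) rising to the v-wave (`pv_wave = 38 mmHg`) at end
systole. The aortic profile is a two-branch cosine. Two deliberate
fidelity decisions here:

* the tabulated `pmax = 50` / `pmin = 110` mmHg contradict their names;
  the defaults keep the values exactly as tabulated, with a
  `swap_max_min` flag to exchange them rather than a silent correction;
* the two printed branches are discontinuous at `ta_wave` (branch 1 ends
  at `pmax`, branch 2 restarts at `pmin`). The default `as_printed` mode
  evaluates them verbatim; a `continuous` mode replaces the second branch
  by `0.5 (pmax - pmin)(1 + cos(pi (t - ta)/(tmax - ta))) + pmin`, which
  joins branch 1 at `ta_wave` and decays to `pmin` at `tmax`. The mode is
  recorded with the output, never inferred.

All pressures are handled in mmHg at the interface and converted with the
fixed factor 133.322 Pa/mmHg; all other computation is SI.

## Universal ventricle geometry

The simplified chamber is an axisymmetric body: an ellipsoid of revolution
of width `D` and height `H`, truncated at the height where its
cross-section width equals `d`, continued by a cylinder of diameter `d`
and height `h`, optionally rounded at the top edge by a circular fillet,
and closed by a flat disc. The generatrix is revolved on a structured
longitude × latitude grid (poles as single vertices), which is watertight
and consistently oriented by construction; enclosed volumes come from the
divergence theorem (`sum of det(v1,v2,v3)/6` over faces).

A closed composition of the published reference dimensions does not
reproduce the published chamber volumes (the analytic
ellipsoid-plus-cylinder volume for the diastolic dimensions is ~154,200
mm³ against a tabulated 172,865 mm³ — the published construction's
rounding rule is under-determined). The package therefore treats the
*target volume* as the binding contract: `solve_dims_for_volume` fixes
`d`, `h` and the aspect ratio `D/H` and root-finds the joint ellipsoid
scale (Brent, monotone bracket) until the meshed volume matches the
target, verified to 0.1% relative — far below the few-percent differences
the model comparison is designed to resolve. The fillet radius defaults to
0 and is configurable; it must fit within both `h` and `d/2`.

Leak channels are described by perimeter and cross-sectional area, with the
equivalent diameter implemented as the hydraulic diameter `4A/P` — the
only definition consistent with all tabulated values — and whole-leak
aggregates formed by summing perimeters and areas before re-forming
`4A/P`.

## Keyframe kinematics and volume matching

Ventricular motion is given by a small number of correspondent surface
keyframes (same vertex count and node identity; the correspondence is
produced upstream by diffeomorphic registration and is consumed here, not
computed). Each keyframe is assigned a morph parameter equal to its
normalised ejected-volume fraction `s_k = (V0 - Vk)/(V0 - Vlast)`; this
choice is geometry-intrinsic and reproducible from the volumes alone,
where a time-based assignment would import assumptions about contraction
timing. Node trajectories are straight lines for two keyframes and
per-coordinate cubic Hermite curves with Catmull–Rom tangents (one-sided
at the ends) for three or more: endpoint-exact, C1 in the interior, and
exactly linear when the data are linear in `s`.

At each of `n` uniform time steps the target volume is the initial volume
minus the closed-form cumulative ejection, and the morph parameter is
advanced by bracketed root-finding (Brent on `V(s) - V_target` with a
bisection fallback for locally non-monotone stretches) until the enclosed
volume matches to a relative accuracy of 1e-8. The accuracy is interpreted
as *relative*: an absolute 1e-8 m³ would be 10% of the whole chamber and
meaningless, while an absolute 1e-8 mm³ would chase floating-point noise
on a ~1e5 mm³ volume. The matcher never moves backwards in `s`; a target
above the current volume or below the final keyframe's volume is rejected
rather than extrapolated.

## Effective stress and rheology

The strain-rate tensor is the symmetric part of the velocity gradient,
`D_ij = (dv_i/dx_j + dv_j/dx_i)/2`, and the scalar shear rate is the
frame-invariant magnitude `gamma = sqrt(2 D_ij D_ij)`, which equals the
velocity gradient in simple shear (rotation invariance is property-tested
with random rotations). Blood viscosity follows the Carreau–Yasuda law
with constants `mu0 = 0.16 Pa·s`, `mu_inf = 0.0035 Pa·s`, `a = 0.64`,
`n = 0.2128`, `lambda = 8.2 s`; the effective stress is
`tau = (mu(gamma) + mu_t) gamma`, with the turbulent viscosity `mu_t`
taken from the snapshot (zero where absent). The isotropic
`-(2/3) rho k I` part of the eddy-viscosity Reynolds-stress closure does
not contribute to this scalar; turbulent kinetic energy `k` is carried
through the data model untouched. Wall shear stresses are taken as
provided by the upstream solver rather than re-derived from wall-adjacent
cells, and are left unchanged by the stress stage.

## Severity metrics

All threshold comparisons are inclusive (`tau >= tau_c`). On a continuum
the choice is measure-zero; on discrete data it matters, and the inclusive
form matches the definition of the critical-cell sum used for the mean
speed. Per snapshot:

* `V300` — sum of cell volumes with `tau >= tau_c`; with the sub-critical
  volume it partitions the fluid exactly.
* `A300` — sum of wall-face areas at/above threshold, restricted by
  default to the leak wall group `wall-pvl` (the area metrics describe the
  leak wall; the group filter is configurable, and unknown group names are
  rejected rather than silently matching nothing).
* stress maxima over all cells / selected faces, and volume-/area-weighted
  means over the critical subset only — reported as absent (NaN), not
  zero, when the subset is empty, so downstream comparison skips rather
  than averages them.
* `u_avg` — volume-weighted mean speed over critical cells; `t300 =
  cbrt(V300)/u_avg`, a cube-root length scale over a transport speed. It
  scales linearly under uniform spatial scaling, which the suite tests.

The analysis window defaults to 0.04–0.32 s of the 0.36 s systole,
excluding the valve opening/closing transients; endpoints are inclusive
and the window is configurable.

## Model comparison

Relative errors are always normalised by the reference run,
`eps(t) = 100 |X_var - X_ref| / |X_ref|`, with variant series resampled
onto the reference grid by linear interpolation when grids differ
(nearest-neighbour resampling is deliberately not offered). Summaries use
the population standard deviation: the time grid is fixed and the spread
is descriptive, not an inference about a sample. Timepoints where the
reference magnitude is below an absolute floor (default 1e-12 in SI
units) or a metric is absent are skipped *and counted*, so silent
truncation is impossible. The leak flow fraction is
`Q_pvl/(Q_pvl + Q_aorta)` with zero-total timepoints skipped and counted
the same way.

## Synthetic data: what it shows and what it does not

The generators produce fields whose stress structure is known in closed
form, so every downstream operator has an independent oracle:

* **Poiseuille pipe** (default: leak-sized, R = 1.8 mm) — exact ring-bin
  volumes, analytic velocities and gradients at area centroids, so the
  recovered stress profile is linear in radius to machine precision and
  the thresholded volume fraction has the closed form
  `1 - (tau_c/tau_wall)^2`. At the default 200 radial bins the 300/400
  threshold ratio falls exactly on a bin edge, making the 0.4375 fraction
  exact; the convergence of the fraction is first order in `1/n_r` in
  general. The wall stress target (400 Pa) is reached by back-computing
  the centreline speed, accepting an unphysical speed/viscosity pairing in
  exchange for oracle precision — physiological 300+ Pa stresses come from
  turbulence the package does not solve.
* **Gaussian jet** — a free-shear layer with shear-rate maxima at
  `y = ±sigma`, the qualitative structure of the regurgitant jet's
  high-stress shell.
* **Keyframes** — uniform scaling of a watertight base about its centroid
  hits requested volumes exactly (enclosed volume is exactly cubic in the
  scale) with perfect node correspondence by construction.
* **Synthetic study** — a reference run of Poiseuille snapshots on a
  15-point grid across the analysis window, with wall stress scaled by the
  instantaneous flow fraction `Q(t)/Qmax` so the severity series rises and
  falls with the drive, plus three variant series with documented uniform
  perturbations δ ∈ {0.005, 0.02, 0.04} spanning the sub-0.5% and sub-4%
  error regimes the comparison machinery must resolve. Variants are
  perturbed at the *series* level because a multiplicative perturbation of
  the stress field does not propagate as a uniform factor through a
  threshold (V300 is nonlinear in tau), and the fixture's purpose is a
  known ground-truth error. Everything is deterministic given the seed.

Passing on these fixtures demonstrates that the post-processing is
correct and self-consistent; it does not validate any turbulence model,
patient geometry, or absolute hemolysis magnitude. Quantities that depend
on the full 3-D unsteady solve on patient geometry — the published error
statistics between model variants, sub-millisecond residence times,
~380–395 Pa average critical stresses, 58–82 mL/s leak flows, near-5 m/s
peak jet velocities — are outside what desk-scale fixtures can reproduce
and are covered instead by the property suites and the end-to-end fixture
runs.

## Numerical choices and degenerate inputs

* Watertightness is checked by edge counting (every undirected edge shared
  by exactly two faces, every directed edge unique); violations report the
  offending edges. Inward-oriented closed surfaces are reoriented on read;
  an inward orientation passed directly to the volume routine is an error,
  not a sign convention.
* Root-finding tolerances: ellipsoid scale solved to `xtol = 1e-12` with a
  0.1% relative verification on the meshed volume; morph parameter solved
  to machine precision with a 1e-8 relative verification on volume.
* Defaults that matter: `rho = 1060 kg/m³`; threshold 300 Pa inclusive;
  window 0.04–0.32 s; wall group `wall-pvl` for area metrics; comparison
  floor 1e-12; STL coordinates in mm, field data in SI, with conversion
  only at the interfaces.
* Empty critical sets, zero-total-flow timepoints and all-skipped metrics
  produce absent values with warnings and counts, never exceptions, so
  time series with partially sub-threshold intervals summarise cleanly.

## Known limitations

* The snapshot container is the package's documented CSV/JSON directory
  format; solver-native formats must be exported to it.
* Severity metrics assume the provided cell decomposition is exact
  (volumes sum to the domain); no remeshing or interpolation between
  grids is performed at the snapshot level.
* The residence-time estimate is a scale argument, not particle tracking;
  damage-accumulation (power-law) hemolysis indices and population-balance
  models are out of scope.
* The atrial/aortic profiles are population-mean approximations; no
  patient-specific pressure calibration is provided.
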