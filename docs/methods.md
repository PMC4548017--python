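# Methods

## The model

`vjump` implements a planar two-state velocity-jump process with resting
states. An agent alternates between *runs* — straight-line motion at a
constant velocity — and *rests*, during which it is stationary but keeps
an orientation in memory. Three laws drive the process:

* the run-duration pdf `f_tau(t)`,
* the rest-duration pdf `f_omega(t)`,
* a separable turning kernel `T(v, v') = g(theta, theta') h(s) / s^{n-1}`,
  applied when a run begins: the new heading is the remembered heading
  plus a von Mises(0, kappa) turn, and the speed is redrawn from `h`.

Two scalar summaries of the turning kernel propagate into everything
downstream: the index of persistence `psi_d = I1(kappa)/I0(kappa)`
(the mean cosine of the turn angle; 0 for uniform reorientation) and the
mean squared speed of a fresh run, `S_T^2 = E[s^2]`.

Duration families supported analytically: exponential (rate `b`), gamma
(shape `k`, scale `theta`) and inverse Gaussian (mean `mu`, shape
`lambda_s`, variance `mu^3/lambda_s`). All three have closed-form Laplace
transforms; the inverse-Gaussian transform is
`exp((lambda_s/mu)(1 - sqrt(1 + 2 mu^2 lam / lambda_s)))` on the
principal branch, valid for `Re(lam) > -lambda_s / (2 mu^2)`.

## Delay kernels

Memory enters the governing transport equations through the delay kernel
of each duration law, defined in Laplace space by

    Phibar(lam) = lam * fbar(lam) / (1 - fbar(lam)).

Since `Phibar = lam * ubar` for the renewal density `u`, the time-domain
kernel splits into an impulse `c * delta(t)` with
`c = lim_{lam->inf} lam * fbar(lam)` plus a regular part
`Phi_reg = u'`. Consequences used throughout:

* exponential law: `Phibar ≡ rate`, so `Phi = rate * delta(t)` and the
  process is Markovian (the moment system degenerates to constant-
  coefficient ODEs);
* inverse Gaussian and gamma with shape >= 1: `c` is finite (0 except for
  shape exactly 1) and the regular part is obtained by numerical Laplace
  inversion of `Phibar - c`;
* gamma with shape < 1: `c` diverges (the renewal density blows up at 0).
  The moment solver refuses these laws with a pointed error; the
  stochastic simulator and the effective-diffusion formula handle them
  fine, which is how the high-variance benchmark scenarios are evaluated.

Small-lambda kernel moments, used by the diffusion formula and asserted
as invariants: `Phibar(0) = 1/mu` and
`Phibar'(0) = (sigma^2/mu^2 - 1)/2`.

### Numerical Laplace inversion

Two classic fixed-contour schemes are implemented and cross-checked
against each other to 1e-6 on smooth transforms:

* **fixed Talbot** (default 32 nodes): cotangent-spiral contour, scale
  `r = 2M/(5t)`; retains full relative accuracy down to very small `t`;
* **Euler** (default 18 terms + 15-term Euler averaging, `A = 18.4`):
  vertical contour `Re(lam) = A/(2t)`; discretisation error `O(e^-A)`,
  but an *absolute*-error floor of order `e^{A/2}/t * |F|` appears at
  small `t` where the sum cancels.

Kernel grids are therefore tabulated with Talbot; the Laplace-space
moment solver inverts with the Euler scheme, whose contour stays in the
right half-plane (safe for the inverse-Gaussian branch cut). Round-trip
accuracy (transform → invert → pdf) is 1e-6 relative or better for all
families with bounded density at 0.

## The MSD moment system

Projecting the transport equations onto the test functions
`1, ||x||^2, v.x, ||v||^2` yields eight coupled Volterra
integro-differential equations for `N_p, N_r, D_p^2, D_r^2, B_p, B_r,
V_p^2, V_r^2` (particle number, displacement second moment,
velocity-displacement correlation and velocity second moment, per
state). The observable is the per-capita MSD `(D_p^2 + D_r^2)/N_0`. The
run-kernel convolutions carry `(t-s)` and `(t-s)^2` weights arising from
the spatial delays.

**Time-domain solver.** Uniform grid; history convolutions by the
trapezoidal rule over tabulated kernels (`t^k`-weighted grids are
tabulated once per solve, giving an `O(N^2)` total cost); differential
operators by Crank-Nicolson. Both ingredients are second-order, and the
observed error against an exact oracle scales as `O(dt^2)`. The impulse
component of each kernel contributes its full weight at the current-time
endpoint; with exponential kernels this makes the scheme an exact
Crank-Nicolson discretisation of the Markovian ODE system, which is the
first correctness oracle (matrix exponential, agreement ~1e-7 at
`dt = 1e-3`). Default `dt` is chosen so the shorter of the two mean
durations spans at least 50 steps.

Initial conditions: `N_p(0)`, `N_r(0)` as given; all series zero except
`V_p^2(0) = S_T^2 * N_p(0)` — the value consistent with agents that
start mid-run carrying a typical squared speed (an override is
provided). No pre-`t=0` history is modelled.

**Laplace-space solver.** An independent oracle sharing no stepping
code: the transformed system is block lower-triangular (N → V → B → D
pairs of 2x2 solves, using closed-form `Phibar`, `Phibar'`, `Phibar''`),
inverted numerically at each output time. The two solvers agree to
better than 1e-3 (relative to each series' scale) for exponential and
inverse-Gaussian kernels; this is the only validation route for the
non-Markovian case.

## Effective diffusion

At large times the MSD grows linearly and the density approaches a
planar heat kernel with

    D_eff = (S_T^2 / n) * mu_tau^2 / (mu_tau + mu_omega)
            * [ 1/(1 - psi_d) + (sigma_tau^2 / mu_tau^2 - 1) / 2 ],

the bracket being a Markovian term plus a non-Markovian correction that
vanishes for exponential runs. Only the *mean* of the rest law enters.
The MSD slope is `2 n D_eff`. Checked behaviours: strict monotonicity in
`sigma_tau^2` and `psi_d`; invariance to the rest-law shape at fixed
mean; the degeneracy of an exponential(1) run law and a Gamma(1/5, 5/2)
run law both giving `D_eff = 1/4` at unit speed.

A caution surfaced by the solver: with the bacterial parameter set
(exponential runs at 2.30/s, rests at 11.98/s, `psi_d = 0.46`,
`S_T^2 = 9.26`), the least-squares MSD slope over the window 3–4 s is
12.246 (um)^2/s, still 2.0% below the asymptotic `2 n D_eff = 12.51`:
the slow eigenmode of the velocity-correlation block (rate ≈ 1.13/s) has
not fully decayed. Over 8–10 s the slope matches the closed form to
0.2%. Quoted "diffusive-regime" slopes at ~4 s are therefore approximate
at the 2% level — a property of the model, not of the discretisation.

## Stochastic simulator

A Gillespie-style sampler draws alternating durations, truncates the
final phase at `T_end`, and applies the turning kernel at each
rest-to-run transition (the orientation persists through the rest).
Initial conditions: state split by a configurable run fraction, uniform
initial heading, speed drawn fresh. Two surfaces: `simulate_path`
(explicit phase list per agent) and a vectorised ensemble engine that
advances all agents phase-by-phase in lockstep and deposits
displacements onto an output time grid — 3e4 agents over 100 mean-phase
times cost under a second, which is what makes the ensemble comparisons
routine test material. Identical seed and configuration reproduce
ensembles bit for bit.

Benchmark ensembles (unit speed, unit mean durations, no persistence) are
compared with theory at `t = 100`: the exponential/exponential case
matches the moment-solver MSD within 3 Monte-Carlo standard errors at
every grid time and its `y = 0` cross-section passes a chi-square test
against the `D_eff = 1/4` heat kernel at alpha = 0.01 (20 bins over
±3.5 sigma, strip half-width 2). The gamma-run cases relax to their
diffusion limits much more slowly — the non-Markovian correction
dominates their `D_eff` — so a chi-square test still rejects at 3e4
paths; their checks instead bound the central density-profile deviation
by 0.20 (Gamma(1/5, 5/2) runs, `D_eff = 1/4`) and 0.35 (Gamma(1/7, 7)
runs, `D_eff = 1`) of the peak, versus 0.10 for the exponential case.
Those two bands were calibrated once on these study conditions and are
deliberately coarse: they encode "same diffusion scale, visibly slower
relaxation", nothing sharper.

## Parameter extraction

**Labelled tracks** (t, x, y, state): phase boundaries are placed midway
between the samples flanking each state change; per-run speed uses the
displacement over the *sampled span* (the velocity is constant within a
run, so this avoids boundary-placement bias); turn angles are taken only
between runs separated by exactly one rest.

**GPS tracks** (timestamp, lat, lon): a two-stage segmentation.

1. *Coarse detection*: the diameter (max pairwise great-circle distance,
   equivalent to the convex-hull diameter) of all fixes in a centred
   24 h window, sampled 10 times a day on a midnight-aligned grid kept
   half a window inside the record; rest where the signal is below
   52 km. Rests shorter than 2 days are relabelled as run; runs that
   absorb such a rest are flagged `merged`.
2. *Boundary refinement*: a centred window first crosses the threshold
   up to half a window before movement actually starts, so each coarse
   boundary is relocated to the first (or last) inter-fix step whose
   displacement exceeds the threshold pro-rated to the fix interval,
   positioned within that step using the local migration speed. This
   removes a ~0.3 day/side widening of runs that would otherwise bias
   run durations by tens of percent at gull-like parameters.

Distances use the haversine formula with Earth radius 6371 km; headings
use initial great-circle bearings. Default thresholds (24 h window, 10
samples/day, 52 km, 2-day minimum rest) are the field-calibrated values
for migratory-gull telemetry; the window alignment and refinement rules
are validated against synthetic tracks with known ground truth, not
against any published prescription.

**Fitting.** Von Mises concentration by MLE with the mean angle fixed at
0 (solve `I1(k)/I0(k) = mean cos`, bracketed root-finding, capped at
1e3). Duration laws by MLE per family, with two structural corrections
available and used by the recovery pipelines:

* *Right-censoring of record-boundary phases*: the final (and, for
  records that begin mid-phase, the first) phase is an incomplete
  observation; including it as a survival term removes the
  finite-window inspection bias (complete-phases-only averaging is
  biased low by roughly one mean cycle per record length — 5% for the
  bacterial fixtures, more for gull rests). For the synthetic fixtures
  the leading phase starts fresh at `t = 0` and is kept as complete
  (`censor_ends="last"`).
* *Left truncation*: rests below the minimum-rest rule and runs below
  the detection limit (threshold distance / typical migration speed,
  ≈ 0.17 d for gull-like parameters) are unobservable by construction;
  the likelihood conditions on exceeding these points. Exponential
  truncation/censoring has closed forms (events over exposure);
  inverse-Gaussian variants are maximised numerically (Nelder-Mead on
  log parameters); the gamma fit (scipy MLE) supports neither.

`S_T^2` is the mean of squared per-run speeds; merged runs contribute
neither speeds nor headings (their values would conflate several phases
and a rest). The initial state of a record is the state at `t = 0`
regardless of phase age.

End-to-end recovery on synthetic data: 2000 bacterial-scale labelled
tracks recover both exponential rates within 5% and kappa, `S_T^2`
within 10%; 200 gull-scale GPS tracks (180 days each, 10 fixes/day,
0.5 km jitter) recover both inverse-Gaussian parameter pairs, kappa and
`S_T^2` within 10% and the implied `D_eff` within 15%.

## Synthetic scenarios

The fixtures module is the package's only data source; the two
field-calibrated scenarios lock the published summary parameters of the
systems they emulate (bacterial: exponential 2.30/s runs, 11.98/s rests,
`psi_d = 0.46`, `S_T^2 = 9.26` (um)^2/s, initial run fraction 66/1868,
10 s tracks sampled at 2 ms; gull: IG(1.26, 1.22) runs, IG(10.79, 7.42)
rests, `psi_d = 0.42`, `S_T^2 = 1.03e5` km^2/day, initial run fraction
6/62, 180-day tracks at 10 fixes/day). Speed laws are lognormal with the
prescribed mean square and log-sd 0.25 — the sources report only
`S_T^2`, which is the sole property the theory consumes; the benchmark
scenarios use fixed unit speed. GPS tracks are generated as genuine
great-circle motion on the sphere (runs advance along geodesics, turns
apply to the transported bearing), so the generating durations, speeds
and angles are exact ground truth with no projection distortion;
Gaussian fix jitter is optional. Real-data features deliberately not
emulated: coastlines and geography, day-night cycles, wind, GPS outages,
state-annotation errors in the labelled tracks. Passing recovery tests
therefore demonstrates correctness of the estimators under the model's
own assumptions, not robustness to those field effects.

## Problem sizes and numerical defaults

Chosen as the package's standard configurations: moment solves use
`dt = 1e-3` s over 4–10 s (bacterial) and `dt = 0.02` d over 120–160 d
(gull); ensemble comparisons use 3e4 paths; recovery uses 2000 labelled
and 200 GPS tracks. Inversion defaults: Talbot 32 nodes, Euler 18+15
terms. Root-finding tolerances 1e-8; kernel-pole guard 1e-13.

## Known limitations

* Gamma run/rest laws with shape < 1 are simulator-only (divergent
  kernel impulse); gamma laws with shape in (1, 2) have an integrable
  kernel singularity at 0 that the grid truncates (a warning is issued).
* Heavy-tailed laws with infinite variance are out of scope (the
  diffusion formula requires the first two run moments).
* The moment system's small-time behaviour for non-exponential kernels
  carries no analytic reference here; it is validated only through the
  Laplace-domain cross-check and simulation.
* Segmentation assumes rests are spatially tight on the threshold scale;
  a "rest" with local excursions beyond ~52 km/day would be labelled
  migration.
* Dimension is fixed to n = 2 everywhere except the explicit `n` in the
  diffusion formula; `psi_d = I1/I0` is the planar relation only.
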