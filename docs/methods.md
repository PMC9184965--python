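# Methods

This document defines the models implemented in `waddyn`, the numerical
choices behind each module, the scope of the synthetic data used in examples
and tests, and known limitations.

## Dynamical model

A cell's state is a point `x ∈ ℝ²` moving by overdamped, noisy gradient
dynamics on a smooth potential `F(x, θ)`:

```
dx = −G(x)⁻¹ ∇F(x, θ(t)) dt + σ dW
```

* `θ` is a low-dimensional signal/unfolding parameter, possibly
  time-dependent (`SignalPath`: piecewise-linear interpolation in `t`,
  clamped outside the knot range) and possibly per-cell;
* `G(x)` is a symmetric positive definite *metric* (`RiemannianMetric`;
  currently constant matrices, validated for symmetry and positive
  definiteness). Because `dF/dt = −∇F·G⁻¹∇F ≤ 0`, `F` is a Lyapunov function
  for every admissible metric: metrics can redirect saddle connections but
  never move rest points or change their Morse indices;
* `σ dW` is isotropic additive white noise.

Rest points with Morse index 0 are attractors (cell fates), index-1 saddles
are decision points. Under parameter variation, generic one-parameter events
are of exactly two types: **rest-point collisions** (fold bifurcations,
`det ∇²F = 0` at a rest point) and **connection changes** (flips, where a
saddle's unstable-manifold branch switches its destination attractor).

## Landscape catalogue (`waddyn.families`)

All families expose exact closed-form potential, gradient and Hessian
(batched over points), a phase-space `domain_box` and a parameter `param_box`.

| family | potential | notes |
|---|---|---|
| `elliptic_umbilic` | `x³ − 2xy² − 0.4x² + ax + by + (x⁴+y⁴)/4` | compactified binary-flip landscape; the quartic confines the cubic germ. Parameters `(a,b) ∈ [−3,3]²`, domain `[−6,6]²`. |
| `box2_example` | same with `a=−3, b=−1` frozen | zero-parameter worked example whose central saddle connection is metric-dependent. |
| `flip_with_cusp` | same potential, window `a ∈ [−0.5,0.3]`, `b ∈ [−0.2,0.2]` | contains the closed fold loop with its cusps and the flip along `b = 0`. |
| `cusp1d` | `x⁴/4 + a x²/2 + bx + y²/2` | standard cusp; fold locus exactly `4a³ + 27b² = 0`, bistable inside. |
| `dual_cusp1d` | `x⁶/6 − x⁴/4 + a x²/2 + bx + y²/2` | dual cusp (reversed quartic sign) with sextic confinement; tristable between the fold curves. |

Gradients and Hessians are unit-tested against central finite differences,
and the confinement terms are tested directly (outward gradient and growing
potential far from the origin).

## Flow integration (`waddyn.flow`)

* Deterministic trajectories use `scipy.integrate.solve_ivp` (RK45) on the
  metric gradient field, with event-based termination when the speed drops
  below a convergence threshold and when the state leaves a doubled domain
  box (flags `converged` / `escaped_domain` / `max_time`).
* Stochastic simulation uses Euler–Maruyama with a fixed step `dt`; noise is
  added *after* the drift step so the noise stream depends only on the seed
  and the iteration count, not on the drift.
* `relax_batch` settles a batch of points deterministically (vectorized
  explicit Euler with adaptive freezing of converged points); it accepts
  either one parameter vector or one per point, which lets heterogeneous
  populations be relaxed in a single call.

## Rest points and decision structure (`waddyn.geometry`)

* `find_rest_points` seeds a damped Newton iteration on `∇F` from a dense
  grid over the domain box, deduplicates converged roots, and classifies each
  by the eigenvalues of `∇²F` (attractor / `saddle1` / repeller; degenerate
  Hessians are reported, not silently classified). The metric is irrelevant
  here by construction and this invariance is tested.
* `unstable_manifold` integrates both branches of an index-1 saddle from
  `position ± ε·u`, where `u` is the unstable eigenvector of the *linearized
  metric flow* `−G⁻¹∇²F` (this is where the metric enters), and labels each
  branch's destination attractor.
* `decision_graph` assembles attractor nodes and saddle-mediated edges into
  an undirected multigraph; `basin_of` classifies initial conditions, with
  points on basin boundaries reported as `undecidable` rather than assigned.

## Bifurcation atlas (`waddyn.bifurcation`)

* **Fold curves** are traced by pseudo-arclength continuation on the extended
  system `{∇F = 0, det ∇²F = 0}` in `(x, θ)`, with Newton correction at each
  step and closure detection. The traced cusp fold locus reproduces the
  analytic discriminant `4a³ + 27b² = 0` to `1e-5` pointwise.
* **Cusps** are detected as direction reversals of the fold curve in
  parameter space and classified `standard` vs `dual` by the sign of the
  quartic normal-form coefficient along the degenerate direction (standard:
  two extra rest points appear *inside* the cuspidal wedge; dual: the wedge
  interior is tristable).
* **Flips** are located by bisection on a path in `θ`: a saddle branch is
  tracked continuously and the bisection narrows the parameter where its
  destination attractor changes. Fold interference (the tracked saddle or its
  destinations colliding) raises a dedicated error rather than returning a
  spurious flip. Located flips are verified by re-tracking on both sides.
* `build_atlas` combines fold tracing from grid-detected seeds, cusp
  detection, flip tracing between adjacent grid cells with equal rest-point
  counts but different connections, and labels the complementary regions by
  attractor count. The atlas of the compactified elliptic umbilic contains
  exactly the two mechanism types (`rest_point_collision`,
  `connection_change`).

## Topology census (`waddyn.census`)

Fate topologies (attractors as vertices, saddle connections as edges) are
enumerated as connected simple graphs up to isomorphism by an ascending
orbit-marking sweep with exact canonical certificates (minimum edge bitmask
over all vertex permutations). Counts for `n = 1…6` are `1, 1, 2, 6, 21,
112` (connected) and `1, 2, 4, 11, 34, 156` (all). The test suite checks the
enumeration against an independent brute-force oracle that canonicalizes by
the *maximum* bitmask — a different rule computed by different code — for
`n = 1…6`, and against `networkx` isomorphism for small `n`. The hard limit
is `n = 7` (exhaustive enumeration beyond that is not attempted).

## Population simulation (`waddyn.cellpop`, `waddyn.scenarios`)

* `simulate_population` runs one Euler–Maruyama batch per condition with a
  per-condition child seed (`numpy.random.SeedSequence` spawn keyed by
  condition index), so a condition's results do not depend on which other
  conditions run alongside it.
* Fate labeling: recorded states are relaxed deterministically (coarse
  settings: `dt = 0.3`, `v_tol = 1e-5`, step cap 0.1 — benchmarked to agree
  with the fine default relaxation on post-noise states), then accepted as an
  attractor only if the gradient norm is `< 1e-4` *and* the Hessian is
  positive definite; anything else is labelled `undecided`. Names are issued
  by a `FateRegistry` keyed on attractor position (radius 0.75), which can be
  pre-seeded so fate names align across runs and conditions.
* `waddyn.scenarios` packages three protocols used throughout the docs,
  tests and acceptance script: the *commitment ramp* (drive `a: −2 → −6`
  through the progenitor-destroying fold at fixed offset `b`), the
  *signal-sensitivity fit* scenario (conditions with `b = b₀ + b₁·s` for
  signal levels `s ∈ {−1, 0, 1}`), and the *positional pulse* (per-cell
  trapezoidal pulse on the dual-cusp tilt; fates recorded 20 time units after
  the signal returns to baseline persist because the return path crosses no
  fold for the new fate).

## Likelihood-free fitting (`waddyn.abc`)

Sequential ABC (ABC-SMC) with:

* summary statistic: fate-proportion tables per (condition, time, fate);
* distance: mean absolute proportion difference over the union of fate keys
  within shared (condition, time) groups; a fate absent from one table counts
  as proportion 0, while a *group* absent from one table is an alignment
  error (infinite distance inside the sampler, a raised `AlignmentError` when
  called directly);
* generation 0 samples the prior (uniform box, `PriorSpec`); later
  generations use the 0.3-quantile of the previous accepted distances as the
  tolerance, a Gaussian perturbation kernel with twice the weighted empirical
  variance, and standard importance weights;
* per-simulation seeds derive from `SeedSequence((seed, 1, counter))`, so
  runs are reproducible and particles never share noise;
* the sampler stops early (status `early_stop`, last completed generation
  returned) if acceptance collapses below `1e-3` or all distances are
  infinite.

The recovery benchmark (checked end-to-end in the test suite) uses the
*well-choice* scenario (`waddyn.scenarios.well_choice_simulator`): cells
start at the saddle of the symmetric double well and the tilt
`b = b₀ + b₁·s` biases which well they fall into. At σ = 0.4 the committed
fraction responds smoothly — close to linearly — to `b` over the whole prior
box `|b| ≤ 0.3`, so both parameters are well identified at the sampler
budget (200 particles, 4 generations); the posterior mean recovers the
generating `(b₀, b₁) = (0.05, 0.15)` within a tenth of the prior width
across seeds.

The commitment-ramp scenario was tried first for this benchmark and
deliberately rejected — a finding worth recording. Its dose–response is
switch-like (a step of width `|b| ≲ 0.05` at every noise level tried, σ =
0.25–0.55: commitment is decided in a short window around the fold crossing,
so extra noise barely broadens the step). Two consequences follow: accepted
particles on the flat shoulders bias the posterior mean whenever a probed
offset leaves the step, and the quantile tolerance schedule descends slowly
because most of the prior produces near-constant (saturated) distances. The
achievable tolerance is additionally floored by the simulator's own sampling
noise, `≈ √(p(1−p)/n_cells)` per condition. Fitting the ramp scenario to
better than ~0.05 in the offset parameters would need more generations or
substantially more cells per simulation than the benchmark budget allows.

## Expression signatures (`waddyn.signatures`)

Pearson gene–gene and cell–cell correlation summaries over an
`ExpressionMatrix` (cells × genes). Zero-variance genes/cells are excluded
and reported rather than producing NaNs silently; `transition_report`
summarizes per-group correlation structure (cells in transit along a
low-dimensional path show high mean |gene–gene| correlation; settled
isotropic populations do not). These are descriptive statistics only — no
claim about real transcriptomes is made or tested here.

## Configs and CLI (`waddyn.config`, `waddyn.cli`)

Configs are strict YAML/JSON: unknown keys are rejected with their full path
(`conditions[0].tgrid`), required keys are checked, and round trips are
lossless. The `waddyn` CLI exposes rest points, decision graphs, atlas
construction, population simulation, topology enumeration, ABC fitting and
signature reports; every artifact carries a `.meta.json` sidecar with the
seed, package version and the generating config.

## Synthetic data scope

All data in this repository are synthetic: populations are simulated from
the catalogue landscapes above, observation noise is multinomial resampling
of simulated fate proportions (`synth_dataset`), and expression matrices in
tests are generated from explicit low-dimensional constructions. No
biological dataset is bundled or required, and no empirical claims about any
organism are made.

## Numerical choices and limitations

* Phase space is two-dimensional throughout; families with more state
  dimensions are out of scope.
* Metrics are constant matrices; position-dependent metrics are accepted by
  the vector-field code path but not exercised elsewhere.
* The SDE integrator is fixed-step Euler–Maruyama; `dt` must resolve the
  fastest landscape curvature (the tests use `dt ≤ 0.02` on the catalogue
  families). Committed-fate proportions are insensitive to halving `dt` in
  the scenarios used here, but this should be re-checked for new landscapes.
* Fold tracing and flip location assume generic (codimension-one) crossings;
  tangencies of the sampled path with a fold curve can be missed at coarse
  atlas resolutions. Increase `resolution` or decrease the continuation step
  if curves look truncated.
* Rest-point finding is grid-seeded Newton; rest points hiding between grid
  seeds at very small basins can in principle be missed (the default grid is
  dense enough for the catalogue families, verified against Poincaré–Hopf
  index counts in the tests).
* `enumerate_topologies` is exact but exhaustive (limit `n = 7`).
* ABC posteriors are approximations controlled by the tolerance schedule and
  particle count; the defaults (200 particles, 4 generations, 0.3 quantile)
  are chosen for the bundled scenarios, not universal.
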