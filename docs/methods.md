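# Methods

## Problem

Fish sense their surroundings partly through pressure signals along the
lateral line. Pressure cannot be measured optically, but time-resolved 2D PIV
gives the velocity field around a swimming body. `pivpressure` reconstructs
the instantaneous pressure field — including the pressure directly on the
moving, deforming body surface — from such velocity series, and compares the
physics-informed reconstruction against the two classical approaches
(pressure-Poisson solve and multi-directional pressure-gradient integration).

## The physics-informed reconstruction

A fully connected network maps non-dimensional coordinates `(x, y, t)` to
`(u, v, p)`. Training minimizes

```
L = λ_data · L_data + λ_ic · L_ic + λ_bc · L_bc + λ_eq · L_eq
```

* `L_data` — mean-square mismatch between predicted and measured `(u, v)` at
  valid grid nodes (nodes inside or on the body contour are removed first,
  as their PIV vectors are unreliable).
* `L_eq` — mean-square residual of the non-dimensional 2D momentum equations,

  `r_x = St·u_t + u·u_x + v·u_y + p_x − (u_xx + u_yy)/Re` (and the y
  counterpart), evaluated with *exact* derivatives of the network at
  collocation points. `St = L/(U·T)` is 1 whenever the characteristic time is
  the convective time; it differs from 1 only when the time scale is set by
  something else (e.g. a turning maneuver's duration). The continuity
  residual `u_x + v_y` is optional and off by default: a 2D slice of a 3D
  flow is not divergence-free. It should be switched on for genuinely 2D
  flows (we do so for the Taylor-Green benchmark).
* `L_bc` — boundary terms: non-penetration on the body
  (`mean (u·n − u_n)²` over sampled contour points), zero pressure
  (`mean p²`) and/or inlet velocity on selected external edges. Edges with
  uncertain conditions (e.g. a wake outlet) simply get no term.
* `L_ic` — an initial-condition term of the same mean-square form, supported
  for completeness but disabled by default (weight 0).

Default weights are `λ_data = λ_bc = 100`, `λ_ic = 0`, `λ_eq = 1`.

**Gauge.** Only pressure gradients are constrained unless a zero-pressure
edge term is active, so the predicted pressure carries a free additive
constant per time instant. Predictions are returned either anchored by the
trained zero-pressure edges (`zero_at_boundary`) or re-gauged to zero spatial
mean per time step (`zero_mean`); comparisons between differently gauged
fields must remove the gauge first. The test suite verifies the gauge
freedom explicitly (shifting the network's pressure output changes no active
loss term when no pressure boundary term is used).

### Network

Hidden layers apply a weight matrix, bias and a per-neuron trainable gain
("gamma") before the activation, `z' = σ(g ⊙ (W z + b))`; the gain can be
disabled, giving plain affine layers. The full-scale architecture is 12
hidden layers × 120 sigmoid neurons. Inputs are affinely normalized to
[−1, 1] per coordinate using the training-domain bounds (recorded in the
config, so evaluation outside the domain is well-defined). An optional random
Fourier input embedding exists for localized flows but is off in every
preset: in our experiments it destabilized the momentum-residual optimization
more than it helped.

### Differentiation and optimization

No external autodiff framework is used. The package carries a compact
vectorized reverse-mode engine (`pivpressure.autodiff`): forward passes
propagate first derivatives with respect to `(x, y, t)` and pure second
derivatives with respect to `x` and `y` as extra channels built from taped
tensor operations, so that reverse mode differentiates the residual loss —
which itself contains network derivatives — with respect to the parameters
exactly. The correctness of every derivative entering the residuals is
checked against central finite differences of the network in the test suite
(1e-5 relative at random probe points).

Training is ADAM (β₁ = 0.9, β₂ = 0.999) over mini-batches: one epoch is a
full pass over the data points; collocation and boundary points are sampled
in independent shuffled cycles, each capped at the mini-batch size
(full-scale default 10,000). The learning rate defaults to 1e-3 halved every
500 epochs, full-scale training runs 1500 epochs. An optional deterministic
L-BFGS refinement phase on fixed, seed-drawn batches follows the ADAM phase;
this is standard practice for physics-informed training (the stochastic
phase finds the basin, the quasi-Newton phase converges tightly within it)
and in our CPU-scale experiments it reduced both the final loss and its
seed-to-seed spread substantially. Everything is reproducible from
`(parameter_init_seed, sampling_seed)`; training can checkpoint and resume
bit-identically. A non-finite loss aborts with a diagnostic rather than
continuing.

### Desk-scale presets

Full-scale settings (12×120, 1500 epochs, batch 10,000) are the library
defaults but are accelerator-sized. Two CPU presets ship with the package
and are used by the tests and the acceptance script:

| preset | network | ADAM | L-BFGS | use |
|---|---|---|---|---|
| `DESK_*` | 4×64 tanh | 1200 steps (240 epochs × 5), lr 2e-3 ×0.5/100 ep | ≤500 steps | single benchmark case |
| `SWEEP_*` | 3×32 tanh | ≤100 epochs, lr 2e-3 ×0.5/40 ep | ≤400 steps | one training per sweep cell |

The tanh activation optimizes faster than sigmoid at these small sizes;
both are supported.

### Collocation points

Momentum residuals are evaluated on the finest grid available even when the
velocity measurements are coarser — this is what makes the method
resolution-insensitive. `evaluation.collocation_points` additionally
oversamples (×4) nodes within 0.15 L of the body contour: the pressure
signal of interest is concentrated there, while most of the domain is
near-free-stream and cheap to satisfy.

## Classical baselines

Both start from the momentum-derived pressure gradient
`∇p = −(u_t + (u·∇)u) + ∇²u/Re` (second-order central differences; one-sided
second-order time stencils at the series ends; the gradient is flagged
undefined where the stencil touches a masked node).

* **Pressure-Poisson**: five-point Laplacian solve of `∇²p = ∇·(∇p_mom)`,
  with either zero-Dirichlet edges or second-order Neumann closures (mirror
  ghost) from the momentum gradient; fluid nodes adjacent to the body get the
  same Neumann closure. All-Neumann systems are pinned and re-gauged to zero
  mean.
* **Multi-directional integration**: straight rays from the external
  boundary to every node (default 8 directions), trapezoid integration of
  the bilinearly interpolated gradient, median aggregation. Rays crossing
  the body interior are discarded (paths terminate before the fluid-body
  interface). Surface pressure is then *extrapolated* from the nearest valid
  grid node — the extrapolation distance is reported, since it grows with
  grid spacing and drives the baseline's error at coarse resolution.

**Boundary reference.** The widely used convention pins p = 0 on all
external boundaries, which is inconsistent whenever the true boundary
pressure is non-uniform (e.g. a wake crossing the outlet) and breaks exact
path-independence even for manufactured fields. Our default instead
integrates the gradient once around the perimeter from a single
zero-pressure reference corner and starts each ray from that integrated
boundary value; the strict zero-everywhere convention remains available via
`IntegrationOptions(zero_boundary=True)`. With the integrated reference, a
constant-gradient field is recovered exactly (all rays agree to round-off)
and the Taylor-Green error converges at second order in grid spacing.

## Synthetic truth flows

No suitable public dataset pairs time-resolved 2D velocity fields around a
deforming body with ground-truth pressure, so validation uses analytic
flows whose pressure is exact:

* **Taylor-Green vortex** (`u = −cos x sin y e^{−2t/Re}`, …) with its
  closed-form pressure, zero-mean per time step. The standard benchmark for
  pressure solvers; used for the PINN recovery check and the baseline
  convergence studies.
* **Carangiform swimmer surrogate**: point doublets riding on an undulating
  midline in a uniform free stream. The midline follows
  `Δy/L = A(x) sin(kx − 2πft + φ)` with amplitude envelope
  `A(x) = a₀ + a₁(x/L) + a₂(x/L)²` (defaults a₀ = 0.02, a₁ = −0.08,
  a₂ = 0.16, k = 2π/L — a literature-standard mackerel-style prescription).
  A potential velocity field is harmonic, hence an exact Navier-Stokes
  solution at any Reynolds number, and its pressure is the unsteady
  Bernoulli relation `p = ½U∞² − φ_t − ½|u|²` — an exact oracle for surface
  pressure around a moving body.

  Surrogate design choices that matter:
  - the body contour is midline ± half-width with the smooth profile
    `w(x̂) = 0.35 x̂ (1−x̂)` (max half-width 0.0875 L, fusiform);
  - doublets (default 4) sit on the mid-body only (25–75% of the length),
    where the body is thick: a singularity close beneath a thin nose or tail
    produces near-singular surface pressure no method could recover from
    exterior data;
  - the drawn contour is *not* a stream surface of the doublet flow, so the
    kinematics returned with the surrogate carry flow-consistent surface
    velocities (the flow sampled at the contour) rather than the contour's
    material velocity — the role silhouette-derived normal velocity plays
    for experimental data. The purely kinematic generator
    (`carangiform_kinematics`), used for geometry and masking tests, keeps
    the analytic material velocity `∂(Δy)/∂t`.

  The default evaluation window is a 1.5 L × 0.7 L field of view at 0.02 L
  spacing, 11 snapshots at 0.02 T (a fifth of a tail beat) — PIV-realistic
  resolution at desk-scale cost.

What the surrogate does **not** emulate: boundary layers and flow separation
(potential flow is inviscid in character even though it solves the viscous
equations), three-dimensional wake effects (a stated error source for real
mid-plane slices), and a true no-slip body. Passing the sweep tests
therefore demonstrates the *relative* resolution robustness of the methods
on an exact unsteady truth, not absolute accuracy on a real fish.

**Degradation operators** emulate measurement limitations: pure subsampling
(integer strides over the truth grid, matching the 0.02–0.1 L and
0.02–0.1 T design) and additive white Gaussian noise with standard deviation
`noise_level × reference velocity` at valid nodes only (the reference
defaults to the maximum speed of the clean series; the exact scaling
convention is a package choice since none is standard). Both are seeded.

## Error metric

The headline metric is the relative global surface RMSE: the root of the
mean — over retained surface points and all time steps, one global mean
inside the root — of the squared difference between predicted and true
non-dimensional surface pressure, divided by the head-pressure magnitude,
reported in percent. Points aft of x > 0.9 L are excluded before
aggregation (tail region; strongly 3D in real data). "Head pressure" is
operationalized as the time-averaged magnitude of the true surface pressure
at the nose station (x/L = 0); it is configurable. For the doublet
surrogate the nose is not a true stagnation point, so this normalizer is
small (≈0.04 in free-stream units) and the percentages look large; all
method comparisons are ratios under the same normalizer and unaffected.

Gauge alignment before scoring: every compared field (truth included) is
shifted by the mean of its pressure over the valid perimeter nodes, putting
`zero_at_boundary` and `zero_mean` reconstructions on a common zero.

## Sensitivity studies

`run_resolution_sweep` degrades the surrogate truth to grid steps
{0.02, 0.06, 0.1} L at fixed 0.02 T (and optionally coarser time steps),
reconstructs with each method, and tabulates the metric per seed.
`run_noise_sweep` does the same over noise levels (default 0, 5, 10% of the
reference velocity; levels are exposed as parameters since no standard set
exists). Expected qualitative picture, verified by the acceptance tests:
the integration baseline's error grows monotonically as the grid coarsens
(its surface extrapolation distance grows), while the network's error stays
comparatively flat because its residuals always see the finest grid and its
surface pressure needs no extrapolation.

## Numerical choices and limitations

* Float64 throughout; BLAS-level determinism on a fixed platform.
* Nearest-node ties in surface extrapolation break toward the lowest
  row-major index.
* On-contour grid nodes count as body-interior (masked).
* The Poisson solve falls back to a first-order ghost only where both
  stencil neighbors along an axis are missing (isolated strips).
* Divergence of training raises; it does not silently continue.
* At desk scale the network under-resolves the sharpest near-surface
  pressure dips of the surrogate: small networks smooth the field across the
  masked near-body gap, so surface-pressure correlation with truth is
  positive and substantial but well short of perfect (the acceptance suite
  asserts the level the sweep preset reaches). Full-scale settings exist
  precisely because surface accuracy is capacity-hungry; the desk presets
  are sized to demonstrate the method's *properties* (resolution
  insensitivity, exact surface evaluation, gauge behavior) within minutes
  on one CPU.
* For every new velocity series the network is retrained from scratch;
  nothing transfers between datasets, by design.
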