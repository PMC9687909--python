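# Methods

This note documents the models, numerical choices and known limitations of
the `angioflow` pipeline in the order the data flows through it.

## Scene generator

**Flow field.** The duct flow is the analytic fully developed laminar
profile for a square cross-section: the axial momentum balance reduces to a
Poisson problem −∇²v = const with no-slip walls, whose classical solution is
a single Fourier series

v(x, z) ∝ Σ_{n odd} (−1)^{(n−1)/2} n⁻³ [1 − cosh(nπx/a)/cosh(nπ/2)] cos(nπz/a),

rescaled so the cross-section mean equals the bulk velocity (0.005 m/s by
default). The series is evaluated with overflow-safe cosh ratios and is
truncated at 50 terms by default (the centreline value is converged to
≈ 1e-10 by then; the test suite cross-checks the profile against an
independent finite-difference Poisson solve to relative L2 < 1e-3).
Momentum and continuity are therefore satisfied by construction rather than
solved numerically; the lateral velocity components are identically zero.
This is a deliberate substitution: the learning problem only requires a
self-consistent, exactly known ground truth, not a general Navier–Stokes
solver. An axisymmetric jet perturbation hook exists in the configuration
surface but is off by default.

**Scalar transport.** Dye concentration obeys an advection–diffusion
equation with D = 1e-9 m²/s. At the duct's scale the cell Péclet number is
~1e5, so numerical diffusion — not D — is the accuracy concern. The solver
is semi-Lagrangian with cubic interpolation: departure points are traced one
step upstream and the previous field is interpolated there
(unconditionally stable, negligible numerical diffusion at ~1-cell
displacements). Two guards keep the scheme physical:

* a **quasi-monotone limiter** clamps each interpolated value to the bounds
  of the cell containing its departure point, suppressing cubic overshoot at
  sharp dye fronts (without it the pulsed cases gain several percent of
  spurious mass);
* concentrations are clipped to [0, 1] and the inlet boundary is re-imposed
  after each step.

Diffusion is an explicit 3-D Laplacian update (stable for D·Δt/h² ≤ 1/6,
satisfied by ~4 orders of magnitude at the physical D).

**Time step.** Δt = 0.02 s makes the centreline displacement ≈ 1 grid cell
per step. Semi-Lagrangian error accumulates per interpolation, so *larger*
steps are more accurate here; halving Δt measurably worsens mass
conservation. Δt also equals the image-pair companion offset, so exports
fall exactly on step boundaries.

**Mass balance.** The scheme is not conservative by construction; a mass
audit (trapezoidal boundary-flux quadrature at inlet and outlet against the
domain inventory) closes within 0.05–0.6% for the continuous-injection
cases and ~1.5% for the pulsed cases at the default resolution, whose
0.1-s boluses keep two sharp axial fronts alive for the whole run. The
intermittent valve gate has a one-step raised-cosine rise/fall — an
injector transient that also keeps the bolus edges resolvable on the grid.

**Injection patterns.** Four cases: (1) constant injection with the jet
radius ramping linearly 0.37 → 2.0 mm over 1 s (the ramp law and duration
are configuration choices; only the endpoints are prescribed); (2)
intermittent top-hat, 0.1 s on / 0.25 s off; (3) intermittent with radial
cosine profile φ₀cos(ωr), ω = 500 rad/m (φ = 1.0 on the axis, 0.54 at the
2-mm rim); (4) continuous with temporal cosine cos(4π/3·t), clipped below
at zero since a negative scalar concentration is unphysical and the
projector requires φ ≥ 0. The 2.0-mm figure is read as a radius for all
cases for cross-case consistency (a diameter reading for case 2 is
available via configuration). The jet rim is feathered over max(0.25 mm,
one grid cell) — a shear-layer realism choice that doubles as sub-grid
smoothing. Default durations (2.85/2.65/2.65/3.95 s with export intervals
0.2/0.2/0.2/0.3 s) yield 106 exported snapshots forming 53 analysable
pairs across the four cases.

**Quarter domain.** The scene is symmetric under x → −x and z → −z, so only
one quadrant is simulated and mirrored on demand. A full-domain run agrees
with the mirrored quarter to ~1e-6 (the only coupling is the global cubic
spline prefilter, which sees an array edge at the symmetry plane).

## Projector

Parallel rays along z; per-column optical depth τ = μ_ref·Δz·Σφ with
μ(φ) = μ_ref·φ linear in concentration; exit intensity I₀e^(−τ) mapped
linearly to gray with I₀ ↦ 255, rounded half-up, clamped. μ_ref = 463 1/m
was calibrated once so a full-concentration 2-mm-radius jet (4-mm chord)
projects to gray ≈ 40 at its core — comfortably below the gray ≤ 80
dye-dominance threshold, so the sample mask is never empty on a developed
jet. The optical depth is computed on the volume grid and interpolated
bilinearly to the 161 × 306 pixel grid (whole duct width and length in
view). Additive Gaussian gray noise is available behind a seed and is off
by default; the synthetic images are deliberately noise-free so that model
errors are attributable to the physics of projection and optical flow.

## Optical flow

The brightness-transport constraint

Q_t + V·∇Q + Q∇·V = D∇²Q

is the conservative transport statement Q_t + div(QV) = D∇²Q for the
projected intensity. Discretized (central differences for ∇, forward
differences for the smoothness term, homogeneous Neumann borders) the
residual is linear in the unknown pixel displacement field, so the
variational objective

E(u, v) = Σ [Q_t + D_x(Qu) + D_y(Qv) − DΔt∇²Q]² + λ(|∇u|² + |∇v|²)

is a symmetric positive-definite quadratic form. It is minimized by
Jacobi-preconditioned conjugate gradients (monotone in E, which the test
suite asserts per iterate), with Q_t = Q_b − Q_a per frame and all spatial
terms evaluated on the frame average for second-order accuracy in time.
λ = 2000 (squared gray-level units) was calibrated on synthetic sub-pixel
translation fixtures: a 0.5-pixel shift is recovered within ~1%, and the
λ default is held fixed everywhere else. The D∇²Q sink converts the
physical diffusivity to pixel units (D·Δt/pitch² ≈ 3e-3 px² per frame at
the dye value — negligible, but the term is exact on constructed
heat-kernel pairs, which the tests exercise). Velocities are returned in
m/s via the pixel pitch and frame interval. Vectors are computed for every
pixel including dye-free regions; the downstream mask, not the solver,
removes the pseudo-vectors, matching the stage ordering of the pipeline.

The estimator's known failure modes are exactly the interesting ones: a
steady dye column gives Q_t ≈ 0 and hence near-zero velocity regardless of
the true flow, and displacements beyond one pixel are systematically
underestimated (the error-vs-displacement curve is monotone in the tests).
At the default imaging scale the true pattern displacement is ~2.5 px per
frame pair, which is why the raw optical-flow v-error averages ~50%.

## Dataset

Dye-dominant pixels are those with gray ≤ 80 in the first frame of a pair.
Each record carries (u_ofm, v_ofm, Ix, Iy) — the intensity gradients are
central differences of the frame-average image — and the ground truth
(u, v) sampled from the centre-plane slice by bilinear interpolation at the
pixel centre. The duplicate-coordinate split keys on exact integer pixel
indices: for every coordinate with m ≥ 2 records across time, one uniformly
chosen record is held out for test and m − 1 go to training; singleton
coordinates go to training (configurable to drop). Deduplication is global
across the four cases. The default four-case run yields ≈ 42 000 records,
roughly a 3:1 train:test ratio.

## Regression models

All models map the 4 standardized features to the 2 velocity components.
Features are standardized per column on training statistics. Targets are
standardized with **one pooled scale across both components**: u and v are
the same physical quantity, and a per-column scale would inflate a
zero-variance component (u is identically zero on the centre plane of the
substitute flow) to unit scale in m/s, amplifying harmless standardized
residuals into large velocity errors. Predictions are inverse-transformed,
so all reported errors are in m/s.

* **LASSO** — scikit-learn coordinate descent, one L1-penalized linear
  model per output (penalty 1e-3 on standardized data). The baseline and
  interpretability reference; as the penalty → 0 it reproduces least
  squares, as it → ∞ it predicts the training mean (both are test oracles).
* **MLP** — 4 → 10 → 2, ReLU hidden layer, dropout 0.02 after the hidden
  layer (the post-grid-search architecture; a 32-unit variant is one config
  field away), linear output.
* **CNN** — the features are read as a length-4 single-channel sequence:
  three same-padded 1-D convolutions (8, 16, 16 channels, kernel 3) with
  ReLU and a max-pool after the first, then a linear regression head. The
  alternative reading (convolving over pixel-neighbourhood patches of the
  feature maps) was not implemented: it couples the sample table to image
  storage and the 4-feature-vector reading keeps all four models exactly
  comparable on the same records.
* **LSTM** — the features are read as a length-4 sequence of scalars
  through a 10-unit LSTM cell (standard gates: input, forget and output
  sigmoids, tanh candidate, c_t = f·c_{t−1} + i·c̃, h_t = o·tanh(c_t); the
  cell function is exposed and tested against hand-computed states),
  followed by a 10-unit ReLU dense layer and a linear head.

The three networks are implemented in seeded numpy with hand-coded
backpropagation (verified against numerical differentiation) and Adam
(lr 1e-3 default, β = 0.9/0.999). Two training-loop choices matter for
robustness and are on by default: cosine decay of the learning rate to 2%
(the MAE loss has constant-magnitude gradients, so undecayed Adam dithers
around the optimum with amplitude ~lr) and global gradient-norm clipping at
1.0 (heavy-tailed gradient features otherwise destabilize the MSE-loss
fits). Each model is trained twice, once per loss (MAE and MSE), and both
metrics are reported for every model.

**Protocol.** 10-fold cross-validation with 3 repeats (30 fold scores per
model/loss), fold scores computed on the entire validation fold in m/s.
Desk-scale training schedule: MLP 100 epochs/batch 32/lr 1e-3, CNN 150
epochs/batch 128/lr 3e-3, LSTM 120 epochs/batch 128/lr 3e-3, with the
iterative fits subsampling at most 4000/3000/3000 training rows per fold
(scoring always uses every validation row). The batch sizes stay on the
{32, 64, 128} tuning grid; the CNN/LSTM epoch counts are scaled down from
500 as the package's one-CPU problem size — on linear-task fixtures the
schedule lands within ~15% of the noise floor, and on the pipeline data all
three networks reach a few 1e-6 m/s MAE, well past every bound they are
held to. A paired t-test across the 30 fold MAEs marks each deep model's
difference from the LASSO baseline (the test choice is ours; the
significance markers it reproduces do not name one).

## Evaluation

MAE and MSE are the plain formulas over both components. The station
profile uses definition **D1**: at station y, error% = 100·Σ|v_est −
v_truth| / Σ|v_truth| over the dye pixels binned to that station (nearest
station within half the station spacing). Alternatives — pointwise mean of
|Δv|/|v| and normalization by the station max — sit behind a config tag;
D1 is the default because it is robust to near-zero truth values at
individual pixels. The default station set is the nine y-locations 0.00083
to 0.01328 m used for the profile comparisons; the "average v-error" is the
unweighted mean over that set. The downstream trend (optical-flow error
grows with y, corrected error shrinks) is asserted on upstream-third vs
downstream-third station means: at desk scale the station-by-station curve
is not strictly monotone (the first station is inflated by the inlet
transient).

## What the synthetic data does and does not show

The generator reproduces the *structure* of the problem — projective
integration along the beam, Beer-Lambert contrast, sub-pixel-violating
displacements, steady-column blindness, dye-dominance masking, duplicate
coordinates across time — with an exactly known ground truth. It does not
reproduce: detector noise and non-uniform illumination (noise is off by
default), lateral and through-plane secondary flows (the substitute profile
has u = w = 0, so the u-target is exactly zero on the centre plane and the
u-component of the learning task is degenerate), pulsatile bulk flow,
non-Newtonian rheology, or patient geometry. Passing the suite therefore
demonstrates that the correction machinery works where optical flow is
biased in the ways projection makes it biased — not that a model trained
here transfers to clinical images.

## Numerical details and edge cases

* The duct-series cosh ratio is computed in exp space to avoid overflow at
  high harmonics.
* Transport clamps departure points at the inflow face (values come from
  the imposed inlet slice) and the outflow face (outflow is one-way by
  construction since v > 0).
* The conjugate-gradient solver warns and returns the current iterate if
  the tolerance (1e-6 relative) is not met within 1000 iterations; the
  warning carries the residual.
* Zero-variance features are guarded in the standardizer (scale forced to
  1) — relevant for constructed fixtures more than pipeline data.
* The duplicate split permutes records once with the split seed and marks
  the first occurrence of each multi-record key as test: uniform over
  records, byte-reproducible, and O(n log n).
* Model files are .npz containers with the JSON config embedded; a
  load/save round trip reproduces predictions bit-identically.
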