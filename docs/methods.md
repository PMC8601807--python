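# Methods

## Problem and model

The package reconstructs a 2D attenuation map `x` (1/mm) from noisy
parallel-beam transmission data. The measurement model is

    y = M x + noise,

with `M` the line-integral (Radon) operator of the scan geometry. The
estimator is penalized weighted least squares (PWLS):

    x̂ = argmin_{x ≥ 0}  Φ(x) = ½ ‖ȳ − M x‖²_W + Q(x),

where `ȳ` is the log-transformed transmission sinogram, `W = diag(w_i)`
holds per-ray statistical weights, and `Q` is an edge-preserving roughness
penalty. Under the Poisson transmission model (below) `w_i` is the plug-in
inverse variance of `ȳ_i`, so the data term is the quadratic approximation
of the transmission log-likelihood.

## Projector

The system matrix uses exact pixel-intersection chord lengths (Siddon-style
grid traversal), assembled once per geometry as a sparse CSR matrix and
cached. Forward and back projection are `A @ x` and `A.T @ s`, a matched
adjoint pair — a requirement of the splitting solver, which otherwise
inherits an inconsistent gradient. A deliberately naive scalar per-ray
implementation (`dense_system_matrix`) serves as the testing oracle on tiny
geometries; it shares the crossing formulas with the fast path so that rays
riding exactly on grid lines (a measure-zero set that does occur with
integer bin offsets at axis-parallel angles) resolve identically.

FBP deliberately uses a *mismatched* interpolating back projector: it is a
one-shot analytic baseline (frequency-domain ramp filter on a physical
frequency axis, optional Hann window, linear-interpolation back projection,
π/n_views scaling), not part of the iterative machinery.

## Noise model and weights

Counts are simulated per ray as `m_i ~ Poisson(I0 · exp(−[Mx]_i))`, clamped
at 1 (photon starvation guard), log-transformed to `ȳ_i = ln(I0/m_i)`, with
weights `w_i = m_i`. The delta method gives `Var(ȳ_i) ≈ 1/E[m_i]`, so `m_i`
is the standard plug-in inverse-variance weight. Noiseless mode
(`I0 = inf`) returns exact line integrals with unit weights. An optional
additive Gaussian electronic-noise term (variance in counts²) is available
and off by default. The generator does not model polyenergetic spectra,
scatter, detector crosstalk or anatomical realism, so passing benchmarks
here demonstrate solver behaviour, not clinical image quality.

## Regularizer

    Q(x) = Σ_i λ_i Σ_r u_r η_δ([B_i x]_r)

with forward differences toward offsets (0,1), (1,0), (1,1), (1,−1)
(diagonals down-weighted by 1/√2), per-pixel weights `u_r` (default 1) and
an even potential `η_δ`: quadratic, Huber, or the hyperbola
`δ²(√(1+(t/δ)²)−1)` (default). Differences crossing the border are dropped.

Defaults: `λ = 1e7`, `δ = 1e−4` /mm. These were frozen from a
converged-fidelity sweep on the default noisy instance (single-subset runs
to convergence): the near-TV regime (small δ) preserves the piecewise-
constant phantom's edges and reached ≈ 50 dB PSNR, an order of magnitude
better RMSE than weaker or smoother (larger-δ) settings. The λ scale is set
by the weights: transmission counts reach `I0 = 1e5`, so the data-term
curvature per pixel is ~1e8 and λ of order 1e6–1e7 balances it.

The solver needs `prox_{s}(Q + ind(x≥0))`; it is approximated by 10
projected-gradient steps with the elementwise safe step
`1/(1/s + L_Q)`, `L_Q = 4·max(u)·Σλ_i` (each first-difference operator has
`‖B'B‖ ≤ 4`, every potential has `η'' ≤ 1`). This inner iteration is
monotone in the prox objective; on the benchmark instance the subproblem is
so well conditioned (the quadratic term dominates) that 10 steps are
effectively exact.

## OS-LALM

The split-gradient linearized augmented Lagrangian iteration, per subset:

    s     = ρ ∇T_k(x) + (1−ρ) p
    x⁺    = prox_{1/(ρD)} ( x − s/(ρD) )
    p⁺    = (ρ ∇T_k(x⁺) + p) / (ρ + 1)

with `∇T_k` the subset gradient scaled by the subset count, `D = A'WA·1`
the separable-quadratic-surrogate diagonal majorizer (entrywise dominates
`A'WA` because `A ≥ 0`; zeros replaced by the smallest positive entry), and
`p` the split-gradient memory initialized at the full gradient of the FBP
starting image. Initialization `x⁰ = FBP(ȳ)` clipped nonnegative. Subset
visiting order is bit-reversed by default (decorrelates successive subset
gradients); strided order is available for reproducibility studies.

The penalty parameter follows the deterministic downward continuation

    ρ(0) = 1;  ρ(g) = max( π/(g+1) · √(1 − (π/(2g+2))²), ρ_min ),

advanced **once per outer iteration** (g counts data passes). Advancing it
per subset update was tested and diverges at 40 subsets: the `1/(ρD)` step
then grows faster than the split-gradient memory can damp the
ordered-subset gradient error. The gradient-ratio diagnostic
`ϖ = ‖p − ∇T(x)‖ / ‖∇T(x) − ∇T(x_prev)‖` is logged per iteration and does
not drive restarts.

Two empirical properties of OS-LALM matter for interpretation:

* With one subset the iterates contract cleanly onto the PWLS minimizer
  (the quadratic-potential run matches the dense closed-form solve to
  ~3e−6 relative after 2000 iterations). With `ρ_min = 1e−3` the clamped
  regime is underdamped and convergence stalls in slow oscillation; a
  damped clamp (`ρ_min ≈ 0.02`) restores linear convergence. The converged
  reference `x*` used by the benchmark is therefore a 500-iteration
  single-subset run with `ρ_min = 0.02`.
* With many subsets the iterates converge to an ordered-subsets fixed point
  that is biased away from the true minimizer, with bias growing as ρ
  falls (the step `1/(ρD)` amplifies subset-gradient staleness). On the
  default instance this shows as a PSNR decline from iteration ~20 onward
  (45.4 → 44.1 dB) when the schedule is allowed to run to `ρ_min = 1e−3` —
  the gradient-error accumulation that motivates the momentum variant. The
  W=1 vs W=2 limits differ by ~0.4% relative, independent of iteration
  count.

## OS-LALM-OGM

How to compose OGM momentum with OS-LALM is an open design point (the
coefficient recursion is standard; its attachment to the splitting is not).
The package applies momentum to the prox output,

    x⁺ = P_≥0 [ z + ρ·(θ_prev − 1)/θ · (z − z_prev) ],
    θ⁺ = (1 + √(1 + 4θ²))/2   (reset to 1 at each continuation step),

with two stabilizers, both forced by measurement rather than taste:

* the coefficient is damped by ρ — the continuation already realizes
  second-order (inertial) dynamics, and undamped momentum on top of the
  deep-continuation steps diverges under ordered subsets;
* momentum runs while `ρ` exceeds a floor (default 0.3) and the
  continuation is frozen there. The momentum phase does the transient
  acceleration; pushing ρ further down afterwards only grows the
  ordered-subsets limit cycle. Freezing removes the late-iteration
  degradation entirely (stationary fixed point ≈ 48.3 dB on the default
  instance instead of a declining 44–45 dB).

A candidate second momentum term proportional to `(z − v)` (v the pre-prox
point) was implemented and rejected: under the nonnegativity constraint it
re-injects the clamped amount in air regions each update, a measurable
positive haze bias (~0.2 dB). With θ pinned to 1 all momentum terms vanish
and the ρ floor is disabled, so the OGM path retraces plain OS-LALM
bit-for-bit — this degeneracy is tested.

## Metrics and benchmark

PSNR uses the conventional 255 peak: both images are passed through the
affine map that takes the reference range onto [0, 255], then
`10·log10(255²/MSE)`; identical images report infinity. RMSD is
`‖x − ref‖/√N` in native units; the benchmark reports it both against the
converged reference `x*` (convergence metric) and against the truth.

Benchmark conditions (package defaults, also the study conditions): 128×128
Shepp-Logan (contrast-enhanced ten-ellipse table scaled to [0, 0.04] /mm),
1 mm pixels, 120 views over [0, π), 185 bins at 1 mm, `I0 = 1e5`, 40
subsets, checkpoints at iterations 5/20/40, FBP (ram-lak) as the
iteration-independent comparator. The desk-scale grid (rather than a
512×512 clinical matrix) keeps a 10-seed ensemble under ten minutes on one
CPU; the qualitative algorithm ordering is asserted over that ensemble
(≥ 9/10 seeds), not a single draw.

## Cohort fixture

A 128-row synthetic cohort reproduces the published marginal counts exactly
(angina 25, fainting 27, dyspnea 49; hypertension 59, diabetes 26, renal
insufficiency 9, cerebrovascular disease 21, atrial flutter/fibrillation
19; bicuspid 71, trilobular 57). The joint distribution is unreported and
is filled by independent seeded assignment — only margins are meaningful.
Percentages are rounded half-away-from-zero, which reproduces every printed
value (e.g. 59/128 = 46.09375 → 46.1 at one decimal).

## Degenerate inputs and numerical choices

All-zero sinograms return the zero image. Simulated counts are clamped at
1 before the log. Majorizer zeros (pixels missed by every ray) are replaced
by the smallest positive entry. Phantom ellipse sums cancel to O(eps)
residues which are snapped to zero. Geometry construction rejects detectors
narrower than the image diagonal; rays exactly on pixel boundaries are
assigned by the floor convention consistently in both projector paths.

## Known limitations

Parallel-beam 2D only (no fan/cone beam), monoenergetic noise model,
matched-pair projector without finite beam width, approximate (inner
iterative) prox, and an ordered-subsets fixed-point bias at high subset
counts that the package measures but does not remove. The momentum floor
(0.3) and reference-run clamp (0.02) were set on the default instance and
may need retuning for very different geometries or doses.
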