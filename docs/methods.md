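# Methods

This note records the model conventions, algorithmic choices, and default
parameters implemented in `respyro`, and what the synthetic studies do
and do not establish about real respirometry data.

## Forward model and conventions

The chamber/analyzer system is treated as linear and time-invariant:
the recorded concentration is the convolution of the instantaneous gas
release x(t) with the system impulse response h(t). On a uniform grid of
n samples at interval δt (0-based indices, half-open slices throughout),

    b = H(h) x + ε,

with H(h) the lower-triangular Toeplitz matrix whose first column is the
**δt-scaled** kernel sample vector. That scaling convention is global:
`ImpulseResponse.values` already contain the δt factor, so the operator
is a pure Toeplitz multiply with no hidden scaling, and the continuous
mass-preservation condition ∫h dt = 1 reads `values.sum() == 1` on the
stored vector. (The alternative reading — raw samples with δt carried in
the constraint — is algebraically equivalent here; with the default
δt = 1 s synthetic grid the two coincide exactly.)

Matrix-vector products use FFT-based linear convolution (direct
summation below 32 samples, where the FFT round trip costs more than it
saves), giving O(n log n) applications. Leading zeros of the kernel (the
transit delay) are handled by shifting the convolution, so a delayed
kernel produces an *exactly* zero observation head rather than one
polluted by FFT rounding — several structural tests rely on this.

**Delay/support reduction.** With d leading zero samples and an s-sample
support, the first d observations carry no information and the system
reduces to dimension n − d with an s-sample unknown kernel. The final d
entries of x are unrecoverable from the trimmed data: gas released there
has not reached the analyzer when recording stops. This is the standard
practice of discarding the reconstruction tail, and it reappears in the
uncertainty results as inflated posterior variance on those coordinates.

A rule of thumb connects the kernel support to the apparatus: the
washout time constant of a well-mixed chamber is V/F (volume over flow),
and the IRF has effectively decayed after 3–5 time constants
(`estimate_support_seconds`). A 28 ml chamber at 250 ml/min gives
roughly 20–34 s.

## Synthetic study

`make_test_problem` generates the study conditions used by the tests and
the acceptance script:

* **Signal**: six rectangular pulses of widths 30, 20, 12, 8, 4, 2
  samples, unit amplitude, spread over the grid. Real metabolic traces
  often vary slowly, but discontinuous ventilation produces exactly such
  bursts, and the sharp edges are the adversarial case for deconvolution.
* **Kernel**: gamma-form h(t) ∝ t²e^{−βt} with delay ≈ 0.05 n samples
  and support ≈ 0.25 n samples, normalized to unit mass, with β set so
  the peak sits about a fifth of the way into the support — a delayed,
  unimodal washout shape typical of chamber IRFs.
* **Noise**: white Gaussian, rescaled so the *realized* relative level
  ‖e‖₂/‖Hx‖₂ equals the requested 0.5% or 1% exactly (not just in
  expectation). "p% noise" is not otherwise well defined; the exact
  rescaling makes discrepancy-style checks reproducible to rounding.
  The per-sample standard deviation this induces is exposed as
  `noise_sigma`; the Gaussian likelihood is parameterized by the
  precision scale σ = 1/ς throughout.
* All randomness flows through `numpy.random.default_rng` (PCG64); a
  fixed seed reproduces a problem bit-for-bit across platforms.

What passing these studies does **not** show: the generator assumes a
perfectly linear, time-invariant system, exactly known δt, exact white
Gaussian noise, and a single gas channel. Real chambers drift, mix
imperfectly, and couple CO₂/H₂O channels; conclusions about convergence
rates and recovery quality transfer qualitatively, not numerically.

## ℓ2 reconstruction

The Gaussian-prior MAP estimate minimizes
½‖Hx − b‖² + (λ₂²/2)‖Q(x − μ)‖², with Q ∈ {I, first difference, second
difference, custom} as full lower-triangular Toeplitz matrices (diagonal
1, hence invertible). Eliminating the noise scale gives λ₂ = λ/σ (prior
scale over noise scale); λ₂ is the primitive parameter everywhere.

Three routes, which agree to 1e−6 relative on 200-dim problems (tested):

1. **Direct**: dense normal equations (cap 4096); near-singular systems
   are detected by backward error and refused rather than silently
   returning garbage.
2. **CGLS** on the stacked system [H; λ₂Q] x ≈ [b; λ₂Q μ], matrix-free,
   recording per-iteration data misfit and (when the truth is supplied)
   relative error — the curves that exhibit semi-convergence.
3. **Hybrid**: Golub–Kahan bidiagonalization with full
   reorthogonalization; at each outer iteration the projected Tikhonov
   problem is solved with λ chosen by GCV on the projected system.

**GCV.** The objective G(λ) = m‖(I − HA(λ))b‖²/trace(I − ωHA(λ))² is
evaluated through the (projected) SVD. The weighted variant (ω < 1,
used in hybrid methods to counteract over-smoothing of projected
problems) is available; the default is standard GCV, ω = 1 — adaptive ω
schemes exist in the hybrid-method literature but add a tuning rule of
their own, and ω = 1 reproduces the brute-force scan exactly, which is
the property the tests pin down. Minimization is a 200-point log-grid
scan over [10⁻¹⁰, 10] × max singular value refined by bounded scalar
minimization between the bracketing grid points. The hybrid stops when
the GCV value changes by less than 1e−6 (relative) over three
consecutive iterations — the selection has stabilized and further
enlargement of the subspace no longer changes the regularized solution
materially — or at `max_iter`, or on bidiagonalization breakdown.

An **oracle mode** (`optimal_lambda2`) scans 64 log-spaced values in
[1e−6, 1e2] and picks the λ₂ minimizing the true relative error. It
requires the true signal and exists purely as a benchmarking baseline.

## ℓ1 reconstruction (FISTA)

The Laplace-prior MAP problem min ½‖Hx − b‖² + λ₁‖x‖₁ is solved by
FISTA with constant step 1/L: gradient step at the extrapolated point,
soft-thresholding at level λ₁/L, momentum recurrence
t_{k+1} = (1 + √(1+4t_k²))/2. L is estimated by power iteration on HᵀH
with a 1% safety factor. Defaults: λ₁ = 0.002 (the reference value for
the simulated and real studies), 500 iterations or relative step change
below 1e−8. The plain (non-monotone) method is the default; a monotone
restart variant exists for use inside outer loops. Conversion from the
Laplace rate δ: λ₁ = 2δ/σ² — the form consistent with dividing the
negative log posterior σ²/2‖Hx−b‖² + δ‖x‖₁ through by σ² (the product
form 2δσ² that a quick reading of the MAP algebra can suggest is
dimensionally inconsistent with that derivation).

## Circulant preconditioning

The circulant matrix with the kernel as first column matches H on its
lower triangle and is diagonalized by the DFT: θ = fft(kernel). Because
inverting small eigenvalues would amplify noise toward the exact
(undesired) inverse solution, eigenvalues with |θᵢ| < τ are replaced by
exactly 1 (not truncated to zero): retained modes are whitened, dropped
modes pass through untouched. The preconditioner therefore approximates
a *regularized* pseudoinverse. τ can be selected by GCV on the circulant
surrogate Mx = b, which is diagonal in Fourier space and admits an
exhaustive scan over truncation levels; candidate cuts are restricted to
distinct-|θ| boundaries because conjugate-pair ties cannot be split in a
basis-independent way.

Both right preconditioning (default — it leaves the data-fidelity norm
unweighted, so residual-based stopping retains its meaning) and left
preconditioning are supported on the regularized stacked system.

**The preconditioner is built from the delay-free (reduced) kernel.** A
transit delay rotates the circulant completion's eigenvalue phases and
destroys the approximation: empirically, preconditioning the delayed
system attains a far worse best error (0.72 vs 0.33 relative on the
default problem), while on the reduced system the preconditioned run
reaches the *same* best error several-fold faster (13 vs 69 iterations
at 0.5% noise). Preconditioned runs semi-converge faster too, so pair
them with early stopping or explicit regularization.

## Uncertainty quantification

**Gaussian case.** Γ_post = (σ²HᵀH + λ²Q̂⁻¹)⁻¹ and
x_MAP = Γ_post(σ²Hᵀb + λ²Q̂⁻¹μ), dense with a 2048 cap — the study
itself reduces to n ≈ 128 for sampling, and variance extraction beyond
the cap (e.g. stochastic diagonal estimation) is deliberately out of
scope. x_MAP coincides with the Tikhonov solution at λ₂ = λ/σ (tested to
1e−8). Pointwise level-γ bounds are x_MAP ± z_{(1+γ)/2}√diag(Γ_post).
When the truth is drawn from the prior, these intervals have exact
frequentist coverage; the suite verifies 95% intervals cover 90–99% of
coordinates over 200 simulated realizations.

**Laplace case.** The monotone map g(z) = L⁻¹(G(z)) (G standard normal
cdf, L Laplace(0, δ⁻¹) cdf) sends i.i.d. standard normals to i.i.d.
Laplace variates, so the transformed posterior in z has an exactly
Gaussian prior factor:
p(z|b) ∝ exp(−½‖Hg(z) − b‖² − ½λ₁²‖z‖²). Both g and g⁻¹ are computed
through log-cdf/survival identities (`log_ndtr`, `ndtri_exp`), accurate
to |z| ≈ 30 where the naive cdf round trip underflows at |z| ≈ 8.
Sampling uses adaptive random-walk Metropolis in z: the proposal scale
starts at 2.38/√m and is multiplicatively adapted every 100 burn-in
steps toward 25% acceptance, then frozen (preserving detailed balance
for the retained draws). δ defaults to λ₁, matching the weighting of z
in the misfit block. Chains with post-burn-in acceptance below 1% are
flagged but still returned. Effective sample sizes per coordinate come
from initial-positive-sequence autocorrelation sums.

The sampled posterior is deliberately the *literal* transformed target
above — the data misfit is not rescaled by the noise precision, so its
variance scale is meaningful relative to that target, not to the raw
noise level. The qualitative structure is what the studies assert: in a
delayed-kernel problem the final d coordinates are data-free, and their
posterior variance visibly exceeds the interior's (ratio ≈ 1.8 at
n = 128 with λ₁ = 0.5).

## Semi-blind alternating optimization

With only (d, s) known, signal and kernel are estimated jointly:

    min ‖H̃(h̃)x̃ − b̃‖² + λ₁‖x̃‖₁ + λ_h‖h̃‖²   s.t.  h̃ ≥ 0, Σh̃ = 1.

The two blocks exchange through H̃(h̃)x̃ = Ĥ_s(x̃)h̃, so each half-step is
linear:

* **x-step**: FISTA, warm-started from the previous x̃, 200 inner
  iterations per outer pass. Because the joint objective carries no ½ on
  the misfit while FISTA's canonical objective does, the solver receives
  λ₁/2 — the subproblems are then *identical*, not merely proportional.
  An ℓ2 x-step (CGLS) is retained as an option; it reproduces the
  known failure mode in which overly smooth signal iterates drive the
  residual down without pinning the kernel.
* **h-step**: the feasible set {h ≥ 0, Σh = 1} is the probability
  simplex, so the regularized least-squares kernel update is solved by
  accelerated projected gradient with exact simplex projection
  (sort-based), run to a 1e−10 fixed-point residual and verified against
  a generic constrained-QP solver in the tests. s = 1 is constraint-forced
  to h = [1]. λ_h‖h̃‖² acts as a flatness prior: over the simplex its
  minimizer is the uniform kernel, so larger λ_h yields smoother kernels.
* **Stopping**: kernel change below tol·‖h̃‖ or residual change below
  tol·‖b̃‖ (tol = 1e−6; the residual check is skipped on the first
  iteration, where no previous residual exists), or 50 outer iterations
  (60 in the acceptance studies). Defaults λ₁ = 0.002, λ_h = 0.01.

Every kernel iterate is feasible by construction (the projection is the
last operation of the h-step), and the joint objective is non-increasing
across full outer passes up to subsolver tolerance — both asserted in
the tests.

**Initialization.** `initialize_h` provides a uniform kernel and
gamma-density shapes. The classical presets Gamma(α=4, β=3) and
Gamma(α=2, β=0.5) are appropriate for second-scale supports (e.g. an
18.4 s support sampled at 10 Hz); on the synthetic grid (δt = 1 s,
s = 128) they collapse to near-delta spikes, so the two-initialization
consistency study uses a broad Gamma(α=1.5, β=1/(0.4·s·δt)) — a weakly
informative unimodal shape whose mass spans the support without
asserting a peak location.

**Known limitation — the shift valley.** Shifting the kernel right and
the signal left by the same small lag changes neither ‖x̃‖₁, ‖h̃‖², nor
(away from boundaries) the misfit: the joint objective has a nearly flat
valley of shifted solutions, the discrete face of blind deconvolution's
scaling/shift non-uniqueness (the test suite constructs two visibly
different (x, h) pairs whose forward images differ by <1%). The
constraints remove the amplitude ambiguity but only the support
endpoints resist shifts, so runs from different initializations settle a
few samples apart: recovered kernels correlate with the truth at
NCC ≈ 0.88–0.91 but retain pairwise normalized ℓ2 distances of ≈
0.26–0.31, and ±2-sample delay misspecification moves the recovered
kernel by up to ≈ 0.37 while leaving its shape (and NCC with truth)
essentially unchanged. The regression thresholds in the acceptance tests
(NCC > 0.80, two-init distance < 0.35, delay-shift distance < 0.45) are
frozen from reference runs of this implementation at seeds 1 and 5.

## Problem sizes and runtime

The studies run at the native n = 512 for reconstruction,
preconditioning, and the semi-blind solver; n = 128 for posterior
sampling and m = 100 for dense-covariance checks — the sizes at which
dense oracles remain exact and the full suite completes in a few
minutes on one CPU. All sizes are parameters, and the matrix-free paths
(CGLS, hybrid, FISTA, preconditioner) scale to traces of 10⁴–10⁵
samples.
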