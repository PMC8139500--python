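# respyro

Deconvolution and uncertainty quantification for **flow-through
respirometry**.

In a flow-through respirometry experiment an animal sits in a chamber,
air is pumped through continuously, and a gas analyzer records the CO₂
(or O₂/H₂O) concentration downstream. Chamber mixing and tubing smear
the animal's true, time-resolved gas release x(t) into the recorded
trace b(t): the measurement is a convolution of x with the system's
impulse response function (IRF) h, plus noise. Recovering x — needed
whenever metabolic signals must be synchronized with behavior,
locomotion, or ventilation movements — is an ill-posed linear inverse
problem, and becomes a much harder *nonlinear* one when the IRF itself
is uncertain. This package is for physiologists and quantitative
biologists who want to invert such traces, attach honest uncertainty to
the result, and do so even when only coarse IRF metadata (its delay and
support) is known.

## Model

Sampling at interval δt gives the discrete forward model

    b = H(h) x + ε,        ε ~ N(0, ς² I),

where **H(h)** is the n×n lower-triangular Toeplitz matrix whose first
column is the δt-scaled IRF sample vector **h**. When the IRF has a
transit delay of d samples and a compact support of s samples, the
system reduces to an (n−d)-dimensional problem in the s unknown kernel
samples — the *semi-blind* setting.

The toolkit provides:

* **ℓ2 (Tikhonov / Gaussian-prior MAP)** reconstruction — dense
  closed-form solve, matrix-free CGLS on the stacked regularized system,
  and a Golub–Kahan **hybrid** method that selects λ per iteration by
  generalized cross validation (GCV);
* **ℓ1 (Laplace-prior MAP)** reconstruction via **FISTA** with constant
  step size — sparser, crisper pulse recovery;
* a **circulant TSVD-like preconditioner** M = F*Θ̂F (Θ̂ replaces small
  DFT eigenvalues of the kernel by 1) with GCV-selected truncation τ,
  clustering the singular values of M⁻¹H near 1 and cutting CGLS
  iteration counts several-fold;
* **uncertainty quantification**: exact Gaussian posterior moments and
  95% credibility bounds for the ℓ2 case, and transformation-based MCMC
  (mapping the Laplace prior to a Gaussian through the cdf pair
  g = L⁻¹∘G) for the ℓ1 case;
* **semi-blind deconvolution**: alternating optimization that interleaves
  FISTA signal updates with nonnegative, mass-preserving (Σhᵢ = 1)
  constrained least-squares kernel updates, estimating x and h jointly
  from b, d, and s alone.

A synthetic-problem generator reproduces the simulated study used
throughout the tests: a 512-sample train of rectangular pulses (the hard
case — discontinuous ventilation), a delayed gamma-form kernel
h(t) ∝ tᵐe^{−βt}, and white noise at an exact 0.5% or 1% relative level.

## Worked example

Simulate the standard n = 512 problem and invert it two ways:

```bash
respyro simulate --n 512 --noise 0.005 --seed 1 --out demo/prob
respyro reconstruct --signal demo/prob/b.csv --kernel demo/prob/h.json \
    --method fista --lambda1 0.002 --max-iter 500 \
    --truth demo/prob/x_true.csv --out demo/fista
respyro reconstruct --signal demo/prob/b.csv --kernel demo/prob/h.json \
    --method hybr --truth demo/prob/x_true.csv --out demo/hybr
```

which prints

```
wrote n=512 problem (noise 0.500%, seed 1, config 36776285342c4f14) to demo/prob
fista: 500 iterations, lambda=0.002, rel_error=0.2316
hybr: 200 iterations, lambda=0.006904, rel_error=0.3412
```

Read: FISTA (ℓ1, fixed λ₁ = 0.002) reconstructs the pulse train with a
relative ℓ2 error of 0.23 — sparsity suppresses the ringing artifacts
that ℓ2 methods leave between pulses — while the hybrid ℓ2 method needs
no tuning at all: it picked λ ≈ 0.0069 by GCV on its projected
problem and lands at error 0.34. Each output directory contains the
solution (`solution.csv`), per-iteration history (`history.csv`), and a
`metadata.json` with the resolved configuration hash and seed for exact
re-runs.

The same library calls are available in Python:

```python
import respyro as rp

prob = rp.make_test_problem(n=512, level=0.005, seed=1)
rep = rp.fista(prob.operator, prob.b, lambda1=0.002, max_iter=500,
               x_true=prob.x_true)
print(rep.relative_errors[-1])        # 0.2316
```

Other subcommands: `respyro uq` (credibility bounds, Gaussian or Laplace
prior), `respyro blind` (semi-blind joint estimation from `--delay` /
`--support`), `respyro spectrum` (preconditioner diagnostics).

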