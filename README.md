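# cvsans

Estimation of partial scattering functions from contrast-variation
small-angle neutron scattering (CV-SANS) data by Gaussian-process
regression, with a weighted-least-squares baseline and a synthetic
core–shell validation generator.

## The problem

A CV-SANS experiment measures the same p-component system N times in
solvents of different H/D composition. Under incompressibility each measured
intensity is a quadratic mixture of the L = p(p−1)/2 latent partial
scattering functions S_ij(Q):

    I_n(Q_m) = Σ_{i≤j} A[n,(i,j)] · S_ij(Q_m) + ΔI_n(Q_m),

with A[n,(i,i)] = Δρ_{n,i}² and A[n,(i,j)] = 2 Δρ_{n,i} Δρ_{n,j}, where
Δρ_{n,i} is the scattering-length-density contrast of solute i against the
solvent of sample n (carried in 10⁻⁶ Å⁻²). Solving this per Q point by
weighted least squares is unbiased but noisy — especially for weakly
constrained cross terms.

`cvsans` instead places a zero-mean Gaussian-process prior on each S_ij(Q)
with covariance k(Q, Q′) (Gaussian, Matérn 3/2 or Matérn 5/2, plus a white
nugget τ²), encoding the physical knowledge that partial scattering
functions are smooth in Q. Stacking S̃ pair-major (prior N(0, E_L ⊗ D),
D_{mm′} = k(Q_m, Q_{m′})) and observations sample-major with design
B = A ⊗ E_M and noise covariance Σ̃ = diag(σ²), the posterior is the exact
multivariate Gaussian

    mean = K̃Bᵀ (BK̃Bᵀ + Σ̃)⁻¹ Ĩ,
    cov  = K̃ − K̃Bᵀ (BK̃Bᵀ + Σ̃)⁻¹ BK̃,

whose mean gives the estimates and whose diagonal gives statistically
meaningful error bars. Kernel parameters (α, l) are chosen by fixed
subjective choice, by MAP under a hyper-prior, or by empirical Bayes —
maximizing the log marginal likelihood (evidence)

    log p(Ĩ) = −½ Ĩᵀ(BK̃Bᵀ+Σ̃)⁻¹Ĩ − ½ log det(BK̃Bᵀ+Σ̃) − (NM/2) log 2π

over a parameter grid. Internally everything is computed through a whitened
weight-space SVD, which is exact and keeps full floating-point accuracy from
the strong-smoothing regime up to the diffuse-prior (α → ∞) limit, where the
posterior mean provably coincides with weighted least squares.

## Worked example

Estimate the three partial functions (core–core, core–shell, shell–shell)
of a simulated core–shell sphere contrast series, restricted to the smooth
low-Q region, with the kernel chosen by evidence maximization:

```python
from cvsans import (CoreShellParams, generate, split_A, grid_search,
                    fit_gpr, fit_wls, mse)

data, contrasts, truth = generate(CoreShellParams(seed=0))
low = split_A(data)                      # Q < 0.05 1/A
truth_low = truth.below()

sel = grid_search(low, contrasts, families=("matern52",))
print("selected:", sel.best_spec.describe())

gpr = fit_gpr(low, contrasts, sel.best_spec)
wls = fit_wls(low, contrasts)
print(f"GPR  mse = {mse(gpr, truth_low):.3g}")
print(f"WLS  mse = {mse(wls, truth_low):.3g}")
print(f"log evidence = {gpr.log_marginal_likelihood:.1f}")
```

prints

```
selected: matern52(alpha=0.1, l=0.1, tau=1e-05)
GPR  mse = 4.07e-07
WLS  mse = 2.34e-05
log evidence = 280.7
```

The evidence-selected Matérn 5/2 kernel reduces the mean squared error
against the exact curves by a factor ≈ 60 relative to per-Q weighted least
squares on this realization, and its mean error bar (1.2·10⁻³) is a quarter
of the WLS one (4.8·10⁻³): neighbouring Q points share information through
the prior.

The same pipeline is available from the shell:

```
cvsans simulate --preset core-shell --subset A --seed 0 --out sim/
cvsans select   --manifest sim/manifest.yaml --contrasts sim/contrasts.yaml \
                --objective lml --out sel/
cvsans fit      --manifest sim/manifest.yaml --contrasts sim/contrasts.yaml \
                --method gpr --kernel matern52 --alpha 0.1 --length-scale 0.1 \
                --out fit/
cvsans benchmark --subset A --seeds 3 --out bench/
```

`fit` writes one `Q S dS` text table per partial function plus a JSON run
summary (kernel, evidence, diagnostics, seed); `select` writes the full
objective table and the winning kernel; `benchmark` sweeps kernels and
parameters against the known truth.

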