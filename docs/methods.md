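# Methods

## Model

A p-component system measured at N solvent contrasts on a shared Q grid
(Q_1 < … < Q_M, Å⁻¹) obeys, under incompressibility,

    I_n(Q_m) = Σ_{i≤j} A[n,(i,j)] S_ij(Q_m) + ε_{n,m},
    ε_{n,m} ~ N(0, σ_{n,m}²) independent,

where A[n,(i,i)] = Δρ_{n,i}², A[n,(i,j)] = 2Δρ_{n,i}Δρ_{n,j} (i < j), and
the per-point standard deviations σ_{n,m} are taken as known from the data
reduction. Component pairs are ordered lexicographically, (1,1), (1,2), …,
(1,p−1), (2,2), …, (p−1,p−1); the cross-term factor 2 lives in the design
matrix, so each unordered S_ij is reported once. Contrasts are carried in
10⁻⁶ Å⁻², which keeps design-matrix entries O(1–100) and the linear algebra
well scaled; the estimated S inherit the reciprocal units.

The prior on each latent function is a zero-mean Gaussian process along Q,
independent across the L = p(p−1)/2 functions (we claim no knowledge of
their mutual relationships), with a stationary kernel plus white nugget:

    gaussian : α exp(−r²/2l²)
    matern32 : α (1 + √3 r/l) exp(−√3 r/l)
    matern52 : α (1 + √5 r/l + 5r²/3l²) exp(−√5 r/l)
    + τ² [P = Q],     r = |P − Q|.

Assumptions this encodes: S_ij are smooth (twice differentiable sample
paths for Matérn 5/2, once for 3/2, analytic for the Gaussian kernel);
values at nearby Q are correlated over a scale l; amplitudes are O(√α)
around zero. Zero prior mean is kept exactly — no centering — so negative
posterior means are possible and are reported as-is (a diagnostic flags
points whose mean is negative with zero outside ±2 stderr, and
Cauchy–Schwarz violations |Ŝ_ij| > √(Ŝ_ii Ŝ_jj) are logged as warnings,
never enforced).

## Parameters

| parameter | meaning | units | default | why |
|---|---|---|---|---|
| α | prior variance scale; larger ⇒ weaker smoothing, α→∞ ⇒ WLS | (S units)² | 1.0 (grid 10⁻³…10²) | covers strong smoothing to near-WLS around O(1)-scaled data |
| l | correlation length along Q | Å⁻¹ | 0.1 (grid 10⁻³…10²) | commensurate with typical SANS Q ranges (here 0.004–0.4 Å⁻¹) |
| τ | white-nugget scale | same as √α | 10⁻⁵ | stabilizes the near-singular Gaussian-kernel covariance; negligible for Matérn |
| log_q | measure r on log Q | — | off | optional; exposed for strongly log-structured grids |

Kernel-parameter selection: (a) subjective — fix (α, l) from prior
knowledge; (b) MAP — maximize evidence + log hyper-prior density; (c)
empirical Bayes — maximize the evidence on a grid, optionally with one
local refinement pass that doubles grid density around the winner.
Ties within 10⁻⁶ prefer smaller l, then smaller α: when the evidence cannot
distinguish candidates, the less-flat prior is the safer choice. Kernel
*family* selection is reported per family but not automated — evidence
differences between families are typically within noise. Hyper-prior
families: Gaussian (penalty −(θ−θ₀)²/2β², normalizer dropped as
θ-independent), log-normal (full log density; respects positivity; the
default weakly-informative choice), uniform (hard support, −∞ outside,
excluded from the search rather than raised as an error).

## Computation

The stacked system is Ĩ = B S̃ + ε with B = A ⊗ E_M, prior
S̃ ~ N(0, E_L ⊗ D), D_{mm′} = k(Q_m, Q_{m′}). The posterior and the
evidence are evaluated through a whitened weight-space factorization:
D = RRᵀ by Cholesky, Φ = Σ̃^{−1/2}(A ⊗ R), thin SVD Φ = U diag(s) Vᵀ, then

    mean = (E_L ⊗ R) V diag(s/(1+s²)) Uᵀ Σ̃^{−1/2} Ĩ
    cov  = Z diag(1/(1+s²)) Zᵀ + (K̃ − ZZᵀ),   Z = (E_L ⊗ R) V
    log evidence = −½[‖ỹ‖² − Σ_k (s_k²/(1+s_k²))(u_kᵀỹ)²]
                   − Σ log σ − ½ Σ_k log(1+s_k²) − (NM/2) log 2π.

This is algebraically identical to the textbook function-space and
precision-form solutions (the tests verify agreement with dense
implementations of both to 10⁻⁸), but the shrinkage factors s/(1+s²) and
1/(1+s²) involve no cancellation at any amplitude, so accuracy is uniform
in α: the α = 10¹² diffuse-prior check agrees with weighted least squares
to ~10⁻¹³, where a direct Cholesky of BK̃Bᵀ + Σ̃ (condition ~ α/σ²) loses
all but two digits. The (K̃ − ZZᵀ) term is the prior carried by latent
modes the data never touch (exactly zero when NM ≥ LM); posterior variances
are clipped at zero against roundoff. Cost is O(NM·(LM)²), trivially
dense at experimental sizes (NM ≲ 10³).

If the Cholesky of D fails (Gaussian kernel with large l and τ = 0), a
diagonal jitter of 10⁻¹² × (α + τ²) is added and escalated tenfold per
retry up to 10⁻⁶ × (α + τ²), each escalation logged; exhaustion raises a
conditioning error naming the kernel. Degenerate inputs: M = 1 grids and
zero-contrast samples are valid (the posterior falls back toward the
prior); σ ≤ 0, non-finite contrasts, non-increasing grids are rejected at
construction.

The WLS baseline solves each Q point independently:
Ŝ(Q_m) = (AᵀW_mA)⁻¹AᵀW_m I(Q_m), W_m = diag(1/σ_{n,m}²), with estimate
covariance (AᵀW_mA)⁻¹ and no degrees-of-freedom correction (σ are treated
as known, not estimated). Rank deficiency or N < L is an error, not a
silent pseudo-inverse, so comparisons against the smoothing estimator stay
honest.

## Synthetic validation data

The generator emulates a contrast-variation series on a concentric sphere:
core radius 50 Å, shell thickness 10 Å, core/shell SLDs 4.0/1.0 × 10⁻⁶ Å⁻²,
solvent SLD mixed linearly between D₂O (6.36) and H₂O (−0.56) over
φ_D ∈ {1.0, 0.90, 0.80, 0.66, 0.40, 0.22, 0.10, 0.0} — bracketing the core
match point (φ_D ≈ 0.66) and shell match point (φ_D ≈ 0.22). Exact partial
functions come from the sphere amplitude f(x) = 3(sin x − x cos x)/x³
(series expansion below x = 10⁻³ for the removable singularity):
S_CC = c·A_C², S_CS = c·A_C A_S, S_SS = c·A_S² with A_C, A_S the core and
shell amplitudes; the overall scale c = 10⁻¹² makes I(Q→0) O(1–10) in
arbitrary units (absolute units are immaterial to estimator behaviour since
the noise is multiplicative). Noise is I = I₀(1 + η), η ~ N(0, σ²) with
constant relative σ = 0.05 by default (per-point override available), and
the reported error bar is σ|I₀| — the generator's exact one-sigma. The Q
grid is 100 log-spaced points in [0.004, 0.4] Å⁻¹; the low-Q subset
(strict Q < 0.05 Å⁻¹, ≈ 55 points) isolates the smooth region, while the
full grid adds the sharp form-factor minima that stress a stationary
smoothness prior.

What the generator does *not* emulate: polydispersity, instrumental
resolution smearing, inter-particle structure factors, incoherent
background, or Q-dependent error structure from circular averaging.
Passing the validation suite therefore demonstrates correctness of the
inference given the stated error model, and the comparative behaviour of
GPR vs WLS on smooth truth — not performance on raw instrument data, whose
reduction is upstream of this tool.

Study sizes in the validation suite (10 noise realizations for the
comparative findings, 200 replicates for the WLS bias check on a reduced
20-point grid, dense-oracle checks at N ≤ 5, M ≤ 8, L = 3) were chosen as
the smallest sizes at which the Monte-Carlo statements are stable;
the whole suite runs in seconds on one core.

Waviness under misreported errors is quantified as the total variation of
the *deviation from the exact curves*, Σ_m |(Ŝ−S)(Q_{m+1}) − (Ŝ−S)(Q_m)|,
reported alongside the raw total variation of the estimate: the exact
curves themselves fall by orders of magnitude across the grid, so raw
variation is dominated by the truth and barely responds to noise-chasing,
while the deviation-based statistic isolates it.

## Known limitations

- Stationary kernels assume uniform smoothness in Q; data whose character
  changes across the grid (e.g. sharp high-Q minima after a smooth Guinier
  region) are better served by restricting the fit range, as the low-Q
  subset does. Non-stationary and cross-function kernels are out of scope.
- The Gaussian prior admits negative estimates; positivity-constrained
  (log-normal/gamma) priors would require variational or MCMC machinery
  and are deliberately not implemented.
- Hyperparameter search is grid-based (with one optional refinement pass);
  no gradient optimization.
- Evidence values are comparable across kernel parameters on fixed data,
  but are not reliable for choosing between kernel families.
- All curves must share one Q grid; interpolation/rebinning is upstream.
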