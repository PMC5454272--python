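# Methods

## The statistical model

All seven trait models are Gaussian processes evolving along a rooted time
tree whose branch lengths are in Myr and whose tips carry occurrence ages
`t_i` in Ma before present (present = age of the youngest tip unless a root
age is given explicitly). Writing `s_ij` for the root-to-MRCA shared path
length of tips i and j and `T` for the root age, each model specifies a
mean vector and covariance matrix for the tip values; the likelihood is the
multivariate normal density with `diag(SE_i^2)` added to the covariance
diagonal. The SEs come from the trait table and are treated as known — they
are never rescaled by model parameters. Evaluation uses a Cholesky
factorisation; a non-positive-definite total covariance yields −inf rather
than an exception, so optimisers simply avoid that region.

Model specifics:

- **BM** — `V_ij = σ² s_ij`, `E(x_i) = θ`.
- **OU (fixed root)** — `V_ij = (σ²/2α) e^(−α d_ij) (1 − e^(−2α s_ij))`
  with `d_ij` the non-shared time separating the two tips. This is the
  non-stationary form appropriate for trees with fossil tips; the root
  state equals the optimum θ, so the model has k = 3 parameters, and it
  tends continuously to BM as α → 0.
- **trend** — BM covariance with `E(x_i) = θ + β (T − t_i)`. On an
  ultrametric tree all lineages have equal duration and β is confounded
  with θ; the mean constructor warns, and the GLS system is reported as
  singular if a fit is attempted.
- **AC/DC** — instantaneous rate `σ₀² e^(r t)` with t measured forward from
  the root; integrated along shared paths this gives
  `V_ij = σ₀² (e^(r s_ij) − 1)/r`, with the r → 0 limit taken explicitly.
- **rate shift** — `V_ij = σ²₁·(path older than t_shift) + σ²₂·(younger)`,
  with the shift age a free parameter in [0, T].
- **environment-dependent rate** — `σ²(a) = σ₀² e^(b·env(a))` for an
  environmental proxy curve env (age → value). Covariance entries are the
  integral of the rate over each shared path, computed by adaptive
  quadrature (scipy `quad`) accumulated between consecutive distinct node
  depths, so discontinuous test curves integrate correctly too.
- **mode shift (trend shift)** — BM covariance;
  `E(x_i) = θ + β max(0, min(t_shift, T) − t_i)`: drift accrues only over
  the part of each lineage younger than the shift age. Tips older than
  t_shift keep mean θ, which is what makes the shift time identifiable from
  fossil tips.

## Fitting

θ — and β, wherever the mean is linear in it — is profiled out by
generalized least squares at each candidate covariance; this reduces every
model to at most three nonlinear parameters. When all SEs are zero the
overall variance scale also profiles in closed form (the mean GLS quadratic
form), which makes the large simulation studies cheap. Otherwise log σ² is
optimised by bounded scalar minimisation (σ² ∈ [1e−10, 1e4]), and the
remaining shape parameters (α ∈ [0, 20] /Myr, r ∈ [−20/T, 20/T] /Myr,
b ∈ [−20, 20], log rate ratio ∈ [−12, 12]) by L-BFGS-B with five seeded
starts (one moment-based, four random within bounds).

`t_shift` in the mode-shift model is *always* scanned on a global grid
(default spacing 0.1 Myr) before bounded local refinement between the
best grid point's neighbours. The profile surface is piecewise smooth with
kinks at tip ages and can contain saddle points when an interval of time
contains no fossil tips; a grid-free local search can converge to such a
point silently. After any fit, finite-difference gradient and Hessian
diagnostics on the natural parameters are attached to the result; a
non-positive-definite Hessian is flagged (`hessian_pd=False` with a
message), never suppressed.

AICc uses `n` = number of tips in the fitted tree (overridable), with the
guard n > k + 1. Akaike weights are computed from AICc differences and are
invariant to adding a constant. One calibration caveat worth knowing:
models with a free shift age (rate shift, mode shift) scan a breakpoint
over the whole tree span, so their maximized likelihood gain over BM under
BM truth is the supremum of many correlated increments and runs well above
the nominal chi-square scale. AICc alone therefore over-selects such
models at the "within 2 units" margin; decisive support should be judged on
Akaike weights (the mode-shift model exceeds w_A = 0.95 in only a few
percent of BM-truth replicates) or by parametric bootstrap.

The 2-unit support region for the shift time is the set of grid values
whose profile log-likelihood (all other parameters re-optimised) lies
within 2 units of the maximum; a 2-D (t_shift × β) surface is available for
contour plots. The parametric bootstrap simulates datasets under the null
ML parameters — trait values plus Gaussian noise with the observed SE
structure — refits both models per replicate, and reports the proportion of
null 2ΔlnL statistics at least as large as the observed one; its resolution
is 1/nsim.

## The environmental curve

`smooth_env_curve` fits a cubic smoothing spline whose penalty is chosen by
bisection so that the trace of the smoother matrix equals the requested
effective degrees of freedom (default 15, matched to ~0.05 df; a fixed-probe
Hutchinson trace estimate is used for series longer than 150 points).
Evaluation is clamped to the data range, i.e. constant extrapolation at the
boundary values. Note that a curvature-penalised spline reproduces *linear*
data exactly at any penalty but a cubic polynomial only as the penalty
vanishes (df → n); the fitted likelihood is insensitive to the exact df on
smooth curves, which is the property that matters and the one the tests
check (df 15 vs 30 moves the env-rate lnL by < 0.01 on a smooth synthetic
proxy).

## Signal and disparity

Pagel's λ multiplies the off-diagonal shared paths only and is optimised on
[0, 1] jointly with σ² (θ profiled), with the SE diagonal included; the
likelihood-ratio test against λ = 0 (a diagonal-covariance, i.e.
non-phylogenetic, normal fit) uses χ²₁. Blomberg's K uses the standard
MSE₀/MSE formulation with the analytical BM expectation
`(tr V − n/Σ(V⁻¹))/(n−1)` and a tip-permutation test on the variance ratio;
measurement error is not folded into K's covariance (the classical
formulation), and the implementation agrees with the R reference
implementation to 1e−8 on a fixed fixture. K's sampling distribution under
BM is right-skewed; its mean is ≈1 on any tree but its median sits below 1
on strongly non-ultrametric trees, so the calibration test uses an
ultrametric tree, where the median is also ≈1.

Disparity through time uses average squared pairwise distance (for a scalar
trait, twice the sample variance), each unordered pair counted once. The
curve is a step function on the internal-node age grid: the point at
relative time 0 is 1 (whole-clade disparity, normalised), and the value at
each later internal-node age is the mean disparity of the subclades whose
stems cross just below that age divided by total disparity. The BM
reference curves are simulated with rate and root state estimated from the
data (SE noise added to match the observed sampling), on the same grid.
MDI is the signed step-function integral of (observed − simulation median)
over relative time, either over the whole curve or over a user-supplied age
window mapped to relative time; p is the one-sided proportion of simulated
curves whose (windowed) MDI is at least the observed (two-sided available
by flag). A dataset with zero trait variation has zero disparity
everywhere and MDI ≡ 0 by convention (with a warning). The per-tip BM
envelope reports central quantile bands (default 80/90/95%) of simulated
tip values indexed by occurrence age.

## The synthetic-data generator

`sim_fbd_tree` runs a forward birth–death simulation from a single origin
lineage, with fossil samples as a Poisson process along every lineage.
Fossil samples become terminal tips: a sample on a lineage with no later
sampled descendants truncates that lineage at the sampling age; a sample on
a lineage whose continuation is also sampled is attached as a zero-length
side tip (a sampled-ancestor-like configuration that downstream code
accepts with a warning). The returned tree is rooted at the MRCA of the
samples, as in standard comparative analysis: a single-lineage stem
contributes a variance component that is confounded with the root state
under GLS, which time-flexible models would otherwise absorb as a spurious
likelihood gain; stem fossils older than the first sampled divergence are
discarded for the same reason (without the stem frame they would sit at
zero depth and make the covariance singular). Trees are resimulated until
the total tip count falls in the configured range.

Defaults mirror the empirical regime the package targets: origin 36 Ma,
birth 0.18, death 0.12, fossil recovery 0.28 (all per lineage per Myr),
full extant sampling — giving on the order of 78 tips with ~15 extant —
trait θ = 2.66 log10 mm and σ² = 0.002 (log10 mm)²/Myr, ~13.3 replicate
measurements per extant species, and within-species SD 0.04 on log10 length
(≈ 10% length CV, a realistic adult-size spread). The measurement module
emits fossil records as single skull-width measurements via an invertible
regression so the fossil length-estimation path is exercised end to end.

`sim_traits` draws Gaussian increments branch by branch with each model's
exact conditional law (OU transition law; integrated rates for AC/DC,
rate-shift and environmental models; age-dependent drift for the trends),
so simulated tip vectors match the analytic mean/covariance constructions —
verified by Monte-Carlo against them.

The size-bias filter retains fossil tip i with probability
`min(0.5, logistic(−k (x_i − x̄)))` against the clade mean trait x̄:
steepness k = 0 keeps every fossil with probability 0.5 (random sampling),
and k → ∞ removes every above-mean fossil while leaving smaller taxa at
0.5. The exact interpolation between these published endpoints is a design
choice; a single steepness knob with a 0.5 cap is the simplest form
satisfying both limits. `bias_study` wraps the whole false-detection
pipeline (simulate BM truth → filter → fit {BM, mode shift} → Akaike
weight > 0.95 counts as a detection) and doubles as the plain
false-positive calibration study when the bias level is `None` (no
subsampling at all).

## What the synthetic studies do and do not show

The generator reproduces the *scale* of the real system (tree span, tip
counts, trait magnitudes, replication structure) but not its topology,
its correlated fossil-age gaps (e.g. a Pleistocene preservation gap), or
non-Gaussian measurement error; passing calibration and recovery tests
shows the estimators behave correctly under the stated generating
processes, not that any particular empirical dataset satisfies those
processes. The published headline estimates that depend on the original
tree and specimen data are therefore exercised as *arithmetic* (AICc and
weight recomputation from the printed fit table) and as *properties*
(recovery, calibration, bias-invariance) rather than as value-for-value
reproductions.

## Numerical choices and edge cases

- Shared-path matrices are validated positive semidefinite to 1e−8 of the
  largest eigenvalue; zero-length terminal branches are permitted with a
  warning (they arise from sampled-ancestor-like fossils).
- Pruning preserves the original time frame: if removing tips would
  collapse the root, the stem is restored so all retained pairwise shared
  paths — and all tip ages — are unchanged exactly.
- Tip truncation (creating pseudo-fossil tips from dated occurrences of
  extant species) only shortens terminal branches; ages older than the
  parent node are rejected, and truncation to exactly the parent age
  produces a zero-length branch with a warning.
- The trend-shift design column is dropped when numerically zero
  (t_shift = 0), making the fit collapse cleanly to BM instead of raising
  on a singular GLS system.
- All stochastic operations take explicit integer seeds; study loops derive
  per-replicate seeds from a single `numpy` Generator so runs are
  bit-reproducible.
- Problem sizes in the shipped studies (50×150-tip recovery replicates,
  100–200 calibration replicates, 300–1000 DTT/envelope simulations) were
  chosen as the smallest sizes at which the Monte-Carlo error is clearly
  inside the asserted bounds.

## Known limitations

- The OU model is single-optimum with the root pinned at the optimum; no
  multi-peak or stationary-root variants.
- Rate heterogeneity is temporal only (no clade-specific rates), matching
  the scientific question of a clade-wide mode shift.
- The mode-shift profile likelihood is non-smooth at tip ages; the reported
  Hessian diagnostics use finite differences and should be read as flags,
  not curvature estimates, near those kinks.
- Fossil ages are treated as known constants; occurrence-age uncertainty
  propagates only through whatever tree sample (`fit_over_sample`) the user
  supplies.
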