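# Methods

## Latent variable model

K outcomes per patient are modelled jointly as a latent Gaussian vector
Y\* ~ N_K(μ, Σ), ordered continuous → ordinal → binary. Continuous
components are observed directly with free SD σ_k. Discrete components are
observed through threshold crossings and carry unit latent variance (the
usual probit identifiability constraint): an ordinal outcome with levels
0..w has strictly increasing cut-points τ_1 < … < τ_w and its observed level
is the number of thresholds the latent value exceeds; a binary outcome has
the single threshold fixed at 0. One correlation matrix Γ (unit diagonal,
positive definite) is shared by both arms; arm-specific matrices are
rejected with a validation error rather than averaged, since every power
formula uses a single Γ and a silent average would misstate the design. Off-
diagonal entries are latent-scale (biserial/polychoric-type) correlations,
not Pearson correlations of the observed data.

### Orientation conventions

For a discrete outcome with response probabilities π_T and π_C, the latent
treatment effect is δ\* = Φ⁻¹(π_T) − Φ⁻¹(π_C). For this to be positive when
treatment helps — as required by one-sided tests that reject for large
μ̂_T\* − μ̂_C\* — the response event must be an **upper** tail of the latent
scale. The package therefore defines response as exceeding a threshold:
level 1 for a binary outcome, and a cumulative upper level set (default:
any level ≥ 1) for an ordinal outcome. Scores where improvement means a
*decrease* are handled by sign flips, which the composite machinery does
explicitly (below).

The composite responder is the opposite orientation by convention: a
patient responds when **every** component lies at or below its cut η_k
(think symptom scores where lower is better). Users whose components
improve upward recode by negating the component and its cut. Composite
power simulations therefore shift treatment latent means *down* by the
standardized effects so that treatment raises the response probability.
An m-of-K relaxation (response requires only m components to meet their
cuts) is available through inclusion–exclusion over component subsets; the
default remains all-of-K.

## Power functions

With standardized effects d_k (δ_k/σ_k continuous, δ_k\* discrete),
allocation ratio κ = n_C/n_T and per-test level α′, the shifted criticals
are z_k = z_{α′} − d_k √(κ n_T/(1+κ)) and

* co-primary: Φ_K(−z₁,…,−z_K; Γ), each test at α′ = α (an intersection test
  needs no multiplicity adjustment);
* multiple primary: inclusion–exclusion over all 2^K−1 upper-orthant
  probabilities at α′ = α/K (Bonferroni default), cross-checked against the
  complement identity 1 − Φ_K(z; Γ) at 1e−6 — disagreement raises a
  numerical error. Enumeration is capped at K = 12; Holm has no fixed
  per-test level and is handled only by simulation;
* composite: Φ(δ\*/√(2σ²/n) − z_α) with σ² supplied directly or recovered
  from a pilot fit as σ² = n_pilot·σ_δ²/2, where σ_δ² is the delta-method
  variance at the pilot size. When a fit lacks a covariance matrix the
  variance is reported absent and the user must supply σ².

### Multivariate normal quadrature

Φ_K is evaluated by three deterministic paths: exact `norm.cdf` for K=1; a
one-factor reduction integrated by adaptive Gauss quadrature (absolute
error ~1e−12) for equicorrelated Γ with ρ ≥ 0; and scipy's Genz-type
quasi-Monte-Carlo integrator at absolute tolerance 1e−8 with a fixed
internal seed — repeated calls are bit-identical — for general matrices.
The tolerance default is chosen so that integer sample-size outputs are
stable; it is configurable per call (`abseps`).

### Sample-size search

Power is strictly increasing in n, so the search brackets and then bisects
on the integer lattice. The co-primary search starts at the closed-form
single-outcome size for the *weakest* effect (a lower bound, since an
intersection can never beat its worst margin); the union search starts at
the closed-form size for the *strongest* effect at the adjusted level (an
upper bound) and brackets downward. Results carry a minimality certificate:
achieved power at n and the power at n−1. Reported n is per treatment
group; n_C = ⌈κ·n⌉ is reported alongside (tables assume κ = 1). All testing
is one-sided superiority at default α = 0.025.

One boundary case worth recording: on the equicorrelated grid with all four
standardized effects 0.12 and ρ = 0.8, the power at n = 1438 is 0.8000808
by exact quadrature, so the minimal n is 1438 — a value sometimes quoted as
1439, which a quadrature tolerance of ~1e−3 would produce. The package
reports what the model implies at its tighter tolerance.

## Estimation from pilot data

The likelihood factorises each patient's contribution exactly as the
multivariate-normal density of the continuous block times the conditional
(on the continuous values) rectangle probability of the observed discrete
cells. Rectangles are evaluated by the same quadrature engine; the
conditional covariance is shared across patients, so the discrete block is
vectorised. Optimization is L-BFGS-B on an unconstrained reparameterisation
(log σ, first threshold plus log-increments, atanh ρ with a positive-
definiteness guard); starting values come from sample moments and marginal
probit transforms. Cov(θ̂) is the inverse of the numerically differentiated
observed information at the optimum (central differences, statsmodels
`numdiff`), symmetrised; a non-PSD matrix entering the delta method is
projected to the nearest PSD matrix with a warning. The delta-method
gradient of δ\*(θ) uses central finite differences with relative step 1e−5.

Identifiability requires every discrete level observed at least once per
arm (checked, with a named error) and at least 10 patients per arm. Rows
with missing entries are dropped with a logged count; within-patient
missing-data modelling is out of scope. Covariates beyond the treatment
indicator, arm-specific correlation matrices and more than two arms are not
supported.

## Synthetic-trial generator

`simulate_trial` draws latent vectors from the spec's implied MVN: control
continuous means at 0 (power depends only on differences), control discrete
means anchored so the control response rate matches π_C
(μ_C\* = τ_1 + Φ⁻¹(π_C)), or at 0 when a design states latent effects
directly; treatment means are shifted by the standardized effects. Ordinal
thresholds default to equally spaced normal quantiles (uniform category
probabilities at latent mean 0) when a design does not state them — the
generator records this in its output. Latent values are retained alongside
the thresholded observations.

What the generator emulates: two-arm randomised trials whose mixed outcomes
truly follow the latent MVN with a common Γ. What it does not: model
misspecification (non-Gaussian latents, arm-specific correlations),
covariate structure, dropout or missingness. Passing empirical-power checks
therefore demonstrates internal consistency of the power formulas with the
model, not robustness to violations of it.

Empirical power applies the endpoint decision per replicate. The default
*latent* surface computes z statistics from latent sample means with known
unit variance (known σ_k for continuous) — the planning-relevant idealised
test. The *observed* surface re-estimates each discrete latent mean by the
marginal probit transform Φ⁻¹(p̂) with its delta-method standard error
p̂(1−p̂)/(n·φ(Φ⁻¹(p̂))²); this keeps the test correctly sized but loses
power relative to the latent surface, dramatically so for response rates
near 0 or 1 (dichotomisation discards most of the information there).
Proportions are clipped to [1/(2n), 1−1/(2n)] before the transform. FWER
simulations draw test statistics directly from their exact null law
N_K(0, Γ). A single seed expands into fixed 200-replicate blocks via
`SeedSequence.spawn`, making runs reproducible and order-independent.

## Default sizes and tolerances

* α = 0.025 one-sided, target power 0.80, Bonferroni for multiple primary.
* Quadrature abseps 1e−8; inclusion–exclusion cross-check tolerance 1e−6.
* Monte-Carlo replicates default 10 000 (MC SE ≈ 0.4 % at power 0.8);
  heavier checks in the test suite use 2 000 refits (variance comparison)
  and 200 replicates at n = 400 per arm (parameter recovery) — sizes chosen
  to keep MC error well inside the asserted bands.
* Probabilities exactly 0 or 1 are rejected, never clipped: the latent
  effect is unbounded there and any clip constant would be arbitrary.
* Continuous-outcome variances are design inputs, not estimated nuisance
  parameters, in all power functions.

## Known limitations

* The closed-form C_K sample-size representation for equal effect ratios is
  not exposed; the monotone search is the single authoritative path.
* Holm power/FWER are simulation-only.
* Composite sample size inherits the usual pilot-data caveat: σ̂² and δ̂\*
  are treated as known when inverting the power formula, so small pilots
  propagate their noise into n.
* The latent-scale anchoring ties the stated response probabilities to one
  threshold (the first); designs needing a different response level set
  should state thresholds and cuts explicitly.
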