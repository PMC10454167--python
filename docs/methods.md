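# Methods

## Model

`pedliab` estimates the narrow-sense heritability of a binary trait on the
liability scale from extended families that entered a study through affected
probands. Each individual carries a latent liability; the observed phenotype
is the indicator that the liability exceeds a threshold `c = Φ⁻¹(1 − K)`
fixed by the population prevalence `K`. Per family,

    L ~ MVN(Xb, Σ),
    Σ = h²·K₂ + c²_sibs·H₁ + c²_mo·H₂ + c²_fo·H₃ + c²_sp·H₄ + e²·I
        [+ h²_gxe · (K₂ ∘ S)]

where `K₂` is twice the kinship matrix from the standard pedigree recursion,
the `H` matrices are 0/1 shared-household indicators (full siblings,
mother–offspring, father–offspring, spouses = pairs with a common offspring),
and `S` is the same-stratum indicator for the optional gene-by-environment
component. The variance parameters are proportions of the residual liability
variance; `e²` is derived as one minus the sum of the listed components, so
`Σ` is a correlation matrix on non-inbred pedigrees. Fixed effects contribute
`τ² = var(Xb)`, decomposed exactly into per-covariate shares
`β_k² var(X_k)` plus pairwise `2 β_k β_l cov(X_k, X_l)` terms.

Two reporting scales coexist. Internally the components live on the residual
scale and sum to one with `e²`. Output tables divide every component and
every `τ²` share by the per-draw total phenotypic variance `1 + τ²`, so the
printed fractions — components plus covariate shares — sum to one. Residual-
scale rows are kept alongside with a `_resid` suffix. Fixed effects are
printed per raw covariate contrast (females vs. males; born on/after 1946
vs. before; per 10 years of birth year), undoing any standardization.

## Ascertainment correction

Families are observed only because they contain affected probands. The
likelihood is therefore the complete-data truncated-MVN density divided by
the probability of the proband's phenotype,

    μ = P(L_p > c) = 1 − Φ(c − x_pᵀ b),

one Bernoulli factor per family. When a family has several probands, a
single fictitious proband is used whose covariate row is the arithmetic mean
of the actual probands' rows (unrounded, even for binary covariates); the
per-family actual proband count is retained as a diagnostic. `μ` is clamped
to `[1e−12, 1 − 1e−12]` for numerical safety, with a logged warning.

This correction conditions on the proband's *phenotype* only. It is the
exact conditional likelihood when a family enters the study through one
pre-identified individual being affected — a property verified by a
dedicated round-trip test — and an approximation under stronger
ascertainment (see Limitations).

## Inference

Posterior sampling alternates two kernels:

1. **Liability Gibbs sweep.** Each latent liability is redrawn from its
   univariate conditional normal (mean and variance from the family
   precision matrix) truncated to `(c, ∞)` for cases and `(−∞, c)` for
   controls. One-sided truncated draws use normal rejection for non-extreme
   bounds and the translated-exponential rejection sampler in far tails.
2. **Adaptive random-walk Metropolis on θ.** The variance proportions are
   updated on a log-ratio-transformed simplex (flat Dirichlet prior over
   listed components plus `e²`, the joint version of independent Beta(1,1)
   margins under the sum constraint, with the softmax Jacobian included);
   the fixed effects are updated as a second block under independent
   Normal(0, SD 10) priors. Proposal scales adapt by Robbins–Monro toward
   30% acceptance during warmup and are frozen afterwards, so the
   post-warmup chain is a valid Markov chain.

Default chain settings are four chains with 5000 warmup and 5000 sampling
iterations. Initialization: variance proportions at the simplex barycenter,
fixed effects at zero, liabilities at their truncated-normal means — a
feasible state inside all constraints. Per-chain seeds derive
deterministically from the master seed; runs are bitwise reproducible.

Summaries report posterior medians, SDs and 95% highest-posterior-density
intervals (shortest contiguous window over sorted draws; earliest window on
ties; zero-width for constant draws), plus split R-hat and effective sample
size computed with arviz. `c²_total` is summarized from its per-draw sum.

## Synthetic-data generator

The simulator emulates the target study design: random two-to-four
generation extended pedigrees containing parents, siblings, spouses,
uncles/aunts, first cousins, nieces/nephews and grandparents; sex drawn
evenly; birth years laid out by generation (founders near 1911, about 27
years per generation) so both sides of the 1946 dichotomization occur;
liabilities drawn from the family covariance at a chosen true parameter
value; affection by thresholding; and retention of families containing at
least one affected member, with each affected member labelled a proband
with probability 0.75 (at least one forced) — matching the study's 89
probands among 118 cases. Default shape parameters were calibrated once so
family sizes span roughly 7–93 with a median in the twenties, the shape of
the study's family table. Default true parameters are
(h² = 0.5, c²_sibs = 0.2, e² = 0.3, β_sex = 0.4, β_yr = 3.0).

Simulated fixed effects apply to the raw covariate codes (female = 1, born
on/after 1946 = 1) rather than to sample-standardized columns: the retained
sample — and hence any sample-dependent standardization — depends on the
phenotypes being simulated, so only a raw-scale β is well defined a priori.
Recovery experiments therefore fit with `standardize_covariates=False`;
standardized fitting (the study configuration) is fully supported and the
raw-contrast transform is recorded so both report the same contrasts.

What the simulator does not emulate: realistic demography or mortality,
marriage migration, register-based proband sampling intensity, diagnostic
misclassification, and merging of families through distant common
ancestors. Passing round-trip tests therefore demonstrate the correctness
of the estimator under its own generative assumptions, not robustness to
these real-data features.

## Numerical choices

- PSD policy for assembled covariances: smallest eigenvalue below 1e−10 but
  above −1e−8 gets a 1e−8 diagonal ridge (roundoff); below −1e−8 is an
  error surfaced with the family ID.
- Cholesky failure during a Metropolis proposal is treated as log-density
  −∞ (the proposal is rejected), so the sampler never leaves the PD region.
- Covariate standardization uses the analysis sample with ddof = 1; a
  zero-variance covariate is an error.
- Inclusion filters never delete individuals: dropped members stay as
  structural link ancestors so kinship among retained members is unchanged.
  The degree filter bounds `−log₂(2φ)` to the closest proband.
- Half-siblings are not household siblings (H₁ requires both parents
  shared); their genetic covariance is carried by K₂. Spouses are defined
  as pairs with at least one common offspring — the only spouse relation
  derivable from a pedigree file.

## Design choices made where the design was open

- **G×E construction.** The interaction between additive genetic effects
  and the year-of-birth stratum is modelled as `h²_gxe · (K₂ ∘ S)` with `S`
  the same-stratum indicator — the standard pedigree construction for a
  variance component active only within environment strata. A family whose
  analysis members all share one stratum makes this term proportional to
  `K₂`; a warning flags the confounding with `h²`.
- **Sampler backend.** The inference contract is distributional (stationary
  distribution plus diagnostics), so any correct MCMC scheme conforms; this
  implementation uses liability Gibbs sweeps with adaptive random-walk
  Metropolis on transformed θ rather than gradient-based sampling.
- **Experiment sizes.** The recovery harness uses 200 ascertained families
  of three-generation pedigrees (about 2000 individuals) with 20 replicates;
  the bias-direction experiment uses 150 families at 1% prevalence, where
  per-family retention is genuinely low and ascertainment informative. The
  calibration check uses 40 prior-predictive replicates of 25 small
  families. These sizes give Monte Carlo error well inside the tolerances
  they are tested against.

## Limitations

- The proband correction is exact for single pre-identified-proband
  ascertainment and approximate otherwise. Under *complete* ascertainment
  (every family with any affected member is retained) of a trait that is
  common in one covariate stratum, the correction over-penalizes large
  fixed effects: in the round-trip experiment at the default true values,
  the posterior median of β_yr sits about 0.3 below the truth (and
  downstream components shift slightly) while the matched single-proband
  mechanism recovers all parameters. This mirrors the method's own
  approximation, not a sampler defect; the corrected fit's implied
  population prevalence is correspondingly conservative.
- The fictitious-proband average of a binary covariate is a non-observable
  covariate value; it is used unrounded.
- No dominance component (absorbed by the sibling household term), no
  epistasis, no marker-based kinship, no X-linked inheritance.
- The multivariate-normal liability assumption is untestable from binary
  data; mis-specification propagates to all components.
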