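# Methods

`psaphen` stratifies psoriatic-arthritis (PsA) patients into latent
phenotypes from baseline clinical features and evaluates treatment
response by phenotype. This note describes the statistical model, the
data-cleaning conventions, the synthetic cohort the package is tested
against, and the numerical and design choices that were genuinely open.

## The mixture model

Each patient contributes a mixed-type baseline feature vector
`y = (y_cont, y_cat)`. The model is a finite mixture with `K` latent
phenotypes:

    h(y | φ) = Σ_{k=1..K} π_k f_k(y | θ_k),

where `π_k` are the mixing proportions and `f_k` is the component
density. The component family is the latent-class convention for mixed
data: features are conditionally independent given the phenotype, with

* continuous features: univariate Gaussian, component-specific mean and
  variance (diagonal covariance);
* binary/categorical features: independent multinomials over the declared
  levels.

Covariates are deliberately not modelled — the mixture describes the
joint baseline distribution only, so clustering is hypothesis-free with
respect to outcomes.

Fitting is by EM. The E step computes posterior membership
(responsibilities) via log-sum-exp; the M step updates `π_k` as mean
responsibilities, continuous parameters as responsibility-weighted
moments, and level probabilities as responsibility-weighted frequencies.
Free parameters: `(K−1) + K·(2·p_cont + Σ_j (L_j − 1))`.

### Numerical guards

* **Variance floor**: `1e-4 ×` each feature's pooled variance, preventing
  degenerate spikes on (near-)duplicated values.
* **Laplace smoothing** `α = 0.5` on categorical counts, so no level
  probability reaches exactly zero during fitting (disable with `α = 0`;
  the K=1 fit then equals the closed-form sample statistics exactly).
* **Empty components** (total responsibility `< 1e-6·n`) are reseeded at
  the observation with the lowest maximum responsibility.
* Convergence: relative log-likelihood change below `tol = 1e-6`
  (`max_iter = 500`).

### Initialisation

Each of `n_restarts = 10` restarts seeds EM with k-means run on the
standardized continuous columns *plus one-hot categorical indicators*,
then softens the hard partition with a Dirichlet perturbation. Running
k-means on continuous columns alone was tried first and discarded: with
few continuous features the discrete structure (e.g. hand- versus
feet-dominant involvement) is invisible to the initialiser and restarts
collapse into poor local optima. Restart streams are derived
deterministically from `random_state`.

## Choosing K: BIC grid search with an elbow rule

`select_k` fits every `K` in 2..10 and computes
`BIC = −2·log L + p·log n` (lower is better). Because each extra
component buys a real log-likelihood gain well past the true `K`, the
selection is not the bare minimiser but an elbow: with
`d_K = BIC(K) − BIC(K+1)`, the selected `K` is the smallest grid value
from which **every remaining decrease** satisfies `d < τ·d_first`
(`τ = 0.10`), i.e. the decrease of BIC is minimal for all larger `K`.
Quantifying over all remaining steps (rather than only the next one)
makes the rule robust to a single under-optimised fit producing a
transiently small decrease. If the global BIC minimiser is interior to
the grid and smaller than the elbow, it wins; if BIC never decreases
from the first step the grid minimum is returned with a `no_elbow` flag.
All decreases and gain ratios are emitted so the choice can be audited
or overridden, mirroring the judgement-based character of elbow
selection.

## Cohort cleaning

Applied in a fixed order before modelling:

1. **Feature exclusions** — features missing in `> 20%` of loaded rows are
   dropped first; then pairs of (numerically coded) features with
   absolute Pearson correlation `≥ 0.95` on complete cases lose the
   feature later in schema order (keep-first, deterministic). The
   threshold pair (0.20, 0.95) is configurable.
2. **Patient exclusions** — rows missing any remaining feature are
   removed; EM therefore never sees missing data.
3. **Encoding** — age in years is banded to `≤45 / 45–65 / >65` (45 and
   65 fall in the lower band so the bands partition the axis); race is
   collapsed to White / Black-African American / Asian / multiple-others;
   binary and categorical features become 0-based level codes; continuous
   features pass through untransformed.

## Consensus stability

Stability of a `K`-cluster solution is assessed by subsampled consensus:
`T = 200` rounds, each drawing `a = 80%` of patients **without
replacement** (a with-replacement mode exists behind a flag, but
duplicated rows would make pair indicators ambiguous, so subsampling is
the default), refitting the mixture (3 restarts per round for
tractability), and accumulating the co-sampling indicator `I_t` and
co-assignment indicator `M_t`. The consensus entry is
`C(i,j) = Σ_t M_t(i,j) / Σ_t I_t(i,j)`; pairs never co-sampled are
*undefined* (NaN), not zero, and are excluded from all summary averages.
The stability summary reports mean within-cluster and between-cluster
consensus and the cluster-ordered patient permutation used for heatmaps.

## Responder endpoints

Composite flags per patient-visit (units: joint counts 0–68/0–66, VAS in
mm, HAQ-DI 0–3, FACIT-F 0–52, CRP mg/L, BSA %):

* **DAPSA** = TJC68 + SJC66 + CRP (mg/dL) + pain (cm) + patient global
  (cm); CRP is stored in mg/L and divided by 10 at computation. LDA is
  DAPSA ≤ 14 (inclusive).
* **MDA**: at least 5 of 7 — TJC68 ≤ 1, SJC66 ≤ 1, BSA ≤ 3%, pain ≤ 15 mm,
  patient global ≤ 20 mm, HAQ-DI ≤ 0.5, tender entheseal points ≤ 1.
  (The skin criterion uses BSA rather than PASI because BSA is the skin
  measure carried in the baseline table.)
* **TJC50/SJC50**: ≥ 50% improvement from baseline. A zero baseline
  counts as a response only when the visit value is also zero.
* **ACR50**: both joint counts improved ≥ 50% and ≥ 3 of 5 auxiliary
  measures (pain, patient global, physician global, HAQ-DI, CRP)
  improved ≥ 50%.
* **MCIDs**: HAQ-DI decrease ≥ 0.35, pain decrease ≥ 10 mm, FACIT-F
  increase ≥ 4. Denominators are gated on baseline eligibility
  (HAQ-DI ≥ 0.35, pain ≥ 10 mm respectively, boundaries inclusive).

All cut-offs live in module-level constants and can be overridden.

### Aggregation

* **As observed (AO)**: rate = responders / patients with a non-missing
  flag, with a Wilson score 95% CI (chosen for small-cell robustness).
* **NRI-MI**: the denominator is every eligible cluster member. Flags
  missing for reason `other` or `dropout` are non-responders; flags
  missing for pandemic/geopolitical disruption (`covid_geo`) are imputed
  `m = 20` times as Bernoulli draws from the cluster-week as-observed
  rate — the simplest imputation model consistent with basing imputation
  on observed data — and pooled by Rubin's rules (pooled rate = mean;
  total variance = within + (1 + 1/m)·between; normal 95% CI). A
  cluster-week with no observed basis falls back to non-responder with a
  warning.

## The synthetic cohort

No patient-level trial data are public, so the package carries a
generator whose defaults encode the published five-phenotype baseline
structure; everything downstream is exercised against it.

* **Mixing weights** (0.403, 0.208, 0.140, 0.138, 0.111) and, per
  phenotype, the tabulated TJC/SJC/pain means and SDs and the level
  frequencies of the BSA, enthesitis, CRP, disease-duration, age, BMI
  bands plus sex, dactylitis and psoriatic-spondylitis — all taken from
  the published stratified baseline table.
* **Per-location involvement binaries** (tender/swollen by anatomical
  region, dactylitis in hands/feet, psoriasis by body site) are part of
  the published feature list but not tabulated per phenotype; their
  frequencies were set once to encode the phenotype descriptions
  (hand-dominant disease concentrated in hands/wrists, feet-dominant in
  ankles/feet, the enthesitis phenotype in large joints, very-high
  activity everywhere). Without them the feature set under-separates the
  phenotypes relative to the published analysis.
* Features are drawn **independently within a phenotype** — exactly the
  conditional-independence family the estimator fits — so parameter
  recovery is well-posed. Joint counts are truncated Gaussians rounded
  to integers and clipped to their physiologic ranges; the model fits
  plain Gaussians to them, a deliberate, mild misspecification.
* **Planted artefacts**: a fatigue score with 25% missingness (always
  excluded by the >20% rule), three exact duplicate columns (always
  excluded by the collinearity rule), and a base per-feature missing
  rate of 0.002, chosen so complete-case retention over the ~33 final
  features is ≈ 93.6%.
* **Visits**: per patient and week, components improve from baseline by
  phenotype-specific Beta-distributed fractions on a saturating week
  ramp (60% of the asymptote by week 12, 97% by week 196); FACIT-F
  improves additively. Visit missingness gets a reason (`covid_geo`
  2%, `other` 3%, absorbing `dropout` 1.5% per visit). The asymptotes
  were calibrated once so that simulated week-196 MDA rates by phenotype
  span roughly 44–62% with the moderate-activity phenotype highest —
  the clinically reported pattern — and then frozen.

What the generator does **not** emulate: within-phenotype feature
correlation (real joint counts co-vary with pain and CRP), right-skewed
count distributions, informative dropout, treatment switching, placebo
arms, and safety events. Passing tests therefore demonstrate
correctness of the machinery and recoverability under the model's own
assumptions, not validity of the five-phenotype solution on real
patients.

## Problem sizes

Tests and the acceptance script use the cohort sizes the analysis is
defined at: n = 1119 for model selection (the analyzed-cohort size) and
n = 5000 for parameter-recovery checks, where sampling error in a mixing
proportion is ≈ 0.7 percentage points. Monte-Carlo checks of generator
moments use n = 5000–100 000.

## Known limitations

* The elbow rule, though audited, still embeds a judgement threshold
  (`τ`); on weakly separated data the selected `K` is sensitive to it.
* BIC for mixtures is consistent only under correct specification; the
  count features are intentionally misspecified (rounded/truncated), so
  selection behaviour on real data may differ.
* The NRI-MI imputation model is a documented stand-in for an
  unpublished statistical-analysis-plan procedure.
* Consensus refits use few EM restarts per round; with hard-to-fit data
  individual rounds may converge to different local optima, which the
  consensus matrix then reports as instability — by design, but worth
  remembering when reading low consensus values.
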