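# Methods

## Model

Each test-day record carries a vector `y` of T traits (default panel: SCS,
CAS, RCT, a30, in that fixed order). The recursive structural equation model
is

    y = Λ y + X b + Z_h h + Z_p p + Z_s s + e,

where Λ holds the phenotype-to-phenotype causal coefficients of a declared
directed acyclic graph (entry `λ_yx` at row y, column x), and the remaining
terms are the usual multi-trait sire-model components: fixed effects
(intercept plus four stage-of-lactation classes, 5–34 / 35–64 / 65–94 /
95–125 days in milk, last class as reference corner constraint), herd
effects `h ~ N(0, H ⊗ I)`, cow permanent-environment effects
`p ~ N(0, P ⊗ I)`, sire additive-genetic effects `s ~ N(0, G ⊗ A)` and
residuals `e ~ N(0, R ⊗ I)`.

Acyclicity is validated by graph search at construction time, never during
sampling. Under any trait ordering that topologically sorts the graph,
`I − Λ` is unit-triangular, so `det(I − Λ) = 1` and the reduced form

    y = (I − Λ)⁻¹ (X b + Z_h h + Z_p p + Z_s s + e)

is always well defined. Coefficients are contemporaneous: a causal effect
acts within a record (the same milk sample), with no lagged terms.

When Λ has at least one edge, R is constrained diagonal. This is the
standard identifiability condition for recursive systems; it conflicts
mildly with sire-model genetics (dam-mediated covariance is absorbed by
residuals), a compromise this package inherits knowingly from the sire-model
formulation. With no edges the model is the ordinary MTM and R is a full
covariance matrix — the SEM code path with an empty edge set *is* the MTM
(asserted bit-for-bit in the tests).

### Relationship matrix

Bulls are related through a sire–maternal-grandsire pedigree. The numerator
relationship matrix uses the 0.5/0.25 recursion

    a_kj = 0.5 a(j, sire_k) + 0.25 a(j, mgs_k),
    a_kk = 1 + 0.25 a(sire_k, mgs_k),

with unknown ancestors as unrelated founders (no unknown-parent groups;
parents referenced but not listed are appended as founders). `A⁻¹` is
assembled directly from the per-individual recursion residual variances —
computed exactly from the tabular relationships, so inbred ancestors need no
non-inbred shortcut constants — and `A A⁻¹ = I` is verified to 1e-8 at
construction. A is stored dense; the target pedigree size (~1254) does not
warrant sparse assembly.

## Priors

* structural coefficients: independent `N(λ0 = 0, τ² = 10 000)`;
* fixed effects: independent `N(0, 10 000)`;
* G, P, H (and R in the MTM): inverse-Wishart with ν = 6 degrees of freedom;
* R in the SEM: independent scaled inverse chi-square per trait, df ν = 6
  (the shared-ν reading of the protocol; flagged as an interpretation).

The scale matrices are not part of the emulated protocol, so the package
supplies weakly informative defaults centred on half the observed phenotypic
variance split equally across the four components: `S = (ν − T − 1) ·
diag(0.5 · var(y)/4)` for the inverse-Wishart blocks, and per-trait
chi-square scale `s² = (0.5 · var(y)/4) · (ν − 2)/ν` so the prior mean
matches the same target. All scales are overridable in `PriorSpec`.

## Sampling scheme

One iteration sweeps:

1. **Location blocks (Gibbs).** On the reduced responses `y* = (I − Λ)y`
   the model is linear-mixed with residual covariance R, so each block has a
   multivariate-normal full conditional. Fixed effects are drawn jointly
   (kT-dimensional). Herd and PE levels are conditionally independent given
   the rest; levels with equal record counts share a precision matrix, so
   one Cholesky factor serves each count group. Sire effects are updated by
   single-site Gibbs through the `G⁻¹ ⊗ A⁻¹` prior coupling (the classic
   mixed-model scheme), which scales linearly in pedigree size per sweep.
2. **Covariance blocks (Gibbs).** `G | s ~ IW(ν + q, S_G + s'A⁻¹s)` with q
   the pedigree size; P and H analogously with identity weighting; R either
   full inverse-Wishart (MTM) or per-trait scaled inverse chi-square with
   posterior draw `(ν s² + e'e) / χ²_{ν+n}` (SEM).
3. **Structural coefficients (Metropolis-Hastings).** Independent Gaussian
   random-walk proposals per coefficient; the acceptance ratio multiplies
   the diagonal-R likelihood of the affected trait's reduced residuals by
   the normal prior. No Jacobian term enters because `det(I − Λ) = 1`.
   Although the full conditional of each coefficient is available in closed
   form for recursive systems (it is normal), the sampler deliberately uses
   MH; the closed form serves as an independent oracle in the test suite.

Step sizes adapt only during burn-in (multiplicative Robbins-Monro update
every 50 iterations toward 0.30 acceptance) and are frozen afterwards, so
the retained chain is a fixed-kernel Markov chain satisfying detailed
balance. The reference protocol is 120 000 iterations, 20 000 burn-in,
thinning 10 — exactly 10 000 retained samples; short protocols for testing
are set in `ChainConfig`. Fixed seeds give bit-identical chains.

## Derived quantities

All dispersion draws are mapped to the MTM scale,
`M* = (I − Λ)⁻¹ M (I − Λ)'⁻¹`, a congruence transform that preserves
positive semi-definiteness and is the identity when Λ = 0. Per retained
draw the package computes: heritability `h² = 4σ²ₛ/(σ²ₛ+σ²ₚ+σ²ₕ+σ²ₑ)`
(sire model: 4× the sire variance), genetic correlations from G*,
phenotypic correlations from `G* + P* + H* + R*` (the herd component is
included in the phenotypic denominator), and SD-unit causal effects
`λ′ = λ · sd(x)/sd(y)` using the *observed* phenotypic SDs of the input
data, not model-implied SDs.

Derived scalars are computed per draw and then summarised by posterior mean
and 95% HPD (shortest sorted-sample interval, ties toward the lower start),
which propagates uncertainty coherently; the variance-loss table is also
reported as plain point-estimate arithmetic
`100 · (σ²(M0) − σ²(Mk)) / σ²(M0)` on posterior means, the convention used
for headline loss percentages.

**Variance loss uses the structural-scale components.** The direct
(untransformed) G, P, H, R of a causal model describe the dispersion that
would remain if the upstream phenotypes were held fixed by intervention;
comparing them with a no-edge baseline fitted to the same records quantifies
how much variation the causal paths absorb. The MTM-*transformed* components
necessarily reproduce the observed phenotypic covariance, so they are the
wrong basis for this comparison (loss would be ~0 by construction). The
direct-component heritability is reported alongside.

Convergence tooling: lag-k autocorrelations by FFT, effective sample size by
truncating the autocorrelation sum at the first non-positive lag (for an
AR(1) chain this recovers `n(1−ρ)/(1+ρ)`; constant chains report NaN with a
warning), trace and running-mean series with an optional matplotlib hook.

## Synthetic data generator

The generator emulates the design of a first-lactation Italian Holstein
milk-recording scheme: 3266 cows in 309 herds, 128 AI bulls inside a
1254-bull sire-MGS pedigree, ~8783 records. A single `scale` factor shrinks
every count proportionally. Cows are allocated to herds by shuffled
round-robin (balanced, none empty) and each herd draws sires from an
overlapping pool (default 15) so herd and sire effects remain separable.
Records per cow are zero-truncated Poisson with mean 8783/3266 ≈ 2.69;
days-in-milk classes advance one per test day from a random starting class,
mimicking monthly recording. One global seed feeds named substreams
(pedigree, sire, herd, PE, residual effects), so each random source can be
varied independently and output is bit-reproducible.

### Calibrated ground truth

Full covariance matrices for the emulated study were never published, so
`default_truth(model)` completes the published marginal summaries into
consistent matrices — a documented modeling choice, not published data:

* MTM-scale targets: observed trait variances (for a30, the model-based
  phenotypic variance 81.998), baseline heritabilities → sire variances
  (`σ²ₛ = h²σ²ᵧ/4`; a30 uses the published 3.829 directly), baseline genetic
  and phenotypic correlation tables, and the posterior-mean causal
  coefficients of the requested structure.
* Unreported splits: permanent environment takes 30% and herd 10% of each
  trait's non-genetic variance (plausible for repeated early-lactation
  records within herds), residual the rest. Structural-scale diagonal
  residual variances are solved so the transformed diagonal hits its target;
  the phenotypic covariance not claimed by the genetic and causal-path terms
  is split between PE and herd in proportion to their variance shares.
* If an assembled matrix is indefinite (it happens for the single-edge
  structure, where the causal path claims less of the strong RCT–a30
  covariance), it is projected to the nearest PSD matrix with a warning.

With the three-edge truth the completion is exact: the implied MTM-scale a30
sire variance, phenotypic variance and heritability equal 3.829, 81.998 and
0.187 to machine precision, and simulated records reproduce the observed
means, SDs and correlation pattern (checked in the tests).

What the generator does **not** emulate: raw somatic cell counts (SCS is
simulated directly on the log scale), lactation-curve dynamics beyond the
class contrasts, right-censored coagulation times (non-coagulating samples),
missing-data patterns, and herd heterogeneity of variance. Passing recovery
tests therefore demonstrate correctness of the estimator under the model's
own assumptions, not robustness to these real-data features.

## Problem sizes in the test suite

Statistical tests run at reduced sizes chosen to keep the suite in the
minutes range while leaving the assertions well powered: shared fixtures fit
a tenth-scale study (≈900 records, 1500 iterations); the recovery acceptance
check fits four independent quarter-scale replicates (≈800 cows, 2500
iterations each) and requires the posterior mean within three posterior SDs
of the generating coefficient in every replicate with HPD coverage in at
least three; the conjugate-oracle check compares 10 000 thinned draws of a
stripped single-trait model against a numerically exact semi-conjugate
posterior by Kolmogorov-Smirnov at α = 0.01. Tolerances on Monte-Carlo
quantities are set at three to five times the measured or analytic standard
error of the estimator under test (e.g. the shortest-interval HPD endpoint
has SE ≈ 0.05 at n = 10 000 normal draws, hence a ±0.16 band).

## Numerical choices and edge cases

* Covariance conditionals are factorised by Cholesky; a failure raises a
  `NumericalError` naming the block, and `run_chain` reports the iteration.
* `(I − Λ)⁻¹` is computed by dense inversion; for acyclic Λ it equals the
  finite Neumann series (property-tested to 1e-12).
* The retained-sample rule keeps iterations `i ≥ burn_in` with
  `(i − burn_in) mod thin = 0`.
* Empty data (zero rows/levels) reduces every conjugate update to its prior,
  which the prior-only tests exploit.
* HPD of a constant chain is the zero-width interval at that constant; ESS
  of a constant chain is NaN with a warning.
* PSD projections clip eigenvalues at `1e-8 · mean(diag)` to keep matrices
  strictly PD for Cholesky and Wishart machinery.

## Known limitations

* Sire (not animal) model: dam contributions are ignored by design; direct
  genetic variances are 4× sire variances.
* No structure learning: causal networks are user-declared.
* No model-comparison criteria, censoring models, or missing-phenotype
  imputation.
* Single-site sire updates mix slowly for very large, strongly linked
  pedigrees; block updates would be the next optimization.
* The calibrated truth is an emulation constrained by published marginals;
  recovery acceptance is defined against the generator's own truth, never
  against the published chain-level estimates themselves.
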