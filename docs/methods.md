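# Methods

## Model

A genome's ordered codon frequency sequence is modelled as a mixture
of two codon compartments with mutually independent frequency
distributions, combined in proportion α (the fraction governed by the
weak-bias compartment):

    y = α·y₁ + (1−α)·y₂.

**Weak-bias compartment.** Frequency follows a normal distribution
truncated to the admissible range [0, 1]:

    P₁(y) = [Φ((y−μ)/σ) − Φ(−μ/σ)] / [Φ((1−μ)/σ) − Φ(−μ/σ)].

Since the 64 frequencies are normalized, the truncated mean must equal
1/64. We impose this with the standard truncated-normal mean formula,

    1/64 = μ + σ·(φ(a) − φ(b)) / (Φ(b) − Φ(a)),  a = −μ/σ, b = (1−μ)/σ,

and root-solve for μ given σ (Brent, bracketing by downward expansion
from μ = 1/64; tolerance 1e−12). The sign convention matters: with
φ(a) − φ(b) in the numerator, truncation at zero pulls the mean above
μ, which is the physically relevant regime (μ < 1/64). The opposite
ordering has no solution consistent with the reference pair
(σ = 0.009, μ = 0.01461), which our solver reproduces to 5 decimals.
Moments are closed-form; `scipy.stats.truncnorm` and direct quadrature
serve as independent cross-checks in the test suite, never as the
implementation.

**Expected ordered sequence.** The compartment's contribution to the
frequency/rank curve is its distribution sampled into 64 bins of equal
cumulative-probability width. Two routes are implemented:

* *Monte-Carlo* (default 10⁶ cycles): draw R ~ U(0,1), invert the
  truncated CDF for y by bisection (45 halvings, interval < 1e−13),
  accumulate y into bin ⌊64R⌋, average per bin. Per-bin standard
  errors are recorded; an empty bin (probability ~64·(63/64)^cycles,
  negligible at default settings) raises rather than silently
  degrading.
* *Exact*: 64·∫ quantile(P) dP over each probability bin by adaptive
  quadrature of the closed-form quantile μ + σΦ⁻¹(·). This is the
  exact expectation of the MC bin average and doubles as the MC
  sampler's oracle; the two agree within 3 MC standard errors per bin.

The bisection and closed-form quantiles are independent code paths by
design, so the MC-vs-exact comparison also cross-validates the
inversion.

**Strong-bias compartment.** No parametric family is imposed. From
data, it is the renormalized average of the ordered sequences of the
genomes in the right-most (highest-B) non-empty bin of the bias
histogram. The package additionally ships a *synthetic* stand-in
(`data/strong_compartment_synthetic.tsv`, regenerable with
`synthetic_strong_compartment()`): frequencies decaying exponentially
with rank, normalized to sum 1, with the decay constant root-solved so
the sd about 1/64 (denominator 63) equals 0.0207 exactly. The
stand-in preserves the two statistics the bias-composition relation
depends on (mean 1/64, sd 0.0207) and the qualitative convex decay of
real strong-bias sequences; it does not reproduce the cascade plateau
structure of any particular genome group, so fits against real data
should derive the compartment from the data instead
(`codonmix empirical`).

**Merging and the residual floor.** An observed genome hides which
codon sits at which rank within each compartment. Merging therefore
scrambles compartment 2's rank-to-codon assignment — by 10⁴ random
pair transpositions (default) or an equivalent uniform random
permutation (`scramble="permutation"`, faster) — before the scaled
sequences are summed per codon and re-ordered. The mean over 100
randomizations (each re-ordered before averaging, the mean re-sorted
defensively) is the theoretical curve; the trial scatter about it,
rms ≈ 10⁻³ at α = 0.5, is the floor below which no fit can push the
residual. Under random pairing the compartment deviations are
independent, so squared biases compose:

    B(α) = √[(N−1)(α²s₁² + (1−α)²s₂²)], N = 64.

The (N−1) prefactor follows from the exact identity B² = 63·s² for any
normalized 64-vector with sample sd s (the sample mean is pinned at
1/64), which the suite checks both algebraically and by simulation.

## Fitting

`CodonMixture.fit()` minimizes the rms residual (denominator 64 —
plain mean of squared residuals over ranks) between the observed
ordered sequence and the mean theoretical sequence. The trial
randomizations are drawn once per model from the seed and reused for
every candidate α (common random numbers), making the objective
deterministic and smooth in α. A grid scan (default step 0.01) is
followed by golden-section refinement on the flanking interval to
1e−3. Grid-plus-refinement was chosen over derivative-based search
because the objective is piecewise-smooth with possible shallow local
structure from re-sorting; at 64 ranks the scan is cheap. Results
carry the fitted α, rms residual, residual floor (trial scatter),
observed B, closed-form B(α), per-rank residuals and a `summary()`.
The practical uncertainty of α is set by the residual floor and is of
the order of the grid step; the parameter-recovery suite quantifies it
directly (MAE ≤ 0.03 at 10⁵ codons).

## Synthetic data

`generate_genome` draws one genome exactly through the data model: a
single randomized merge at the true α, a seeded random assignment of
the 64 merged frequencies to codon labels, then multinomial counts at
the requested total. Count noise is modelled deliberately — real
codon-usage summaries are finite counts, and the 10⁴-codon inclusion
filter is only meaningful with sampling noise present. Defaults
(σ = 0.009, packaged stand-in compartment 2, total 10⁵ codons, α
uniform on [0, 1] for cohorts) are the study conditions under which
the recovery suites run. What the generator does *not* emulate:
phylogenetic correlation between genomes, per-gene inhomogeneity
within a genome, GC-content covariates, or any specific codon-identity
ordering — so passing recovery tests demonstrate the estimator's
self-consistency under the model, not the model's adequacy for any
particular real genome.

## Numerical choices

* Bias histogram: half-open bins [edge, edge+width), width 0.005 over
  [0.04, 0.18] by default (~28 bins spanning the roughly threefold
  observed bias range); an epsilon of 1e−9 bins in the bin-index
  computation keeps exact edge values in their proper bin. Out-of-range
  genomes are reported, not binned.
* Ordered sequences are validated (non-increasing, Σ = 1 within
  1e−12) but not renormalized, so ordering is bit-for-bit idempotent.
  Compartment sequences *are* renormalized to sum exactly 1 (MC input
  tolerance 2e−3, analytic 1e−9).
* Ties in ordering keep input label order (stable argsort).
* Degenerate inputs: all-zero count tables parse but refuse
  normalization; genomes outside the histogram range are excluded from
  compartment derivation; duplicate genome ids are rejected where
  membership matching would be ambiguous.
* Seeds: every stochastic routine takes an explicit seed; cohort
  generation spawns per-genome seeds from one master seed; CLI outputs
  carry a deterministic provenance header (no timestamps), so reruns
  are byte-identical.

## Problem sizes

The shipped test-suite runs use 10⁶ MC cycles for the sampler check, a
50-genome recovery cohort at 10⁵ codons per genome with 100 merge
trials per candidate α, and 5 replicate fits for the residual-floor
check — sizes at which the statistical checks resolve the quantities
of interest while the whole suite completes in a couple of minutes.

## Known limitations

* Compartment 2 is tabulated, not modelled; conclusions about its
  internal statistics are out of scope.
* σ is held fixed across genomes (one distribution explains all weak
  bias); per-genome σ fitting is deliberately not offered.
* The fit is per whole genome; per-gene compartment assignment is not
  modelled.
* Near α ≈ 0.87 (where s₂²/(s₁²+s₂²) crosses), B(α) is flat, so bias
  alone barely constrains α there; the fit uses the full 64-rank curve
  and remains identifiable, but B-based sanity checks lose power in
  that band.
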