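# codonmix

A two-compartment statistical model of genomic codon usage.

## The problem

A genome's 64 codon frequencies, sorted in descending order, form a
frequency/rank curve that summarizes how unevenly the genome uses the
redundant genetic code. Across taxa these curves vary in a strikingly
regular way: weakly biased genomes (most eukaryotes) show a sigmoid
cumulative distribution of codon frequency, strongly biased genomes
(many prokaryotes) a cascade-like decay. `codonmix` models the whole
family of curves with a single fitted parameter.

## The model

Each codon's overall frequency is the algebraic sum of scaled
frequencies from two compartments mixed in proportion α:

    y = α·y₁ + (1−α)·y₂

* **Compartment 1 (weak bias).** Codon frequency follows a Gaussian
  N(μ, σ) truncated to [0, 1]. Normalization forces the truncated mean
  to equal 1/64, which fixes μ once σ is chosen:
  `1/64 = μ + σ·(φ(a) − φ(b)) / (Φ(b) − Φ(a))`, with a = −μ/σ,
  b = (1−μ)/σ. At the reference scale σ = 0.009 this gives
  μ = 0.01461 and a compartment sd of s₁ ≈ 0.0081.
* **Compartment 2 (strong bias).** Described empirically: the average
  ordered frequency sequence of the highest-bias genomes in a dataset
  (sd s₂ ≈ 0.0207). A synthetic stand-in with exactly that sd is
  packaged so nothing external is required.

Because an observed genome does not reveal which codon occupies which
rank inside each compartment, the rank-to-codon assignment of
compartment 2 is randomized (10⁴ random pair swaps) before summing and
re-ordering; the mean over 100 such randomizations is the theoretical
curve, and individual randomizations scatter about it with an rms of
order 10⁻³ — the attainable residual floor of any fit.

Bias is measured as B = √Σᵢ(yᵢ − 1/64)², and the mixture's bias
follows in closed form from variance composition:

    B(α) = √[(N−1)·(α²s₁² + (1−α)²s₂²)],  N = 64.

Fitting a genome means scanning α ∈ [0, 1] for the minimum rms
residual between its observed ordered sequence and the mean
theoretical sequence.

## Worked example

```python
import codonmix as cm

# simulate one genome from the mixture at a known proportion
genome = cm.generate_genome(cm.SyntheticGenomeSpec(alpha=0.6, total_count=100_000, seed=3))
model = cm.CodonMixture.from_counts(genome, seed=1)
result = model.fit()
print(result.summary())
```

prints

```
Two-compartment codon usage mixture fit
=======================================
genome:                synthetic-a0.600-s3
alpha (Gaussian frac): 0.590  (grid 0.01, refined to 1e-3)
rms residual:          9.556e-04
residual floor (rank scatter): 1.174e-03
observed bias B:       0.0769
predicted bias B(alpha): 0.0773
trials: 100   seed: 1
```

The genome was simulated with a true Gaussian proportion of 0.60 and
10⁵ codon counts; the fit recovers α = 0.59. The rms residual
(9.6·10⁻⁴) sits at the rank-scramble floor (1.2·10⁻³), i.e. the model
explains the curve as well as the unknown codon ranks permit, and the
closed-form B(α) = 0.0773 matches the observed bias 0.0769.

The same analysis runs from the shell on CUTG-style `.spsum` files:

```sh
codonmix simulate --n 50 --total 100000 --seed 11 --out cohort.spsum
codonmix fit cohort.spsum --seed 1 --out fits.tsv
codonmix histogram cohort.spsum --out hist.tsv
```

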