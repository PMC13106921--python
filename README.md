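# ucepi

Bias-corrected nucleotide diversity (π / θ) from ultraconserved-element
(UCE) alignments, without a reference genome.

## The problem

UCE capture is a cheap way to collect thousands of loci across almost any
taxon, but the loci are, by definition, centered on sequence under strong
purifying selection. Diversity is depressed near the conserved core and
recovers only a few hundred base pairs into the flanks, so the naive
estimate — averaging per-site heterozygosity over all alignment columns —
systematically underestimates genome-wide diversity. For conservation and
population-genomic work that needs an honest π, this bias matters.

## The method

For each locus alignment (rows = individuals, columns = sites centered on
the core, the shape produced by a Phyluce + MAFFT workflow), the per-site
diversity at a column with coverage *n* and minor-allele count *s* is

    π = s(n − s) / C(n, 2)

the fraction of sequence pairs differing at the site. Multiallelic columns
are excluded; monomorphic columns are genuine π = 0 observations. The
expected diversity at signed distance *i* from the core is modelled with a
Gompertz sigmoid

    f(i) = θ · exp(−β · e^(−γ|i|))

whose asymptote θ is the corrected diversity estimate; β is the core
depression depth and γ the per-bp recovery rate (≈ u/4s and r/s under a
Hudson–Kaplan background-selection reading). Parameters are fitted by
bounded weighted least squares, with each site weighted by
w = 1 − 2/(n + 1) (inverse of the leading term of Tajima's variance of π),
in two modes:

* **Stacked** — fit the across-locus mean diversity at each position,
  after dropping positions whose aggregate coverage falls below a
  data-driven cutoff δ (inflection of the smoothed log-ECDF of coverage);
* **Concatenated** — fit every (locus, position) value with per-site
  weights.

Alternative curves (generalized logistic, piecewise linear, Hudson–Kaplan)
are available for comparison, θ can be converted to an effective
population size Ne = θ/(4μg), and a synthetic UCE generator with known θ
provides a controlled test bed.

## Worked example

Simulate 500 loci (10 individuals, 750 bp flanks, true θ = 0.005) and
estimate:

```bash
ucepi simulate --k 500 --n 10 --flank 750 --seed 11 --out demo/
ucepi estimate --input demo/ --mode both \
    --mu-per-year 6.75e-10 --generation-time 2.7
```

```
stacked       model=gompertz  theta=0.00507493  uncorrected=0.00289887  loci=500  sites=1501    delta=0  Ne=696 k
concatenated  model=gompertz  theta=0.00507493  uncorrected=0.00289887  loci=500  sites=750500  delta=0  Ne=696 k
```

The naive average (0.0029) underestimates the true θ = 0.005 by ~42%
because of the conserved core; the fitted asymptote recovers it within
1.5%, and the two modes agree. `Ne` is the effective population size
implied by the supplied passerine mutation rate and generation time.

The same pipeline runs from the library as a scikit-learn-style estimator:

```python
from ucepi import UCEDiversityEstimator, read_loci

est = UCEDiversityEstimator(mode="stacked").fit(read_loci("demo/"))
est.theta_          # corrected diversity estimate
est.uncorrected_pi_ # naive positional average
est.predict([0, 400, 750])  # fitted diversity curve
```

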