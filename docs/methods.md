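# Methods

## Model

Diversity across a UCE locus is treated as a function of signed distance
*i* from the conserved core (position 0). The expected per-site diversity
is the Gompertz sigmoid f(i) = θ·exp(−β·e^(−γ|i|)): θ is the flank
plateau and the quantity being estimated; β sets how deeply the core is
depressed (f(0) = θe^(−β)); γ sets how fast diversity recovers per bp.
Under a background-selection interpretation — a core under purifying
selection with coefficient s, deleterious mutation rate u and
recombination rate r per bp, with u, r ≪ s — the Hudson–Kaplan reduction
θ·exp(−u·s/(2s + rx)²) is approximated by the Gompertz curve with
β = u/4s and γ = r/s; the approximation is good while 2rx ≪ s (within 3%
for γx ≤ 0.1 and β ≤ 10, which the test suite sweeps numerically). The
Hudson–Kaplan curve itself is available as an alternative fit, in its
identifiable (θ, β, γ) parametrization — u, s and r only enter through
those two ratios, so they cannot be recovered separately from curve shape.
The literature also writes the exponent denominator as (2rx + 2s)²; we use
the (2s + rx)² form, which is the one consistent with β = u/4s, γ = r/s.

Key modelling assumptions: diversity depends on position only through
|i| (symmetry); sites contribute independently to the objective; the flank
plateau equals genome-wide θ (neutral equilibrium, E[π] = θ).

## Per-site statistics

π at a column with coverage n and minor count s is s(n−s)/C(n,2), the
fraction of differing sequence pairs. Columns are classified from their
A/C/G/T content: gaps, `?`, `N`, `*`, `.` and all IUPAC ambiguity codes
count as missing, since an ambiguous base cannot be assigned to an allele
without genotype information. Columns with n < 2 are unusable (no pair to
compare) and are excluded everywhere, including the naive average.
Multiallelic columns (3+ alleles) are excluded per locus-position — at
population scale they are rare and usually artefactual — while the same
position still contributes from other loci. Monomorphic columns are kept
as π = 0 observations; dropping them would inflate diversity.

Each site is weighted by w = 1 − 2/(n+1). Tajima's variance of π is
≈ θ(n+1)/(3(n−1)) for small θ, so this weight is proportional to the
inverse variance (Aitken/BLUE weighting) up to a constant that does not
affect the minimizer; w = 0 at n = 1 and w → 1 as n → ∞.

## Fitting

Both modes minimize a weighted least-squares objective over bounded
parameters with scipy's trust-constr optimizer:

* Stacked: Σ_i w_i (f(i) − mean_j π_{i,j})², with w_i from the aggregate
  coverage n_i = Σ_j n_{i,j}, the per-position mean taken over only the
  loci covering position i, and positions with n_i < δ excluded.
* Concatenated: Σ_j Σ_i w_{i,j} (f(i) − π_{i,j})², no δ filter; missing
  data is handled entirely by the weights.

Because every curve depends on position only through |i|, both objectives
collapse exactly onto per-distance sufficient statistics (Σw, Σwy, Σwy²
at each distinct |i|). This is an algebraic identity, not an
approximation: objective and gradient match the full sums, but each
optimizer iteration costs O(ℓ) instead of O(ℓk). Consequently Stacked and
Concatenated cost about the same here, and on complete data with equal
coverage they yield identical fits (the objectives are then proportional).

Numerical choices: Gompertz initials (θ, β, γ) = (0.001, 10, 0.009) and
bounds θ ∈ [0, 0.05], β ∈ [0.1, 30], γ ∈ [0.004, 0.03] — within-population
θ is generally below 0.01, and the β/γ ranges keep the transition inside
realistic flank lengths. The objective is normalized by total weight and
parameters are rescaled to comparable magnitudes before optimization, so
the stopping tolerances (gtol = xtol = barrier_tol = 1e−14, ≤ 10⁴
iterations) mean the same thing regardless of data size; analytic
gradients are used for Gompertz and Hudson–Kaplan, finite differences for
the comparison curves. Noise-free Gompertz data is recovered to ~1e−6
relative. A fit ending on the θ upper bound is logged as suspect; an
all-zero profile drives θ̂ to the lower bound (up to the interior-point
barrier's ~1e−7 offset). Fits are deterministic: there is no randomness
in the optimizer path.

Ties: with an exact 50/50 biallelic split either allele may be called
minor — s(n−s) is unchanged. For even-length alignments the core is the
left of the two middle columns (floor((L−1)/2)); the model uses |i|, so
the one-column asymmetry is negligible. The alignment midpoint is taken
as the core; MAFFT gapping can shift the true core by the net indel
offset, which slightly blurs β and γ but barely moves the asymptote θ.

## Comparison curves

* Generalized logistic (Richards, 6 parameters A, K, B, Q, ν, M):
  A + (K−A)/(1 + Q·e^(−B(|i|−M)))^(1/ν), θ̂ = K. Initials/bounds are
  package defaults (A = 0, K = 0.001, B = 0.009, Q = 1, ν = 1, M = 100;
  asymptotes bounded like θ, rate like γ). Its six parameters are weakly
  identified on short flanks and estimates can be erratic — it is a
  comparison model, not a recommendation.
* Piecewise linear: flat core level to halfwidth c, linear ramp of width
  d−c, flat asymptote (= θ̂) beyond d. Fitted with all four quantities
  free; a reduced variant pins core_level = 0 and c at a chosen bait-core
  half-width via the `fixed` regressor parameter.

## Coverage cutoff δ (Stacked mode)

Aggregate coverage is a high bulk plus a long low tail from positions only
a few unusually long loci reach. δ is placed at the inflection of the
smoothed empirical CDF of coverage: fit a cubic smoothing spline to
log(ECDF) against coverage and take the first coverage (scanning upward)
where its second derivative changes sign. Two design choices proved
decisive and were validated on constructed tail+bulk mixtures before
freezing:

* The log transform is applied to the ECDF values. Log-transforming the
  coverage axis instead compresses the gap between tail and bulk so much
  that the detected inflection lands just inside the tail rather than
  between the components.
* Smoothing is calibrated to the ECDF's own sampling noise — weights are
  the inverse relative binomial noise sqrt((1−F)/F) and the smoothing
  factor equals the number of distinct coverages — rather than chosen by
  cross-validation. ECDF data is nearly noiseless and the feature sought
  is a corner, so GCV-style criteria drive the spline toward
  interpolation and produce spurious early inflections.

Both ingredients are scale-free, so δ is invariant to duplicating every
position. Fallbacks: fewer than 10 distinct coverages, or no sign change,
give δ = 0 (no filtering) with a warning. δ applies to Stacked mode only;
Concatenated relies on per-site weights.

## Synthetic generator

`ucepi.simulate` emulates the output of a UCE workflow with known truth:
k loci of length 2ℓ+1, n individuals, expected per-site diversity equal
to the Gompertz curve at every position, whole-individual missingness at
rate m, per-sequence-end uniform terminal gaps up to `edge_trim_max`
(length heterogeneity), biallelic sites by construction with uniform
background/alternate bases, and optional multiallelic injection to
exercise the filter. Calibration is exact, not asymptotic: given the
realized coverage n_i at a site, the polymorphism probability is solved so
that E[π_i | n_i] equals the target curve — in `singleton` mode one
carrier with q_i = e_i·n_i/2, in `neutral` mode a minor count drawn from
the folded neutral spectrum P(a) ∝ 1/a + 1/(n_i−a). Each locus is seeded
independently from (seed, locus index), so datasets are reproducible
byte-for-byte and loci can be generated in any order.

Defaults are the standard validation conditions used throughout the tests
and the acceptance script: k = 2000, n = 10, ℓ = 750, θ = 0.005, β = 10,
γ = 0.009 — a diversity level typical of within-population estimates and
core/recovery parameters matching the fitting initials.

What the generator does not emulate — and therefore what passing tests do
not establish about real data: linkage between sites (every site is
independent), probe-capture and bait-design bias, sequencing error,
alignment artefacts beyond simple terminal gaps, and core mis-centering.
Recovery within a few percent on synthetic data demonstrates correctness
of the estimator under its own model, not field accuracy.

## Ne conversion

Ne = θ/(4μg) with μ in substitutions/site/year and generation time g in
years. Display rounding is half-up to the nearest thousand ("64 k"),
which reproduces the published bunting/willet conversions exercised in
the tests.

## Problem sizes

The test suite runs the full pipeline at the standard 2000 × 10 × 750
conditions once (a shared session fixture) and uses 60–400-locus datasets
elsewhere; generator calibration is checked at k = 300 with a
theoretically derived standard error. The acceptance script uses the
standard conditions, the 400 × 5 condition, and a 10-vs-800-locus
subsampling experiment with 10 replicates.

## Known limitations

* The δ rule detects *a* first inflection; on coverage distributions
  without a clear tail/bulk separation the cutoff is essentially
  arbitrary (though harmless, since it then excludes little).
* u, s, r are not identifiable from a Hudson–Kaplan fit; only θ, u/4s
  and r/s are reported.
* No confidence intervals on θ̂; subsampling dispersion is the provided
  variability measure.
* Short flanks (≲ 300 bp) leave the asymptote poorly constrained and the
  estimate degrades, more severely for the generalized logistic and
  Hudson–Kaplan curves than for Gompertz.
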