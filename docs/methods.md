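# Methods

## The compositional model

A survey table holds concentrations C (samples × elements, mg/kg dry
weight). Concentrations are parts of a whole: closing a row to a constant
sum k (k = 10⁶ for mg/kg) discards no information beyond overall scale,
so all inference here is built from quantities invariant to closure —
log-ratios. Three consequences drive the design:

1. **Spurious correlation.** On closed data the covariances of part j with
   all parts sum to zero (`Σ_l cov(x_j, x_l) = 0`), so some negative
   covariances exist by construction and Pearson's r is not a trustworthy
   measure of association between concentrations. The package exposes this
   identity (`closure_covariance_residual`) and verifies it numerically.
2. **The variation matrix** `t_jl = var(ln(x_j/x_l))` is the
   closure-invariant measure of pairwise association: t ≈ 0 means the two
   elements are proportional across samples; large t means opposing
   trends. Sample variance (n−1 divisor) and natural logarithms are used
   throughout; neither convention changes any qualitative conclusion, but
   both are fixed here for cross-implementation determinism.
3. **The Aitchison distance** (Euclidean distance of centred log-ratio
   vectors) is the metric used for all sample-space structure discovery.

## Permutation-null covariability classification

For each pair the null law of t under "random pairing" is estimated by
permuting one series against the other (999 permutations by default; the
count is configurable). The observed t is pooled with the null replicates
before taking quantiles — the identity permutation is itself a permutation,
and pooling guarantees the nominal false-call rate is exactly
`alpha_low + (1 − alpha_high)` (= 2% at the default 0.01/0.99 limits)
under exchangeability, with no zero-p pathologies. Empirical quantiles use
linear interpolation of order statistics.

Because t is symmetric in its arguments, which series is permuted is pure
convention; the classifier permutes the lexicographically first element
label so the emitted label cannot depend on column order. Per-pair seeds
are derived by hashing the master seed with the sorted label pair
(64-bit BLAKE2), giving single-integer reproducibility with effectively
independent streams. No multiple-testing correction is applied across the
D(D−1)/2 pairs; the method is deliberately a per-pair screen.

Pearson's r is computed for comparison only, flagged against the analytic
critical value `r_c = t_c/√(t_c² + n − 2)` with t_c the two-sided Student-t
critical value on n−2 degrees of freedom (0.423 at n = 30, p = 0.02).

## Clustering

Divisive clustering follows the classical DIANA scheme: repeatedly split
the cluster of largest diameter by seeding a splinter with the observation
of maximal average dissimilarity and moving over points whose average
dissimilarity to the remainder exceeds that to the splinter. Split heights
are cluster diameters, so heights are monotone along root-to-leaf paths;
ties break on the lowest sample index, which (together with the
deterministic splinter rule) makes the tree invariant to sample order. The
implementation reproduces R's `cluster::diana` heights and two-cluster cut
exactly on test fixtures.

Fuzzy clustering minimises the dissimilarity-based objective
`Σ_v Σ_{i,j} u_iv^m u_jv^m d_ij / (2 Σ_j u_jv^m)` (membership exponent
m = 2, K = 2 by default) by the classical alternating update; memberships
initialise from a seeded uniform Dirichlet, iteration stops when the
objective improves by less than 1e-8 (max 500 iterations), and the
objective path is recorded so monotonicity is checkable. Marginal costs
are floored at 1e-12 to keep the update defined when a point sits on a
cluster medoid. Memberships agree with R's `cluster::fanny` to better than
0.01 on separated fixtures. When the data carry little structure the
optimum genuinely is near-uniform memberships (grades ≈ 1/K); the package
reports this honestly rather than sharpening it.

The FC contribution matrix is `FC_vk = Σ_i u_iv C_ik` (clusters × elements,
membership-weighted column sums). Indexing note: the membership factor
runs over samples within cluster v and the concentration factor over
samples for element k — the only reading under which the sum over samples
is well-formed. Per element we report both the bounded min/max component
ratio in (0, 1] (1 ⇒ the element does not distinguish the clusters, with a
dominant-cluster flag) and, for K = 2, the raw cluster-1/cluster-2 ratio.

## Summary battery and group comparison

Per element and site class: min, q₁, median, mean, q₃, max, SD, MADN
(= 1.4826 × median absolute deviation about the median; the constant makes
MADN estimate σ for Gaussian data), plus mean/median and SD/MADN ratios as
skewness/outlier diagnostics. Quartiles use linear interpolation — the
convention must be fixed somewhere, and this is numpy's default, documented
rather than assumed. The lowland/mountain comparison is the two-sided
Wilcoxon rank-sum test: exact when both groups have ≤ 10 tie-free values,
otherwise the normal approximation with tie and continuity corrections;
significance is flagged at p < 0.05.

## Zero handling

Log-ratios require strictly positive data. Censored cells (`<DL` in the
CSV dialect) are replaced multiplicatively by 65% of the per-element
detection limit before any log-ratio operation, with a replacement log
emitted; a column censored in every sample is rejected as uninformative.
The 0.65 fraction is the common compositional-geochemistry convention and
is configurable.

## The synthetic survey generator

The generator is the package's test bed: it emulates the statistical
anatomy of a two-class moss survey, not any particular site. On the log
scale each cell is

```
ln C_ik = ln(baseline_k) + λ_k F(i) + s_k · mountain(i) + ε,  ε ~ N(0, σ²)
```

with two shared standard-normal factors — "crustal" (Al, Sc, V, Fe, Co,
Cr, Th, U) and "anthropogenic" (Pb, Cd, Zn, As, Sb plus the Mn partners Mo
and Ba) — Mn loading negatively on the anthropogenic factor (a regulated
antagonist of Zn, Mo, Ba, Pb, Cd), site-class shifts (1.5× upward for As,
Ba, Ca, Cd, Cl, Cr, Cu, Mo, Pb, Sr, Zn; 1.5× downward for Mn), and
multiplicative 5× outliers in 1% of cells. Baselines are typical lowland
geometric means on real mg/kg scales. Defaults: 15 samples per class,
29-element panel, λ = 0.3, σ = 0.09.

The parameters were fixed once, by design analysis: λ/σ ≈ 3 makes
within-factor log-ratio correlation ≈ 0.92, strong enough that the
permutation classifier recovers factor-coupled pairs essentially always at
n = 30, while total within-class log-scale ≈ 0.3 keeps a 1.5-fold shift
detectable by a rank test at 15 per class. This dispersion sits at the low
end of field surveys (where geometric CVs of 50–100% occur); the generator
therefore validates the machinery under clean, well-powered conditions and
deliberately does not claim that real surveys of this size would show
equally crisp recovery. Other unmodelled features of real data: spatial
autocorrelation within parks, inter-element detection-limit censoring, and
element-specific variances.

**Ground truth.** The site-class indicator is itself a shared binary
factor, so the programmed dependence structure distinguishes three pair
classes: *strongly coupled* (shared latent factor; expected `p` for
concordant signs, `n` for Mn against its partners), *shift-coupled only*
(both elements shifted; genuinely dependent but weakly, labelled with the
coupling sign and `strong = False`), and *independent* (no shared factor,
no shared shift; expected `r`). Recovery statistics are quoted on the
strongly coupled pairs, and false-positive rates on the truly independent
pairs; shift-only pairs belong to neither denominator.

## Numerical and degenerate-input choices

- Closure checks use relative tolerance 1e-9 (double-precision round-trip).
- The CSV reader parses numbers with Python's correctly rounded `float`,
  so written fixtures round-trip bit-exactly.
- A constant series has zero log-ratio variance against anything; its
  permutation null is degenerate (all replicates equal the observed t) and
  classifies as `p` by the ≤ convention — flagged to users via the
  small-sample warning path rather than special-cased.
- Distances: symmetry is required to 1e-8 relative; tiny negative squared
  distances from cancellation are clipped to zero.
- Fuzzy non-convergence returns the last iterate with `converged_ = False`
  and a warning, never an exception.

## Problem sizes in the validation suite

The shipped checks run 20 default surveys × 406 pairs × 999 permutations
for label recovery, 1000 independent pairs for null calibration, 1000
random triples for the metric axioms, 100 random closed tables for the
covariance identity, and complete enumeration for rank-sum group sizes up
to 6 — sizes chosen so the whole suite completes in well under a minute
while keeping binomial noise small relative to the margins being checked.
One caveat is inherent to the null-calibration check: the non-random rate
over 1000 replicates has a Monte-Carlo standard error of ≈ 0.0044, so its
±0.005 window around the nominal 0.02 is a ~1σ band; the shipped seed is
fixed and the quantity is recomputed, not tuned.

## Known limitations

- The permutation classifier is a marginal per-pair screen; it inherits
  the variation matrix's blindness to multivariate structure beyond pairs
  and applies no familywise control.
- DIANA and the fuzzy objective both operate on the distance matrix only;
  no compositional centring or balance selection is attempted beyond the
  Aitchison geometry itself.
- The generator's factor model is linear on the log scale with
  homoscedastic noise; it is a validation instrument, not a deposition
  model (no altitude, precipitation or emission physics).
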