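# Methods

## The dispersion model

A set of `M ≥ 2` sequencing lanes over `N` bins is modelled, under the
hypothesis of faithful technical replication, as independent Poisson counts
`y_ij` whose means factorise into a bin effect and a lane-depth effect.
The maximum-likelihood fit under that hypothesis is the margin product
`ŷ_ij = E_i·L_j/T`, and the Pearson dispersion of a bin,

    s_i² = 1/(M−1) · Σ_j (y_ij − ŷ_ij)²/ŷ_ij ,

has expectation 1 under the null (the divisor is `M−1` because each bin's
deviations sum to zero across lanes once `E_i` is fixed).  SERE is the
square root of the average of `s_i²` over the bins retained after two
filters:

* **Zero bins** — bins with `E_i = 0` over the compared lanes are dropped;
  they carry no information.  For `M > 2` the pair rule generalises to
  "zero in *every* compared lane".
* **Singletons** — bins with `E_i = 1` have `s_i² = 1` exactly when lane
  totals are balanced, regardless of whether the samples agree, so by
  default they are excluded from both the numerator and the divisor of the
  average.  Margins (`L_j`, `T`) are recomputed from the retained bins;
  this makes singleton exclusion *exactly* neutral (adding singleton bins
  leaves the statistic bit-identical), which is the invariant the tests
  assert.  The alternative — keeping full-data margins — would differ by
  O(#singletons/T), far below any practical resolution.

Scores read as: 1 pure Poisson replication, >1 overdispersion (real global
differences), <1 underdispersion (excess agreement), 0 identity.  Lanes
with a zero total are rejected rather than dropped: an empty lane is
exactly the kind of upstream failure the statistic exists to catch.  All
accumulation is in double precision with no intermediate rounding.

## Confidence intervals

Extending the classical theory of Poisson dispersion tests, `(M−1)·s_i²` is
chi-square with `M−1` degrees of freedom and noncentrality
`Σ_j L_j²(p_ij − p̄_i)²`-type divergence when the true per-lane bin
fractions `p_ij` differ from the pooled fraction `p̄_i`; summing over bins,
`ν·s²` with `ν = n_used·(M−1)` is (non)central chi-square with `ν` degrees
of freedom.

Two interval modes are provided:

* **noncentral** (default): test inversion on the noncentrality λ — find
  `λ_lo ≤ λ_hi` (floored at 0) at which the observed `ν·s²` sits at the
  `1−α/2` and `α/2` tail quantiles of `χ²(ν, λ)`, then map to the SERE
  scale through the mean relation `E[χ²(ν,λ)] = ν+λ`, i.e.
  `bound = √((ν+λ)/ν)`.  The solver brackets λ by doubling and finishes
  with Brent's method on the monotone CDF.  Because the noncentral family
  only represents dispersion ≥ 1, the interval describes the model-implied
  SERE: it contains the point estimate exactly when `s ≥ 1` (then
  `λ̂ = νs²−ν` lies inside the inverted set), and degenerates toward
  `[1, 1]` for strongly underdispersed data — itself a diagnostic, since
  underdispersion is incompatible with the sampling model and points to
  duplication.
* **null**: central chi-square quantile scaling of the point estimate,
  `s·√(χ²_q(ν)/ν)`.  Always brackets `s`; width shrinks as `O(ν^(−1/2))`.

At the scale of a real exon-level comparison (`ν ≈ 2×10⁵`) both modes give
99% intervals a few thousandths wide.

## Comparator statistics

* **Pearson's r**: computed on `log10` of RPKM after adding a pseudo-count
  of one read (the common convention); `log-count-pseudo` and `sqrt-count`
  (the Poisson variance-stabilising transform) variants are provided for
  sensitivity checks.  r is invariant to the log base.
* **Cohen's kappa**: counts are normalised to RPKM *without* a pseudo-count
  (so the zero category stays reachable) and assigned to the 9-category
  ladder 0, 1–10, 11–20, 21–40, 41–80, 81–160, 161–320, 321–1000, >1000
  RPKM.  The printed category bounds are resolved as the half-open
  partition {0}, (0,10], (10,20], (20,40], (40,80], (80,160], (160,320],
  (320,1000], (1000,∞): exhaustive, disjoint, and consistent with the
  conventional labels; values on a threshold belong to the lower category.
  Continuous values are binned directly (no integer flooring).  A linearly
  weighted kappa (`w_ab = |a−b|/(K−1)`) is included; it reduces to simple
  kappa at K=2.
* When bin lengths are unknown (pure simulations over one shared bin set)
  unit lengths are used, making the "RPKM" scale reads-per-million × 10³;
  the bin edges then apply to that scale.  Length normalisation affects
  neither SERE (raw counts only) nor the rank structure within a common
  bin set.
* All-zero bins are excluded before all three statistics, so every
  statistic sees the same bin universe.

Both comparators are implemented from their defining formulas on the
contingency table / transformed vectors; an external implementation
(scikit-learn's kappa) is used in the test suite only, as an independent
cross-check.

## Pairwise comparison and clustering

SERE generalises to any number of lanes at once; it can also be computed
per pair, re-applying the zero-bin and singleton filters within each pair
(a bin empty in both members of a pair is uninformative *for that pair*).
The multi-lane statistic filters over the full lane set — the documented
default for grouped comparisons.  The pairwise matrix (diagonal 0: a lane
against itself is a duplication) serves as a dissimilarity for
agglomerative clustering, average linkage by default (single and complete
are available; no linkage is canonical for this dissimilarity).  Merge
heights are directly interpretable as excess dispersion: replicate lanes
merge near 1, duplicated lanes at 0, different conditions well above 1.
Trees export to Newick via scikit-bio; following its linkage-tree
convention each tip sits at half the merge height, preserving the
ultrametric structure.

## The simulation framework

Sampling reads without replacement from a pool of counted reads is exactly
a multivariate hypergeometric draw on the per-bin totals, so the simulator
works on count vectors; lanes are drawn sequentially from the shrinking
pool, making them disjoint subsets of the pooled reads (an
independent-draws mode exists for theory checks, but note that two
*independent* without-replacement draws from a finite pool are
systematically underdispersed — the disjoint construction is what makes a
split a perfect replicate pair).  In the contamination design the clean
portion of the second lane is likewise drawn from the pool depleted of the
first lane, so the 0%-contamination arm is exactly a perfect-replicate
pair; contaminant reads are drawn from a second pool, with
`round(fraction·n_reads)` contaminant reads so totals are exact.

**Synthetic pools.**  Per-bin abundances are log-normal(0, σ) and the
pool's counts are one multinomial allocation of `pool_size` reads.
Defaults are 222,097 bins and 22.9×10⁶ reads — the scale of a pooled
three-lane exon-level experiment — with σ = 1.6, calibrated once against
the skew diagnostics of real exon-level data at a 5.5×10⁶-read subsample:
~56% of observed bins at count ≤ 10 (empirical reference ≈ 55%) and a
maximum bin count of order 10⁴.  A single log-normal cannot simultaneously
match the empirical bulk, the extreme maximum (~10⁵) and the singleton
fraction (~12% at 5×10⁶ reads; the synthetic pool gives ~7%); the bulk and
the tail order were prioritised.  Consequences: absolute values of *r* and
kappa on synthetic data differ from those on any particular real dataset
(they depend on the abundance profile by design — that is their flaw), so
tests assert their *qualitative* behaviour (monotone degradation with
depth, maxima at equal splits) and only SERE's calibration is asserted
quantitatively.  What the synthetic pools do not emulate: positional/GC
bias, mappability structure, bin-length correlation with abundance, and
biological variance between libraries — so passing tests demonstrate the
statistics' sampling-theoretic properties, not robustness to those
artefacts.

**Contaminant pools** multiply the main pool's abundances by an independent
log-normal(0, divergence) factor; divergence = 0.3 by default, a modest
fold-change dispersion of the kind seen between biological replicates
(full-contrast SERE ≈ 1.4 under the defaults).  Divergence 0 gives two
count realisations of the same profile — the negative control, which stays
at SERE ≈ 1 for every contamination fraction.

**Reproducibility.**  One master `SeedSequence` per experiment spawns a
pool stream and one child stream per (condition, replicate), so reports are
bit-identical given a configuration and seed, and conditions may be
reordered without changing per-realisation draws.

## Problem sizes in the default test run

Full study conditions are 200 realisations per condition at 222,097 bins.
The test suite uses them where the claim is about the calibration of the
statistic itself (the 200-pair perfect-replicate run at 5×10⁶ reads per
lane); for the depth/split/contamination sweeps, whose effects are hundreds
of standard errors wide, 25–30 realisations per condition are used, keeping
the default suite at a few minutes on one CPU while leaving every asserted
effect with overwhelming margin.  The chi-square calibration check uses
1,000 simulated statistics at 200 bins with per-bin Poisson rates in
[20, 100] — large enough for the chi-square asymptotics, small enough that
the Kolmogorov–Smirnov comparison is instantaneous.  `scripts/acceptance.py`
always runs the full 200-realisation, full-bin-count configuration.

## Known limitations

* SERE addresses *global* agreement; per-gene differential testing with
  biological variance models (negative binomial GLMs) is deliberately out
  of scope.
* The noncentral CI mode does not bracket point estimates below 1 (see
  above); use the null mode when a symmetric-coverage interval around an
  underdispersed estimate is needed.
* The advisory report labels (SERE < 0.9 "possible duplication", > 1.1
  "global difference") are heuristics for human readers, not decision
  thresholds.
* Raw integer counts are required; normalised inputs are rejected because
  the Poisson model does not apply to them.
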