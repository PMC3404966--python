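# Methods

## Model and rationale

A miRNA that degrades its target mRNA suppresses the co-occurrence of high
miRNA and high target expression.  When the miRNA is the dominant regulator
the two profiles are linearly anti-correlated; when other regulators,
copy-number changes or tissue composition also move the target, the joint
scatter instead fills a triangle whose high/high corner is empty.  The
package scores that corner depletion directly rather than fitting a line,
so it detects silencing relationships that Pearson correlation misses, at
the price of needing more samples than a parametric test.

## The antagonism statistic

Both vectors are z-scored per feature (mean 0, unit sample SD with the
n−1 denominator; constant vectors are rejected and must be filtered out
upstream).  Writing $s_i = x_i + y_i$ for the per-sample sums:

- $F_{\mathrm{obs}}(b)$ is the fraction of samples with $s_i < b$ — the
  empirical CDF of the sums with strict inequality, so points on the line
  count as "not below".
- The null reference $\bar F_{\mathrm{null}}(b)$ is the pooled empirical CDF
  of the sums of $K$ random re-pairings of the two vectors ($K = 100$ by
  default).  Pooling is exact: the mean of $K$ step CDFs equals the CDF of
  the pooled sample.
- The coefficient is $A = \sup_b [F_{\mathrm{obs}}(b) - \bar
  F_{\mathrm{null}}(b)]$, floored at 0 (the value for $b$ below every sum).

**Candidate intercepts.**  The difference of two step CDFs is non-increasing
between jumps of $F_{\mathrm{obs}}$, so the supremum over all real $b$ is
attained in the right limit at an observed sum.  The implementation
evaluates only those $N$ right limits with two `searchsorted` passes; the
test suite proves this equal to exhaustive enumeration over the union of all
observed and shuffled sums.

**Null-pool construction.**  Shuffles are applied to *sorted* copies of the
vectors and drawn as permutation/inverse pairs.  The pool then depends only
on the two value multisets, which makes the coefficient exactly invariant
to relabelling the samples and — for an even shuffle count, the default —
to exchanging which vector is called x and which y.  The pairing makes the
$K$ re-pairings mildly dependent ($K/2$ independent draws, each used as
$\pi$ and $\pi^{-1}$); the pooled curve remains an unbiased estimate of the
re-pairing null and the loss of averaging efficiency is negligible at
$K = 100$.

**Permutation p-value.**  The p-value compares $A$ with the coefficients of
$M$ random re-pairings ($M = 1000$ by default) and uses add-one smoothing,
$PV = (1 + \#\{A_p \ge A\})/(1 + M)$, so $PV \ge 1/(M+1)$ and downstream BH
adjustment never sees a zero.  One deliberate numerical choice: the null
reference curve is estimated **once** per pair and shared by the observed
statistic and every permutation replicate.  The statistic is then a fixed
function of the sample pairing, which (a) makes the permutation test exact
— under the null all pairings are exchangeable, so $PV$ is uniform on its
grid, as the type-I and uniformity tests verify — and (b) removes a factor
$K$ from the cost.  Re-drawing the pool per replicate would only add noise
symmetrically.

**Scan.**  `scan_all_pairs` scores the full miRNA x gene Cartesian product.
Every pair consumes its own seed substream spawned from the caller's seed,
so serial and parallel (joblib) execution give identical output.  BH
q-values are attached across all pairs; the default edge threshold is
q <= 0.02.

## Synthetic data and benchmark

`simulate_pair(n, noise, seed)` draws `n - round(noise*n)` points uniformly
on the triangle {x,y >= 0, x+y <= 1} and exactly `round(noise*n)` points on
the complementary triangle, both by rejection sampling from the unit square
(exactly uniform, no transform subtleties).  The noise count is fixed per
dataset, not Bernoulli, so the generator invariants are exact.  `null_mode`
draws uniformly on the whole square — the same distribution the generator
reaches at noise 0.5, since the two triangle components then tile the
square with equal density.  In that regime the coordinates are independent,
so any valid permutation p-value is uniform and its mean is ~0.5; the
benchmark's worst-noise cell is therefore a calibration check, not a power
check.

The benchmark scores each simulated pair through the identical z-score +
permutation pathway used for real data (whether the original analysis
standardized simulated values is not documented; applying the one shared
pathway keeps the scoring uniform and is flagged here as an
interpretation).  Per-cell RNG streams derive from (seed, cell index,
replicate index), so single cells are reproducible in isolation.  Default
problem sizes — 200 datasets per cell, 500 permutations, 100 null shuffles
— give a Monte-Carlo standard error on a mean p-value of well under 0.01 in
the low-p regime and complete in seconds per cell; the statistical tests
allow a ±0.05 Monte-Carlo band on mean p-values and ±0.03 on rejection
fractions.

What the simulator does *not* emulate: platform-specific noise
distributions, batch effects, correlated genes, or compression of the
dynamic range.  Passing benchmarks show the statistic's intrinsic power on
an idealized triangular signal, not its accuracy on any particular array
platform.

## Correlation baseline

`loo_corrected_pearson` computes the n leave-one-out coefficients
$r_{(-k)}$; sample k is an outlier when $|r_{(-k)} - \overline{r}| \ge 2\,
\mathrm{sd}(r_{(-\cdot)})$ (sample SD).  The coefficient is recomputed once
on the retained samples — a single pass, no iteration — and its p-value
comes from the exact t transform at the effective n.  Two degenerate cases:
exactly linear data give sd = 0, in which case no sample "deviates" and
nothing is flagged; if removal would leave fewer than 3 samples the raw
coefficient is returned with `all_flagged=True`.  The sign of r is kept so
the negatively correlated network component can be selected downstream
(FDR 0.1 by default for the comparison network).

## Network and hubs

Connectivity is the per-node edge count of the significant-pair table.
Hub cutoffs are calibrated per node class on a network rebuilt by the same
scan from data in which the mRNA matrix's sample order was globally
shuffled (one permutation, drawn from its own substream).  The default rule
is cutoff = 0.75 x (maximal connectivity in the randomized network); the
alternative reading, the 75th percentile of the randomized connectivity
distribution, is available as `rule="percentile75"`.  The scaled-max rule
is the default because it is the only reading in which "of the maximal
value" carries content.  Rank-based method comparison uses deterministic
ordering (p-value, then |score| descending, then pair id) and min-rank
merging across methods.

## Seed and gene-set enrichment

Seed matches are derived from the first eight nucleotides of the mature
miRNA (position 1 inclusive; `offset=1` shifts the window one base toward
the canonical positions 2-9 definition), taking every contiguous 6/7/8-mer
window and reverse-complementing into DNA.  Occurrences in 3'UTRs are
counted with an overlapping sliding window; when a gene has several UTR
isoforms the longest is used.  Enrichment sums raw counts over all
predicted pairs and permutes the miRNA column of the edge list (preserving
each miRNA's edge count and the UTR multiset exactly); significance is the
one-sided normal tail at the shuffle mean and SD, with a degenerate flag
when the statistic is permutation-invariant (null SD 0).

Gene-set enrichment is the upper-tail hypergeometric test per (miRNA
target set, category), with the universe defined as the genes that
survived expression filtering — the population actually eligible to be
predicted.  No DAG propagation is performed and no multiple-testing
correction is applied inside the GO scoring by default (BH is available by
flag); instead the label-shuffle control permutes target labels at fixed
miRNA connectivity and reports how often categories pass the real-data
threshold (default 0.001).

## Filtering and I/O

Features are kept when their across-sample IQR strictly exceeds the median
IQR of all features; ties are excluded so the rule is deterministic.  An
optional quantile floor on the feature median stands in for
platform-specific low-abundance filters.  Expression tables are TSV
(features x samples); missing-value rows are dropped with a log line when
the paired set is assembled, and non-numeric cells are reported by feature
and sample id.  The pipeline writes every stage table plus a JSON manifest
of parameters and per-stage counts; reruns at the same seed are
byte-identical.

## Known limitations

- The statistic is one-sided by design: it detects depletion of high sums
  (the antagonism corner) and ignores the mirrored "agonist" pattern.
- Power at typical cohort sizes is modest: ~40 samples are needed
  for 5%-level detection of a clean triangle, and ~50-60 with 10% noise.
- Perfect linear anti-correlation is an extreme triangular pattern and is
  scored as strongly antagonistic; the method separates itself from
  correlation on non-linear cases, not by excluding linear ones.
- Normalization of raw arrays is out of scope; inputs must already be
  comparable across samples.
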