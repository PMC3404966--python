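# mirantag

**Antagonism-pattern detection of miRNA-target interactions from paired
expression profiles.**

MicroRNAs silence their target mRNAs, but in heterogeneous samples (tumors in
particular) the miRNA is rarely the only regulator in play, so the joint
expression of a miRNA and a true target need not look linearly
anti-correlated.  What silencing does leave behind is an *asymmetry*: samples
where both the miRNA and the target are simultaneously highly expressed are
depleted, and the joint scatter takes a triangular shape.  `mirantag`
implements a permutation-calibrated statistic that recognizes this triangular
"antagonism pattern" in paired miRNA / mRNA expression matrices, and the
surrounding analysis toolkit:

- a synthetic-data generator and power benchmark for the statistic
  (triangular pairs with a controlled noise fraction);
- a leave-one-out-corrected Pearson baseline for method comparison;
- Benjamini-Hochberg FDR control, bipartite network assembly and hub
  detection calibrated on a sample-shuffled twin network;
- 3'UTR seed-match counting and enrichment against miRNA-to-target
  assignment shuffles;
- hypergeometric gene-set (GO-style) enrichment with a label-shuffle
  negative control.

## The statistic

For a miRNA with z-scored expression $x_i$ and an mRNA with z-scored
expression $y_i$ over the same $N$ samples, consider the anti-diagonal line
$x + y = b$ and the fraction of samples strictly below it,

$$F_{\mathrm{obs}}(b) = \frac{1}{N}\,\#\{\,i : x_i + y_i < b\,\},$$

which is the empirical CDF of the sums $x_i + y_i$.  Let
$\bar F_{\mathrm{null}}(b)$ be the same fraction averaged over $K$ random
re-pairings of the two vectors (default $K = 100$): the value distributions
are preserved but the association is destroyed.  The **antagonism
coefficient** is the one-sided Kolmogorov-Smirnov-type supremum

$$A = \max_b\,\bigl[F_{\mathrm{obs}}(b) - \bar F_{\mathrm{null}}(b)\bigr],$$

searched exhaustively over the breakpoints of the step functions, with $b^*$
the maximizing intercept.  A triangular pattern concentrates the observed
sums below the line relative to random pairings, so $A$ measures exactly the
depletion of the high/high corner.  Significance comes from a permutation
test: the coefficient is recomputed for $M$ random re-pairings (default
$M = 1000$) and

$$PV = \frac{1 + \#\{A_p \ge A\}}{1 + M}.$$

Pairs passing a BH FDR threshold (default 2%) become edges of a bipartite
miRNA-gene network; hubs are nodes whose degree exceeds 0.75x the maximal
degree found in a network rebuilt from sample-shuffled data.

See `docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

```python
import numpy as np
from mirantag import simulate_pair, StandardizedPair, antagonism_pvalue

sim = simulate_pair(60, 0.1, seed=7)           # 60 samples, 10% noise points
pair = StandardizedPair.from_raw(sim.x, sim.y, mirna_id="sim-miR", gene_id="sim-gene")
score = antagonism_pvalue(pair, n_permutations=1000, rng=1)
print(f"A = {score.coefficient:.4f}  b* = {score.best_intercept:.4f}  PV = {score.pvalue:.4f}")
```

prints

```
A = 0.1415  b* = 0.8927  PV = 0.0020
```

read as: at the best intercept $b^* = 0.89$ (on the z-scored sum scale) the
observed below-line fraction exceeds its re-pairing null by 14 percentage
points, and only about 0.2% of random re-pairings reach a coefficient that
large — the triangular pattern is highly significant with 60 samples.

The same is available from the shell; the benchmark prints the mean
permutation p-value per (sample size, noise) cell:

```sh
$ mirantag benchmark --sizes 40,80 --noise 0,0.2 --datasets 50 --perms 200 --seed 1 --out grid.tsv
noise        0.0    0.2
n_samples
40        0.0268 0.2303
80        0.0050 0.0676
```

Detection sharpens with more samples and degrades with noise.  A full scan
of two expression matrices (`mirantag detect --mirna ... --mrna ...`), the
correlation baseline (`correlate`), hub analysis (`network`), seed
enrichment (`seeds`), gene-set enrichment (`enrich`) and the end-to-end
pipeline (`run`, which also writes a JSON run manifest) follow the same
pattern; see `mirantag --help`.

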