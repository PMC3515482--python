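# Methods

## Scope and model

`pathgwas` evaluates whether GWAS association signal concentrates in
predefined gene categories (GO terms, KEGG pathways, any GMT file).  It
consumes per-SNP summary statistics only — SNP id, chromosome, position,
association p-value — never genotypes; linkage disequilibrium enters
exclusively through a pairwise r² table.  All internal coordinates are
1-based inclusive; BED input is converted at the boundary.

Two enrichment methods share one substrate and differ in their statistic:

* **Overrepresentation** counts genes tagged by significant pruned SNPs
  and compares the count per category to random replicate gene lists.
* **Corrected-score GSEA** ranks genes by a confounder-corrected best-SNP
  Z-score and tests each category's leading-edge count by permutation.

Both are permutation methods: no distributional assumption is placed on
the SNP p-values beyond exchangeability under the null.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| flank | 20,000 bp | gene window extension on each side, inclusive bound |
| r² cutoff | 0.2 (strict >) | LD pruning threshold |
| LD window | 1,000,000 bp (inclusive) | maximal distance at which pruning applies |
| SNP thresholds | 0.001, 0.005, 0.01, 0.05 (strict <) | significant-gene selection |
| category size filter | [3, 500] after intersection, inclusive | testable categories |
| replicates R | 50,000 | null gene lists per study |
| bootstrap | 1,000 iterations × 5,000 subsampled lists | study-wide p and excess statistic |
| category thresholds | 0.005, 0.01, 0.05 | excess-of-enrichment levels |
| GSEA cutoff | 0.95 rank fraction | leading-edge definition |
| GSEA permutations | 10,000 | nominal p resolution |
| stepwise entry/removal | 0.05 / 0.10 (partial-F p) | confounder selection |
| proximity gap | 1,000,000 bp edge-to-edge, chained | gene collapsing |
| Stouffer weights | √n_subjects | meta-analysis weighting |

Defaults follow the published scale of each procedure; the test suite and
the acceptance script run R between 2,000 and 5,000 and bootstrap sizes of
a few hundred to two thousand, which keeps every run within seconds while
leaving Monte-Carlo error well inside the asserted tolerances.

## Numerical and algorithmic choices

**Empirical p-values** use the add-one estimator (r+1)/(R+1): never zero,
floor 1/(R+1), ties counted as extreme (`≥ observed`).  With a 5,000-list
subsample the study-wide floor is 1/5001 ≈ 2.0e-4.

**Pruning order.** "Keep the most significant SNP of a correlated group"
is implemented as greedy elimination by ascending p, ties broken by
position then SNP id — the standard clumping reading, and the order makes
the output deterministic and maximal (no removed SNP can be restored
without violating the constraint).  Missing LD pairs count as r² = 0,
matching the convention that LD tables omit sub-threshold pairs.

**Replicate sampling.** Lists are built by sampling SNPs, not genes, so
SNP-dense genes enter replicate lists with the same elevated probability
they have of entering the observed list.  A draw that would push the list
past n is rejected and sampling continues (exact-n lists keep counts
comparable); non-tagging SNPs consume a draw and add nothing.  If a
permutation of the pool strands the list short of n (possible when only
multi-gene SNPs remain), sampling restarts with a fresh permutation.

**Bootstrap comparisons** use `≤` when comparing a pseudo-study's most
significant category p to a category's empirical p, and `<` when counting
categories below an enrichment threshold, mirroring the strict thresholds
used for observed categories.

**Discreteness.** Replicate counts are small integers, so empirical
p-values live on a lattice.  Two consequences are documented rather than
hidden: (i) a continuous-uniform KS test applied directly to null category
p-values is miscalibrated, so calibration diagnostics use the standard
randomized construction p = (#{count>obs} + U·(1+#{count=obs}))/(R+1),
exactly Uniform(0,1) under a calibrated null (`randomized_empirical_p`;
reported p-values remain the conservative lattice version); (ii) the
study-wide p of a category tracks its empirical p only up to the
probability atom at the observed count.

**Stepwise regression** adds the covariate with the smallest partial-F
p-value while below the entry threshold and removes the worst while above
the removal threshold (with one regressor the partial F equals the squared
t, so OLS coefficient p-values are used).  Constant covariates are
excluded a priori.  The corrected score is the unit-variance residual; if
nothing enters, the standardized raw Z.  Hotspot and genetic-map tracks
are optional and default to zero density; LD units per kb is an external
construct exposed as an optional per-gene input rather than computed.

**Rank fraction** is `rankdata(z)/N` (average ties), so "top 5%" means
rank fraction ≥ 0.95 and the statistic depends on corrected scores only
through their ranks.

**Weighted-Z combination** requires p strictly inside (0,1); the
study-level combination table leaves rows with a ceiling p of exactly 1 as
NaN rather than transforming them.  FDR is Benjamini–Hochberg;
permutation-based FDR is out of scope.

**Determinism.** Every stochastic function takes a `numpy` Generator or
seed; the simulator and pipeline split independent streams from one root
`SeedSequence` in a fixed order, so identical configuration + seed
reproduces outputs byte for byte on any platform.

## The synthetic benchmark

`simulate_dataset` emulates exactly the structure the methods assume:
genes laid out sequentially with drawn spans/gaps, SNPs uniform within
flanked windows (plus optional non-tagging intergenic SNPs), block LD with
constant within-block r² (all within-block pairs emitted), null SNP
p-values Uniform(0,1), and planted categories in which a chosen fraction
of member genes each carry one causal SNP with p ~ Beta(a, 1), giving the
analytic tail Pr(p < t) = t^a.  Signal can be shared across studies or
redrawn per study.  Default study sample sizes (4038 / 2014 / 5198) follow
the family, case-control and population-cohort trio the replication design
targets.

What the generator does **not** model: realistic allele frequencies or LD
decay, family structure, imputation error, overlapping samples between
studies, or correlation between gene size and signal.  Passing tests
therefore demonstrate the statistical machinery — calibration, power
against the planted alternative, oracle agreement — not robustness to
those real-data complications.

## Problem sizes in tests and the acceptance script

Null calibration runs 20 seeds of a 2,000-SNP / 200-gene / 100-category
study at R = 2,000.  Planted-signal recovery runs 20 seeds of two studies
over 2,000 single-SNP genes with one planted 20-gene category (40% signal
genes, Beta(0.15,1)), SNP threshold 0.005, R = 2,000, overlap bootstrap
2,000 × 1,000 — a configuration chosen by power analysis: the planted
category's null count mean (≈0.14) leaves a wide probability gap between
"one hit" (p ≈ 0.13) and "two hits" (p ≈ 0.009), so the planted category
is detected at the 0.05 category threshold almost surely while remaining
rare under the null.  Exhaustive oracles (replicate-list enumeration over
all SNP orderings; all C(20,4) leading-edge samples) bound Monte-Carlo
estimates within three binomial standard errors.

## Known limitations

* The overlap-significance statistic is coarse when few categories are
  enriched in the conditioning study: with a single common category its
  value is essentially the conditioning category's largest sub-threshold
  null atom, so it cannot fall far below ~0.01 however strong the signal —
  a granularity limit of the count statistic, not an implementation issue.
* Stepwise covariate selection inherits the usual instability of stepwise
  procedures at small gene counts (< a few hundred genes).
* Collapsed-entity counting loops per category in Python; it is intended
  for the moderate category counts typical of collapsed re-analyses.
* Gene categories are flat sets; ontology structure (term nesting) is not
  modeled, so Bonferroni correction across nested GO terms is
  conservative.
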