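# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limitations of `netprio`.

## Gene scoring

### Weighted chi-square GWAS scores

A gene's statistic is T<sub>sum</sub> = Σ z<sub>i</sub>² over the SNPs within the gene body
± 50 kb (1-based inclusive coordinates at both window ends; strand is
ignored for windowing). Under the null z ~ MVN(0, Σ) with Σ the local LD
correlation matrix, T<sub>sum</sub> is distributed as Σ λ<sub>j</sub> χ²<sub>1,j</sub> with λ<sub>j</sub> the
eigenvalues of Σ (clipped at zero below 1e-10). The survival function is
evaluated by Imhof-type quadrature on the characteristic-function
inversion integral (absolute tolerance ~1e-13). The oscillatory integral
loses all relative accuracy in the far tail, so whenever the estimate is
below 1e-14 *or* within ten times the quadrature's own error estimate,
the implementation switches to the Lugannani–Rice saddlepoint
approximation of the cumulant generating function. Equal weights reduce
analytically to the χ²<sub>k</sub> tail and are special-cased.

### QTL-GWAS Mendelian randomization

Harmonization aligns effect alleles between the exposure (QTL) and
outcome (GWAS) tables: swapped alleles flip the outcome beta and
complement its frequency; palindromic (A/T, C/G) SNPs and pairs with an
allele-frequency difference above 0.05 are removed; irreconcilable
allele pairs are dropped with a warning count. The operation is
idempotent.

Instruments require exposure p < 1e-6 and pairwise LD r² < 0.01; the
selection is greedy in ascending exposure p (the selection order within
these constraints is a design choice of this package). The Steiger
filter approximates the variance explained on each side as
r² = z²/(z² + n) and removes an instrument iff the outcome r² exceeds
the exposure r² with a one-sided Fisher-z test significant at α = 0.05
(default; the exposure and outcome samples are treated as independent).
The IVW estimate is the fixed-effect combination of Wald ratios
β<sub>out</sub>/β<sub>exp</sub> with first-order standard errors se<sub>out</sub>/|β<sub>exp</sub>| — no NOME
correction and no random-effects model, the simplest defensible flavor.
Tissue-level results aggregate by minimum p (ties broken by tissue
label). Input p-values of exactly zero are clamped to 1e-300 so the
z-transform stays finite.

## Network diffusion

The random walk with restart solves p<sub>∞</sub> = (I − (1−r)W)<sup>−1</sup> p<sub>0</sub> with W the
column-normalized weighted adjacency matrix. The resolvent is
implemented as printed — without the conventional leading factor r —
and p<sub>∞</sub> is renormalized to sum to one; since only ranks and normalized
probabilities are consumed, the missing scalar factor is irrelevant.
Three numerical paths exist:

* **analytic** — dense LU below ~2,000 nodes; above that, BiCGSTAB
  (rtol 1e-12) on the sparse system. Direct sparse factorization is
  deliberately avoided: scale-free graphs cause catastrophic fill-in
  (a 20,000-node solve went from minutes to ~10 ms).
* **iterative** — the fixed-point iteration p ← (1−r)Wp + rp<sub>0</sub>,
  tolerance 1e-10, cap 1e5 iterations, converging geometrically at rate
  (1−r).
* **r = 0** — the printed inverse is singular; the restart-free limit is
  the stationary distribution of W, computed by lazy-walk power
  iteration ((W+I)/2 shares the stationary vector but is aperiodic, so
  bipartite graphs converge). This limit equals the degree-proportional
  distribution on connected undirected graphs, which is why the
  weighted-degree baseline is the r→0 anchor of the benchmark. A
  disconnected graph is an error at r = 0.

p<sub>0</sub> assigns each scored gene z² with z = Φ<sup>−1</sup>(1 − p/2) and exactly zero
to genes the method could not test. The diffusion background is the
network's node set; an optional mode appends method-background genes
missing from the network as isolated zero-score nodes (they receive no
mass but widen the evaluation background — relevant when the testable
set is itself enriched for targets, as with plasma-proteome panels).

## Target sets and evaluation

Target sets are the per-trait union of target genes over indicated
drugs, after optional filters: interaction confidence ≥ 700 and type in
{inhibition, activation} (both applied only where the column exists).
Identifier reconciliation is a generic two-column map; database-specific
ETL is out of scope. Traits without surviving targets keep an empty,
flagged set so the OR fallback path is exercised downstream.

Fisher enrichment restricts targets to the background first, computes
the exact two-sided hypergeometric p on the raw table, and then applies
two conventions to the cross-product odds ratio: a = 0 ⇒ OR := 1 (the
standard error is then undefined and imputed at aggregation time); a
zero main-diagonal cell (a or d) is set to 1 before the OR and its
Woolf standard error √(1/a+1/b+1/c+1/d). The two-sided binomial test
for background enrichment uses the minimum-likelihood convention. The
AUC uses the midrank (tie = ½) formula with DeLong standard errors;
a 12-observation fixture is pinned to R pROC to 1e-10. Ties at
top-percentile boundaries break lexicographically by gene id, making
prioritized sets deterministic; tied-rank min–max ranges are available
for display. Between-method concordance uses the common scored-gene
background and the percentile grid (0.1, 0.2, 0.5, 1, 2, 3, 5, 7.5,
10)%.

## Aggregation

Observations are ordered database-major / trait-minor, matching
R = R<sub>db</sub> ⊗ R<sub>trait</sub>; the layout is validated at runtime. var(b̄) =
**1**′SRS**1**/m². A correlation matrix that fails the PSD check (below
−1e-8) is projected to the nearest PSD correlation with a warning. The
difference test plugs the empirical Pearson correlation of the paired
observation vectors into the covariance approximation; a nonpositive
variance of the difference raises with diagnostics rather than being
clamped. Fallback observations (OR := 1) contribute b = 0 with the
maximum finite standard error of the method's vector — conservative
weighting without dropping cells.

**Calibration caveat:** the empirical-correlation plug-in is calibrated
at the benchmark's composition (m = 150: type-I error within binomial
error of 0.05 over 10⁴ null replicates) but is anti-conservative at
small m (≈0.08 at m = 10), because the sampling noise of r̂ (sd ≈ 1/√m)
leaks into the variance of the difference. The test should not be used
with fewer than a few dozen cells.

## Synthetic-data generator

No public generative model exists for the real inputs, so all generator
choices are explicit stand-ins. Defaults are fixed study conditions,
not tuning knobs:

* **Universe** 19,430 genes (the protein-coding autosomal count used as
  the default enrichment universe); per-method testable backgrounds of
  0.986 / 0.646 / 0.096 / 0.968 of the universe for GWAS / eQTL-GWAS /
  pQTL-GWAS / Exome, mirroring the very different testable-gene counts
  of the real data sources (~19,150 / ~12,550 / ~1,870 / ~18,800).
* **Disease genes** 2.5% of the universe per trait, drawn around a
  shared core (10% of each set common to all traits, inducing a mild
  between-trait correlation); their p-values come from |N(μ,1)| mapped
  through the null, p = 2Φ(−|z|); all other genes are U(0,1].
* **Drug targets** 2% of the universe per trait, of which 15% are
  disease genes. This split is what keeps undiffused AUCs in the
  51–57% band seen in real benchmarks: most targets have no direct
  genetic support, so threshold-free performance is weak even when the
  top of the ranking is strongly enriched.
* **Calibration.** The non-centrality μ is solved numerically (bisection
  in log-p space for the top-q threshold, then root-finding in μ) so
  that the *expected* top-q × target 2×2 table attains the configured
  odds ratio given the realized background fractions. μ = 0 reproduces
  the null exactly. The planted OR is checked on replicate-pooled
  tables: the per-replicate OR estimator is Jensen-biased upward at
  ~10 expected successes per table, so the pooled table is the
  consistent oracle.
* **Networks.** Preferential attachment (3 edges per node) with an
  attachment-probability multiplier of 1 + hub_bias for target genes;
  the default hub_bias = 1 (2× attachment) reproduces the direction and
  rough size of the log-degree gap between targets and non-targets
  reported for curated PPI networks (Δ ≈ 0.7 at the attachment level,
  ≈ 0.4 realized in the grown graph). Edge weights are U(0.15, 1],
  mimicking score-like weights. An Erdős–Rényi alternative implements
  the bias as a weight multiplier on target-incident edges.
  Disconnected components are bridged into the giant component with
  minimum-weight edges so the r = 0 stationary limit exists.
* **Drug tables.** Each database observes a seeded 95% retention of
  every trait's targets, partitioned over drugs (3 genes per drug), with
  confidence scores U{700..1000} and inhibition/activation types, so the
  default filters pass everything unless the configuration says
  otherwise. The database correlation default is exchangeable 0.9
  (databases share most targets through common sources) and the trait
  correlation 0.1 (weak phenotypic correlation).
* **MR datasets.** Clean instruments have |z<sub>exp</sub>| ~ U(20, 60) —
  realistic for top cis-QTLs and strong enough that weak-instrument
  ratio bias (∝ 1/z²) stays well below the Monte-Carlo resolution of
  the recovery tests. Planted contaminants: palindromic alleles,
  frequency shifts > 0.05, and reverse-causal SNPs with
  |z<sub>exp</sub>| ~ U(9, 12) (always clearing the instrument threshold despite
  sampling noise) against |z<sub>out</sub>| ~ U(25, 40) (always failing Steiger).
  `noise=0` gives the exact noiseless limit.

All randomness derives from one integer seed via `SeedSequence` spawn
keys; regenerating a cohort is byte-for-byte identical, and sampling is
always performed on sorted containers so results do not depend on hash
ordering.

**What the generator does not emulate:** realistic genome-wide LD,
tissue-specific eQTL architecture, real drug-database content, literature
bias in edge discovery, or trait-trait genetic correlation beyond shared
disease genes. Passing tests therefore demonstrate the *machinery* —
statistics, solvers, filters, calibration — not that any method would
achieve these numbers on real data.

## Problem sizes used in validation

The test suite and the acceptance script use: 50 random graphs of up to
200 nodes for solver equivalence (tolerance 1e-10); 10⁷-draw Monte-Carlo
oracles for weighted chi-square tails (3 MC standard errors); 10⁵
replicates for null type-I error and for the aggregation variance check
(5% relative error); 500 replicates for MR recovery; exhaustive table
enumeration up to background 40 for Fisher exactness; and 50 cohorts of
20,000 genes (10 traits × 2 databases) for planted-OR CI coverage, with
a single 20,000-gene cohort for the hub-bias AUC orderings.

## Known limitations

* The Steiger z-test treats exposure and outcome cohorts as independent
  and uses the r² = z²/(z²+n) approximation; sample overlap is not
  modeled.
* The IVW implementation has no heterogeneity diagnostics (no Cochran Q
  pruning) — deliberately, as the minimal reading of the method.
* Degenerate LD handling (missing LD, monomorphic SNPs) is out of
  scope; LD blocks must be valid correlation matrices.
* The enrichment OR is the sample cross-product (not the conditional
  MLE that `fisher.test`/SciPy report alongside the exact p), chosen so
  the Woolf standard errors feed the aggregation formulas coherently.
* The difference test's small-m anti-conservativeness noted above.
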