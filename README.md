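# netprio

Benchmarking machinery for **drug-target gene prioritization**: gene-level
scoring from common-variant, molecular-QTL and rare-variant association
inputs; random-walk-with-restart network diffusion; drug-target gene-set
construction; enrichment/AUC evaluation; and correlation-aware aggregation
across traits and drug databases. Everything runs on a synthetic cohort
with planted ground truth, so the full pipeline is testable without any
external download.

## Who this is for

Statistical geneticists and methods developers who want to (a) evaluate
how well gene prioritization strategies recover known drug-target genes,
(b) quantify what network propagation adds — and where hub bias in curated
interaction networks inflates apparent performance — and (c) stress-test
the evaluation statistics themselves against planted truth.

## The models and statistics at the core

**GWAS gene scores.** For the SNPs assigned to a gene (gene body ± 50 kb),
the statistic is the sum of squared z-scores, T<sub>sum</sub> = Σ<sub>i</sub> z<sub>i</sub>².
Under the null, T<sub>sum</sub> ~ Σ<sub>j</sub> λ<sub>j</sub> χ²<sub>1,j</sub>, a weighted chi-square whose
weights λ<sub>j</sub> are the eigenvalues of the local LD correlation matrix. The
tail probability is computed by Imhof-type numerical inversion with a
saddlepoint fallback in the extreme tail.

**QTL-GWAS gene scores.** Two-sample Mendelian randomization of a
molecular exposure (transcript or protein level) on a disease outcome:
allele harmonization (palindromic SNPs removed, allele-frequency
difference > 0.05 removed), instrument selection (exposure p < 1e-6,
pairwise LD r² < 0.01, greedy by exposure p), a Steiger filter removing
instruments with significantly stronger outcome than exposure association,
and a fixed-effect IVW combination of Wald ratios β<sub>out</sub>/β<sub>exp</sub> with
first-order standard errors. Tissue results aggregate by minimum p.

**Exome gene scores** are consumed as precomputed gene-level burden
p-value tables (validated ingestion).

**Network diffusion.** With W the column-normalized weighted adjacency
matrix and restart parameter r,

&nbsp;&nbsp;&nbsp;&nbsp;p<sub>∞</sub> = (I − (1−r)·W)<sup>−1</sup> · p<sub>0</sub>,

where p<sub>0</sub> is proportional to the squared z-scores of the gene p-values
(untestable genes get 0) and p<sub>∞</sub> is renormalized to sum to one. r = 1
returns p<sub>0</sub>; r = 0 is the stationary limit, which on a connected
undirected graph ranks genes exactly by weighted degree.

**Evaluation.** Top-ranked genes (1% by default, 5% for the sparse
pQTL background) are crossed with per-trait drug-target sets (built from
indication→drug→target joins under confidence ≥ 700 and
inhibition/activation filters) in two-sided Fisher exact tests; when no
prioritized gene is a target the OR falls back to 1, and a zero diagonal
cell is set to 1 before the cross-product OR. Threshold-free performance
uses the ROC AUC with DeLong standard errors (verified against R pROC).

**Aggregation.** Per-method log-ORs/AUCs over m = traits × databases
cells are averaged, b̄ = (1/m)Σ b<sub>i</sub>, with variance
var(b̄) = **1**′·S·R·S·**1**/m², where S = diag(se) and R is the Kronecker
product of the database and trait correlation matrices. Two methods are
compared via var(b̄₁−b̄₂) = var(b̄₁)+var(b̄₂)−2r̂·(**1**′·S₁·R·S₂·**1**/m²)
with r̂ the empirical correlation of the observation vectors.

## Worked example

```python
from netprio import RunConfig, run_benchmark, report
from netprio.synthetic import SyntheticConfig

cfg = RunConfig(
    synthetic=SyntheticConfig(n_genes=5000, n_traits=5, n_databases=2),
    methods=("GWAS", "Exome"),
    r_grid=(0.0, 0.6, 1.0),
    seed=7,
)
bundle = run_benchmark(cfg)
cols = ["method", "network", "r", "overall_or",
        "log_or_ci_lo", "log_or_ci_hi", "auc"]
print(bundle.aggregates[cols].round(3).to_string(index=False))
```

prints

```
method                 network   r  overall_or  log_or_ci_lo  log_or_ci_hi   auc
 Exome                    none 1.0       2.929         0.349         1.800 0.533
 Exome preferential_attachment 0.0       7.304         1.511         2.466 0.611
 Exome preferential_attachment 0.6       8.091         1.643         2.538 0.603
 Exome preferential_attachment 1.0       2.792         0.302         1.751 0.530
  GWAS                    none 1.0       4.745         0.999         2.115 0.535
  GWAS preferential_attachment 0.0       7.304         1.511         2.466 0.611
  GWAS preferential_attachment 0.6       8.384         1.680         2.573 0.606
  GWAS preferential_attachment 1.0       4.624         0.974         2.089 0.532
degree preferential_attachment NaN       7.304         1.511         2.466 0.611
random preferential_attachment 0.0       7.304         1.511         2.466 0.611
random preferential_attachment 0.6       9.027         1.764         2.636 0.584
random preferential_attachment 1.0       1.394        -0.585         1.250 0.492
```

Reading this: the synthetic cohort plants a target-enrichment odds ratio
of 3 among top-scored genes and hub-biased targets in the network. The
undiffused rows (`network = none`) estimate the planted OR with wide CIs
at this small size; undiffused AUCs sit near 53%, echoing the weak
threshold-free signal typical of genetic prioritization. Diffusion
(r = 0.6) sharply raises OR and AUC — but the degree baseline and even a
*diffused random* score do nearly as well, because hub-biased targets make
network degree itself a strong predictor. At r = 0 every initial
distribution collapses to the degree ranking (identical rows), while the
undiffused random baseline stays at AUC ≈ 0.5. `report(bundle)` adds
pairwise method-difference p-values; a CLI (`netprio simulate|diffuse|
targets|enrich|run|report`) wraps the same functions for shell use.

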