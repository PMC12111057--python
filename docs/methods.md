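# Methods

## Scope and model of the data

The package operates on a genetic reference population: a panel of
30–70 fully homozygous RI strains with a fixed biallelic genotype at every
marker (coded 0 for the B allele, 1 for the D allele), one or more
strains × genes log2 expression tables (one per tissue), and a
strains × traits phenotype table with missing values allowed. All
downstream statistics treat the strain as the unit of replication.

## Normalization (2Z + 8)

Each normalization unit is z-scored with the *sample* SD (n − 1
denominator, used consistently throughout the package) and mapped to
`2z + 8`, giving mean 8 and SD 2 exactly. The default unit is the strain
(array) row; a per-gene mode is available via a flag. The transform is a
fixed point on already-normalized units and idempotent up to numerical
tolerance. Zero-variance units are an explicit error naming the unit. The
fold difference is `2^(max − min)` of one gene's per-strain values — the
ratio of the highest- to lowest-expressing strain on the raw scale;
`strain_summary(..., exclude=[...])` drops parental/F1 strains, since
published RI-panel ranges are conventionally reported over the RI strains
only, and the inclusive variant is a caller choice.

## Correlation screens

Pearson r with a two-sided p from `t = r√(n−2)/√(1−r²)` on n − 2 df.
Missing values are deleted pairwise per partner (the convention for sparse
strain phenotype archives); partners with fewer than 3 complete pairs are
skipped and reported, not errors. The transcriptome screen applies
|r| ≥ 0.3, p < 0.05 and partner mean ≥ 7.1 (on the 2Z + 8 scale, where 7.1
sits just below the global mean and removes low/absent probes). No
multiple-testing correction is applied inside the screen; FDR is applied
only in enrichment, differential expression and the phenome scan. The
cross-tissue filter keeps genes present in ≥ `min_tissues` per-tissue hit
lists and also returns the full Venn partition, whose counts sum to the
union as a structural check.

## Mixed-model association (eQTL and phenome scans)

Per marker: `y = μ + xβ + g + e` with `g ~ N(0, σ_g² K)`,
`e ~ N(0, σ_e² I)`. K is the **centered** relatedness
`K = (1/M) Σ_m (x_m − x̄_m)(x_m − x̄_m)ᵀ` (not allele-frequency
standardized, matching the common mixed-model default for RI panels).
Under LOCO the tested marker's chromosome is excluded from M, so the
polygenic term carries zero weight from the proximal region.

The variance ratio λ = σ_g²/σ_e² is profiled by maximum likelihood after
one eigendecomposition of K per chromosome: rotating by the eigenvectors
diagonalizes the covariance, the likelihood is evaluated on a log-spaced
grid of 100 points over 10⁻⁵..10⁵, and the best grid cell is refined by
bounded scalar minimization. ML (not REML) is the default: the two differ
little at these panel sizes and ML keeps the OLS limit exact. β = 0 is
tested by a Wald F statistic `β̂²/Var(β̂)` with the residual variance
estimated on n − 2 df and referred to F(1, n − 2). This choice makes the
scan collapse *exactly* onto the single-marker OLS F-test when K is the
identity (or λ → 0), which the tests exploit as an oracle: agreement to
1e−6 in −log10(p) across a 50-marker scan.

Markers monomorphic within the analyzed strain subset are reported with
logp = 0 rather than dropped, keeping scan rows aligned with the map.
Eigenvalues of K are clipped at 0 to absorb −1e−8-scale numerical
negatives. Fixed genome-wide thresholds of 2.5 (suggestive) and 4.0
(significant) on −log10(p) are used; permutation thresholds are out of
scope.

**Interval rule.** The significant interval is the Mb span of the
contiguous run of markers at or above threshold around the peak, on the
peak's chromosome; a lone qualifying marker gives a zero-width interval.
(Published spans rarely state their rule; a drop-based rule is a
reasonable alternative and would give wider intervals.)

**cis/trans.** A call is cis when the significant interval (or peak) lies
on the gene's chromosome within `cis_window_mb` (default 10 Mb — typical
mapping resolution for a panel of this size; distance is 0 when the gene
position falls inside the interval), trans when significant elsewhere, and
none when no marker reaches threshold.

**Phenome scan.** One locus against many traits: each trait is tested at
the locus marker with the LOCO kinship for that marker's chromosome,
restricted to its complete strains (≥ 10 required), and BH q-values are
computed across traits with thresholds q < 0.05 and stringent q < 0.001.
This is a deliberate single-marker simplification of multi-locus
phenome-scan services; the reporting conventions (q thresholds, −log10(p)
values suitable for a scatter with a reference line at 3) are preserved.

## Over-representation analysis

Upper-tail hypergeometric: `p = P(X ≥ x)` for x query hits in a set of K
reference members, query size n, universe N — over-representation only,
matching standard ORA tools; depletion is not tested. Sets are first
restricted to the reference universe and dropped when fewer than
`min_size = 5` members remain. BH FDR is computed across the tested sets
with significance at FDR < 0.1. The reference universe is user-supplied
(typically all genes on the platform); the CLI defaults to the union of
the collection and the query. Rows sort by p, ties by larger enrichment
ratio then set ID; `top` truncates for presentation.

## PPI ego networks

From an undirected simple edge list (duplicates and reversed pairs
collapsed, self-loops dropped with a warning): primary interactors are the
focal gene's neighbors, secondary interactors the nodes at shortest-path
distance exactly 2. Degree is computed **within the subgraph induced by
the focal gene and both tiers** — mirroring hub scoring applied to the
displayed neighborhood network — with a flag for full-graph degree. Hub
reporting keeps members with degree ≥ 5.

## Differential expression

Welch's unequal-variance t per gene, two-sided, BH FDR across genes,
significant at FDR < 0.1. Genes with zero variance in both groups get
t = 0, p = 1. Welch replaces a moderated-t fit deliberately: the
pipeline's conclusions ride on the downstream any-comparison disjunction
and scoring, not the DE estimator; an optional empirical-Bayes mode
(per-group variances shrunk toward the pooled variance, prior df 4) is
provided for closer mimicry of moderated statistics and is documented as
non-canonical. Cross-cohort gene matching is exact-symbol; human→mouse
mapping is the caller's responsibility.

## Composite score

The scoring universe is the focal gene's primary + secondary interactor
set; genes outside it raise an error rather than scoring 0. Subscores:
degree > 1 → 1; correlated (p < 0.05) with the focal gene in ≥ 1 tissue →
2 (a flat 2 — the per-tissue count is reported for description but does
not scale the subscore); autism-list membership → 1 (the list is a
user-supplied flat file standing in for curated-database keyword queries);
any-comparison DE → 1. Total ∈ 0..5, monotone in every component;
selection at total ≥ 4, i.e. 80% of the maximum. Ties in the candidate
table break by gene symbol.

## Synthetic cohorts: what they emulate, and what they don't

Defaults are the study conditions: 60 strains on a 19-autosome ×
10-marker map at 10 Mb spacing; cis effect 0.45 log2 units with residual
SD 0.3 (a 1.5-SD allelic effect, a clearly-but-not-trivially detectable
cis signal at this panel size); planted co-expression targets in
|r| 0.3–0.9; trait correlations around −0.4 to −0.65; case/control sets of
8 vs 8 with planted shifts in SD units; 1,000 background genes with
means ~N(8, 0.8).

Genotypes: per chromosome, the first marker is Bernoulli(1/2) and
subsequent markers flip with the RI-expanded fraction `R = 4r/(1+6r)`,
where r comes from Haldane's map function on the inter-marker distance at
an assumed 1 cM/Mb. This reproduces the two structural facts that matter
downstream — allele frequencies near 1/2 and linkage decaying with map
distance on an expanded scale — but not real BXD marker density,
segregation distortion, or shared breakpoint history between strains.
Planted correlates use the exact-expectation construction
`y = r·z(x) + √(1−r²)·ε` rescaled to the expression scale, so realized
correlations scatter around their targets with Fisher-z-sized noise.
Expression noise is Gaussian and independent across genes: no
batch/array effects, no correlated background modules, no probe-level
structure, no epistasis. Passing tests therefore demonstrate that the
statistical machinery recovers planted effects of realistic size under
clean sampling noise — not that it is robust to the artifacts of real
microarray cohorts.

All generators are pure functions of (config, seed); per-component streams
are derived from the master seed so any single stage can be regenerated
alone. Per-tissue expression draws use tissue-keyed streams, giving
independent noise per tissue around the same genetic signal; a per-tissue
strain-subset option covers unequal strain coverage across tissue
datasets.

## Problem sizes in the test and acceptance suites

Replicate-based checks run at the cohort scale above: 50 replicates for
cis-eQTL recovery (≥ 90% required), 25 end-to-end pipeline replicates for
planted-candidate selection (≥ 90%), 20 null phenome scans of 100 traits
(≥ 95% with nothing at q < 0.001), 50 replicates for DE power at a 2-SD
shift (≥ 80%, at the candidate-panel scale of 5 genes sharing the BH
correction, which is how the case/control sets are consumed by the scoring
disjunction), and permutation oracles at 10,000 permutations. Background
gene counts are reduced (2–40) inside replicate loops, since background
genes do not enter the statistics under test.

## Known limitations

- The LMM refits λ per marker by ML; REML and score/LR tests are not
  implemented. p-values at very small n lean on the F reference rather
  than permutation.
- The interval rule (threshold run) is one of several reasonable
  conventions; interval endpoints are not comparable across rules.
- ORA assumes the query is a subset of the reference universe and errors
  otherwise rather than silently intersecting.
- The phenome scan tests a single marker; multi-locus models and
  proximal-marker conditioning are out of scope.
- Synthetic cohorts share one genotype draw across tissues (all tissues
  measure the same strains unless a subset option is used), which is the
  clean-overlap corner of real multi-tissue designs.
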