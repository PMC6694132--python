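# Methods

This note documents the models, conventions and numerical choices behind
`adnet`, and what the synthetic experiments do and do not establish.

## Scope and namespace

Integration happens at the gene level: probes, proteins and SNPs are mapped
onto Ensembl gene ids (ENSG) before assembly. Intergenic regions (IGRs) get
composite ids `ENSGC-ENSGD` naming their flanking genes in coordinate
order; they appear in the edge list (IGRI rows) but are deliberately absent
from the node-attribute table, which describes genes only. Score columns
are *not* normalized across sources — an RRA score, a Spearman coefficient,
a PBS score and an epistasis p-value have different semantics, recorded per
`data_source` in the registry.

## Co-expression

* Spearman correlation via the rank-then-Pearson identity (`scipy`);
  constant probes have undefined rank correlation and are excluded with a
  log entry. P-values use the two-sided t approximation with n−2 df.
* "Strongest correlation" is read as largest |ρ|, so strong negative
  co-regulation ranks high; a signed-descending mode exists
  (`rank_pairs(by_abs=False)`) for users who want positive-only ranking.
* Robust Rank Aggregation follows the Beta order-statistic formulation with
  a k-fold Bonferroni factor on the minimum. Pairs absent from a cohort
  (e.g. a probe constant there) contribute normalized rank 1 — the least
  significant value — rather than being dropped, so missingness cannot
  create spurious significance.
* Multiple-testing adjustment is Benjamini–Hochberg everywhere an "FDR
  method" is required. The retention threshold for adjusted RRA scores
  defaults to 1e−5.
* Probe→gene collapse keeps the **maximum** score among duplicate gene
  pairs (the most conservative choice for lower-is-stronger scores), and
  the same rule resolves A–B vs B–A orientation; self-pairs after mapping
  are dropped.
* The region route filters FDR-adjusted p ≤ 0.01 first, then applies the
  quartile rule. Quantiles use linear interpolation between order
  statistics (`numpy.quantile` default) — the cut-offs depend on this
  convention, so it is fixed and documented. For region tables duplicate
  gene pairs keep the coefficient with the largest magnitude.

## Epistasis

* The interaction model is dosage-multiplicative OLS,
  `y ~ 1 + gA + gB + gA·gB`; the F statistic is the squared t of the
  interaction coefficient with (1, n−4) df, which equals the
  full-vs-reduced sum-of-squares F (pinned by an independent ANOVA oracle
  at 1e−10 relative in the tests). The scan uses direct normal-equation
  algebra for speed; degenerate designs (constant dosages, collinear
  interaction, < 5 complete cases) are skipped and logged.
* Missing dosages are handled by pairwise complete-case analysis per SNP
  pair. No imputation and no population-structure correction are applied.
* Marker QC: "call rate" is interpreted as the missing-genotype fraction —
  SNPs with more than 10% missing are excluded (the literal opposite
  reading would discard nearly everything); MAF < 0.05 and Hardy–Weinberg
  1-df chi-square p ≤ 1e−3 are the other exclusions. All three thresholds
  are configurable; stricter per-cohort presets can be expressed through
  `qc_filter` arguments.
* Bin mapping: genes extended by a 5 kb margin on each side, boundaries
  inclusive; a SNP inside several overlapping (extended) genes joins each
  of them, while intergenic assignment is always unique. Chromosome-
  terminal SNPs outside all genes get a terminal IGR with a `TELOMERE`
  sentinel flank, since a two-gene delimitation does not exist there.
* The bin-pair score is the minimum member SNP-pair p-value; a bin pair is
  reported only when that minimum beats α/(m·n) for member counts m, n.
  Gene–gene rows are typed `epistasis`, rows touching an IGR `IGRI`.
* Phenotypes: `latest` is the last observed value; `slope` is the OLS slope
  of value on time and is missing with fewer than two visits. Braak-stage
  adjustment subtracts a loess fit of score on age (span 0.75 by default —
  a conventional smoothing choice, not stated by the original design) and
  falls back to mean-centering when ages are constant. Ventricular-volume
  adjustment is two-stage: per-individual volume slope, then residuals of
  slopes on age, sex and baseline status.

## Regional expression

The Z-score axis is ambiguous in prose descriptions of "Z-scores in each
individual region". The default standardizes **across probes within each
region** (each region column has mean 0, sd 1 per dataset); the alternative
per-probe axis is available via `axis="probe"` and the choice is recorded
in the output's metadata. Cross-dataset combination is an unweighted mean
of per-dataset Z-scores over the datasets where a cell is present.
Probe→gene collapse keeps one whole regional profile — the probe whose
maximum |Z| over regions is largest — rather than cherry-picking per
region. Zero-dispersion regions cannot be standardized and are dropped
with a log entry.

## Integration

The packaged registry enumerates 64 datasets of six data types: the
cross-cohort co-expression aggregate, seven region co-expression datasets,
49 epistasis datasets (ventricular volume, two Braak cohorts, 23 cognitive
traits × latest/slope), four PPI collections, the GWAS table, the
positive-selection table and the aggregated regional-expression dataset.
GWAS rows are filtered to p ≤ 0.05 before merging; genes hit by several
qualifying SNPs keep all rows in the long form, while the flattened
237-field view keeps the minimum p and its SNP id (the flattening rule is
this package's choice; both forms are emitted). Pseudogene nodes and all
incident edges are removed from the final tables; the filter is idempotent.
The "reduced" release applies |ρ| ≥ 0.8 to region co-expression edges only.

## Prioritization use case

IGRI edges and region co-expression edges with |ρ| < 0.5 are excluded from
the case-study graph (the magnitude reading keeps strong negative
correlations). Label conflicts resolve positive-over-negative with a
warning. Hop-2 neighborhoods are **exact** shortest-path distance 2 within
the typed subgraph, not "within two hops"; empty neighborhoods contribute
0. The shipped scorer is a random forest over the feature table — a simple,
strong reference; deep graph-embedding models are out of scope, so
published embedding-based metric values are not reproduction targets. The
package asserts only the qualitative ordering (graph features beat
biological features when positives cluster), evaluated on held-out labels.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic given (arguments, seed) and record planted
signals in a `GroundTruth` object:

* **Gene models** on one synthetic chromosome, 1-based inclusive
  coordinates, configurable fraction of overlapping neighbours, pseudogene
  biotypes, 1–2 probes per gene and one protein per gene.
* **Expression cohorts**: module genes share a latent per-sample factor
  `y = λ·f + base + noise`; λ is calibrated through the Gaussian
  Spearman–Pearson relation r = 2·sin(πρ/6) so pairwise Spearman hits the
  target. Defaults (6 cohorts, 40 samples, module ρ = 0.9, noise sd 0.3)
  mirror the six-cohort design at desk scale.
* **Region expression**: 231-region ontology with the seven disease
  regions; planted genes gain a mean shift in disease-region samples.
  Background probes are independent, so region co-expression finds little
  under the default null — correct behaviour, but it means the default
  pipeline's ABA edge counts are typically zero.
* **Genotypes**: Hardy–Weinberg sampling at per-SNP MAF ~ U(0.1, 0.5),
  uniform missingness; SNP positions span genic and intergenic space. The
  planted epistatic pair feeds a dedicated quantitative scan phenotype via
  `y = β₀ + β_A g_A + β_B g_B + β_AB g_A g_B + ε`. Braak-like scores follow
  `round(clip(1 + 0.12·(age−60) + ε, 1, 6))`; ventricle slopes carry
  age/sex/status confounding.
* **PPI / GWAS / PS tables**: PBS scores U(0, 10), MI scores U(0, 1),
  pseudogene-mapped partners included on purpose; GWAS signal SNPs get
  p < 0.05 and are recorded for bookkeeping.

Not emulated: raw array files and normalization internals (generation
starts at the normalized-matrix level), linkage disequilibrium, population
structure, batch effects, realistic intensity scales (the probe-variance
filter threshold is exposed but the original scale is not reproduced).
Passing tests therefore demonstrate the correctness and calibration of the
*methods* under clean generative assumptions, not performance on real
cohort data.

## Problem sizes and numerical conventions

Default synthetic sizes (60 genes, 6 × 40 expression samples, 231 regions
× 2 samples × 6 brains, 500 individuals × 40 SNPs, 60 PPI edges) keep the
full pipeline under half a minute and the complete verification suite
around a minute; all are configurable upward. Ties in ranking use average
ranks; candidate ranking ties break lexicographically by ENSG id; standard
deviations use ddof = 1; p-values are floored at the smallest positive
double to keep scores in (0, 1]. Thresholds (1e−5 RRA, 0.01 region FDR,
1e−8/1e−5 epistasis, 0.45 MI, 0.05 GWAS, 5 kb margin, 0.01 MAF product,
0.8 reduced cut, 0.5 case-study cut) are the published operating points and
are exposed in `PipelineConfig`.

## Known limitations

* The exhaustive pair scan is quadratic in SNP count and sized for
  desk-scale panels, not genome-wide cohorts; the statistical model is the
  standard one, but the parallel engines used for full cohorts are not
  re-implemented.
* Region co-expression requires ≥ 3 samples per region and fails loudly
  otherwise.
* The loess span (0.75) and the Z-combination rule (unweighted mean) are
  defensible defaults where the original design is silent; both are
  configurable and recorded in outputs.
* `compare_edge_sets` enumerates all 2^k − 1 subset regions and is meant
  for a handful of sets, matching its UpSet-style reporting purpose.
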