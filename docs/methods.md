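# Methods

This note records the statistical model, the conventions and defaults, the
design choices made where the workflow's published descriptions are open to
interpretation, and what the synthetic benchmark does and does not
establish.

## Data model and coordinates

All intervals are 0-based half-open. Bismark-dialect coverage files
(1-based inclusive single-base rows) are converted at read time and never
downstream, so window and overlap arithmetic lives in a single convention.
CpG sites are treated as strandless single positions; coverage files of
this dialect are commonly already destranded, and no +1-offset strand
collapsing is applied by default.

The coverage floor (default 5 reads) is enforced in **every** sample, the
strictest reading of a minimum read-count filter. This keeps the per-sample
percentage defined everywhere and the t-test degrees of freedom constant
across sites. At a floor of *c* reads the smallest nonzero methylation step
is 100/*c* percent — 20% at the default — which bounds the resolution of
any single-site claim.

## Per-CpG tests

- **t-test design** (replicated samples): two-sided unpaired test on
  per-sample percentages. Welch's unequal-variance form is the default;
  with n = 6 per group there is no reason to lean on equal variances, and a
  pooled-variance flag exists for comparison. Sites where both groups are
  constant get p = 1 when the means agree (no signal) and p = 0 otherwise.
- **Fisher design** (one embryo per sample, no meaningful within-group
  replication of percentages): counts are pooled within group into one 2×2
  table per site, tested two-sided under the minimum-likelihood rule.
  Group means and Δ are still computed from per-sample percentages so both
  designs report the same effect measure.

Δ = mean(APA) − mean(young) everywhere; positive Δ is hypermethylation in
the aged group. Significance is p ≤ α with α = .05 (configurable).

## DMR calling

The normative rule is the cluster-and-filter definition: per chromosome,
significant CpGs (p ≤ α, Δ ≠ 0) are partitioned by cutting wherever the
gap to the previous significant site exceeds λ = 1000 bp; each direction
within a cluster is evaluated independently and emits a region when ≥
`min_cpgs` (3; 2 in array mode) members share the sign and |mean Δ| ≥ 10%.
This is deliberately *not* a re-implementation of a smoothing-based
kernel statistic: the membership filters, not a kernel, determine what the
workflow reports, and a kernel stage would not be reproducible from its
published description. The kernel scaling constant C = 75 of the original
smoothing caller is carried in the config for provenance only and is
unused.

Choices a reader should know:

- **mean Δ** averages the significant member CpGs of the region's
  direction (default); `mean_over="all"` averages every tested CpG in the
  span instead. The two differ when a null site sits inside the span.
- **Width** is the half-open span of member CpGs, so three adjacent CpGs
  give a width of a few bp. Published width ranges with minima of 3–4 bp
  only make sense under this convention (a fixed window would floor the
  width at the window size).
- **Mixed clusters** are retained: one cluster may emit one hyper- and one
  hypomethylated region, each spanning its own members. Genes exhibiting
  both directions are a real observation, not an artifact to suppress.
- An O(n²) chain-and-merge re-implementation is kept in the test suite as
  an oracle; the production linear scan must match it exactly on random
  inputs.

## Annotation

Shores are the 2 kb flanks of merged islands minus the islands; shelves the
next 2 kb minus both; precedence island > shore > shelf makes the three
context sets pairwise disjoint. A region's context is decided by its
*member CpGs* (the CpGs define the region; the span may incidentally cross
context boundaries). Gene association is by overlap with the gene body or
the promoter window [TSS − 2000, TSS + 500), mirrored strand-awarely on the
minus strand; one region may associate with several genes, and regions with
none are tallied as gene-free. Nucleosome-retention colocalization is
computed both as bp overlap with supplied regions and as membership of
DMR-associated genes in a supplied retained-histone gene list; the gene
level is the one used for enrichment statistics, since published retention
calls are distributed as gene lists.

## Enrichment

All 2×2 statistics are Fisher exact (two-sided, minimum-likelihood rule)
with cross-product odds ratios. Confidence intervals are Woolf log-OR
intervals, exp(ln OR ± 1.96·SE), with the Haldane–Anscombe +0.5 applied to
all cells only when some cell is zero; the p-value always uses raw counts.
Benjamini–Hochberg adjustment is applied within each analysis family (one
cytoband table, one disease-list family), never pooled across families.
The gene universe defaults to all symbols in the supplied gene models; a
`covered` option restricts it to genes containing a tested CpG. The choice
materially changes odds ratios, which is why it is an explicit, logged
parameter rather than a hidden default.

## Chromosomal localization

Gene start sites are smoothed with a Gaussian kernel whose bandwidth is
0.2 × the normal-reference rule-of-thumb bandwidth (0.9·min(sd, IQR/1.34)
·n^(−1/5)) — the "adjust = 0.2" semantics of the R `density` convention
the original analysis used, since no absolute bandwidth is documented.
Evaluation is a direct vectorized sum of Gaussians on a 512-point grid per
chromosome: exact control of the kernel sd matters here, and the factor-
times-data-sd parametrization of library KDE objects breaks on degenerate
inputs. Bootstrap 95% bands resample sites with replacement (default
10,000 replicates, bandwidth recomputed per resample, fully seeded).

The criterion for flagging a cytoband as divergent is **invented and
labelled as such**: the original figures highlight bands without stating a
rule. Here a band is flagged when the two 95% bands are disjoint over at
least 50% of the grid points inside it — explicit, configurable, and
conservative (pointwise-disjoint CIs are a stricter event than a pointwise
mean difference).

## Downstream

Sample clustering z-scores each DMR member CpG row (positive = above the
site mean), then agglomerates samples with average linkage under
1 − Pearson correlation of sample columns. "Pearson's rank correlation" in
the source description is internally inconsistent terminology (Pearson is
not a rank method); Pearson on z-scores is the standard heatmap default
and a `spearman` option covers the rank reading. Correlations undefined
because a column is constant are treated as 0 (neutral distance 1).
Constant CpG rows are dropped with a warning. Age association is ordinary
least squares of percentage on age, two-sided slope p. The validation-style
group comparison reports both the Welch t and the exact (small-n)
Mann–Whitney p.

The 450K adapter runs a per-probe two-sided t-test on β, converts effects
to the percent scale (Δ = 100·Δβ), and feeds the same caller with
`min_cpgs = 2`. The 10% mean-difference filter is retained for array data
(|Δβ| ≥ 0.10) — the relaxation documented for the array reanalysis concerns
only the membership count — and is configurable.

## Synthetic worlds

The generator states one world and keeps it:

- two groups of 6 samples; ages uniform on [25, 35] (young) and [50, 64]
  (APA) — the cohort definitions, without inventing an age law beyond an
  optional linear slope inside spiked regions (default 0);
- sperm-like baselines: islands at 10% methylation, background at 80%;
- beta-binomial inter-individual noise with ρ = 0.02 (Beta concentration
  (1−ρ)/ρ), chosen so per-sample percentages vary a realistic few percent
  between individuals; binomial-only noise would make the t-test
  unrealistically anti-conservative;
- Poisson(20) read depth per site and sample;
- spiked regions of ±30% over ≥ 5 CpGs inside islands. Islands chosen for
  hypomethylated spikes have their baseline raised to the background level
  first (a "methylated island"), so the −30% effect is representable
  without clamping;
- genes tile chromosomes with alternating strands; cytobands exactly
  partition each chromosome; nucleosome regions are the promoters of a
  random 20% of genes; gene sets can be planted with a chosen overlap
  fraction with spiked-DMR genes.

All generation is a pure function of (config, seed).

What a green benchmark establishes: on data whose noise matches the model,
the pipeline recovers ±30% regions with sensitivity ≥ 0.8 and region-level
false-discovery proportion ≤ 0.2, separates the cohorts by clustering, and
detects planted enrichments while leaving proportional nulls alone. What it
does not establish: robustness to batch effects, cell-mixture
heterogeneity, SNP-overlapping CpGs, bisulfite conversion failure, or
coverage structure of real libraries — none of which the generator
emulates.

One calibration observation worth stating precisely: in a no-effect world
dense enough to carry ≥ 10,000 tested CpGs in 4 Mb, the caller emits about
two false regions per genome (~0.015% of sites; the Poisson-level
consequence of 5% of sites being falsely significant at this site
density). "Essentially zero" relative to the thousands of regions called
when signal is present, but not literally zero; the null-calibration test
bounds the pooled count accordingly rather than asserting none.

## Numerical conventions

- Degenerate t-tests: p = 1 for identical constant groups, p = 0 for
  different constant groups (the limit of the statistic).
- Fisher p-values compare table likelihoods with a 1 + 1e-9 relative
  tolerance, matching the standard two-sided enumeration rule.
- Bootstrap CIs are percentile (2.5/97.5); the profile container widens
  them minimally to include the point estimate, which raw percentile bands
  can miss at extreme tails.
- All randomness flows through numpy Generators seeded from explicit
  integers; reruns are byte-identical.

## Known limitations

- The Fisher per-site design pools counts within group and therefore
  ignores within-group overdispersion; it is anti-conservative for
  replicated designs and is intended for the one-sample-per-subject case.
- No per-CpG multiple-testing correction is applied by design: the
  window rule (≥ 3 concordant significant CpGs) is the false-positive
  control, which is why single significant CpGs are never reported as
  findings.
- Cytoband enrichment localizes genes by promoter start site only; genes
  straddling band boundaries count once.
- The array adapter assumes already-normalized β values and does not model
  probe-type effects.
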