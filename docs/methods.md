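# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `uprnet`.

## Differential expression

Counts are modeled as negative binomial with variance `m + α·m²`
(mean/dispersion parameterization). Size factors are median-of-ratios: for
sample *j*, the median over genes expressed in every sample of
`k_gj / geometric-mean_g(k)`. Factors are defined only up to a common
constant; all downstream quantities depend on ratios of factors.

The per-contrast test (Tm vs mock within one genotype × timepoint) is
Welch's unequal-variance t on `log2(ñ + c)` with pseudocount `c = 0.5`,
with Benjamini–Hochberg adjustment within the contrast over tested genes.
This is an explicit stand-in for a negative-binomial GLM with dispersion
shrinkage: it keeps the calling rule exactly as printed while avoiding an
external model dependency. Consequences: slightly conservative power at
very low counts, and no sharing of dispersion information across genes. The
count filter (total < 100 over the six contrast samples → untested), the
effect threshold (`|log2FC| > 1`) and the significance threshold
(adjusted `p < 0.01`) are all strict inequalities; boundary values fail.
Degenerate zero-variance genes are deterministic: equal group means give
p = 1, unequal means with two zero variances give p = 0.

## The genotype-dependence (DDEG) test

For each union DEG, replicate-level log2 fold changes
`rLFC_i = log2((ñ_Tm,i + c)/(ñ_mock,i + c))` are formed by pairing Tm
replicate *i* with mock replicate *i* — index pairing is the minimal
deterministic convention and is configurable, since nothing in the
experimental design forces a particular pairing. Genotype pairs are
compared per timepoint with a pooled-variance two-sided Student t
(`df = n1 + n2 − 2`) at raw `p < 0.01`. No multiplicity correction is
applied at this stage by design (a BH option exists but is off by default);
the restriction to union DEGs is the only filter. Per-pair unions collect
genes significant at ≥ 1 timepoint; the median per-comparison count is
reported because it sets the size of matched random control sets for motif
analyses.

Calibration: with three replicates per group and normal replicate noise the
test is exact; the suite verifies an empirical false-positive rate of
0.01 ± 50% at p < 0.01 on 10⁵ null genes, and ≥ 0.7 sensitivity (observed
≈ 0.97) at a planted Δlog2FC = 2 with σ = 0.3.

## Coexpression network

The input is a genes × conditions log2FC matrix. Pairwise Spearman
correlation (average ranks for ties) is soft-thresholded into a signed
adjacency `a_ij = ((1 + ρ_ij)/2)^β`, β = 18, so perfectly anti-correlated
genes get adjacency 0 rather than 1. Connectivity is `k_i = Σ_{u≠i} a_iu`
and the topological overlap is
`TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with
`ℓ_ij = Σ_{u≠i,j} a_iu a_uj`, `TOM_ii = 1`. Zero-variance genes are dropped
with a warning (Spearman is undefined for them).

Modules come from average-linkage hierarchical clustering of `1 − TOM`.
Instead of the dynamic hybrid tree-cut algorithm we use a **static
largest-gap cut**: the dendrogram is cut at the midpoint of the widest gap
between consecutive sorted merge heights. The rationale is a property of
TOM worth recording: because the denominator takes the *weaker* node's
connectivity, a weakly connected background gene is marginally closer to a
dense module cluster than to another background gene, so background
attachments form a long, nearly flat band of merge heights just below the
maximum. Any fixed-quantile cut lands inside that band and either absorbs
the background into modules or fragments them; the largest gap, by
contrast, always separates the tight within-module merges from the
background band. A quantile cut is still available
(`tree_cut="quantile"`). Clusters smaller than 25 genes are left
unassigned ("grey"); modules are named by size rank with the conventional
WGCNA color order (largest = turquoise).

Module eigengenes are the first right singular vector of the per-gene
z-scored module submatrix, unit norm, sign-oriented to correlate
non-negatively with the module's mean profile. Modules with eigengene
dissimilarity `1 − cor < 0.05` are merged iteratively (closest pair first,
eigengenes recomputed after each merge, so the result is order-invariant).
Edges are exported at TOM ≥ 0.2, each undirected pair once.

## Cis-regulatory element scanning

The five canonical UPR elements are consensus patterns, not PWMs: matching
is per-position set membership with a mismatch budget (1 for all but
UPRE-I, which is exact; the `GG/A` tail of UPRE-I compiles to two literal
alternatives). Gap positions (`N{k}`) never count toward mismatches; an `N`
in the *sequence* never matches a literal position. Both strands are
scanned and reverse-strand matches are reported at forward-strand offsets;
overlapping matches are all reported. Background letter frequencies matter
only to sequence generation (the generator honors a GC-content parameter),
never to matching.

Set enrichment is the coarsest mode: presence/absence of ≥ 1 match per
promoter, one-sided Fisher exact test against a control set — by default
201 promoters drawn (seeded) from the supplied background universe,
matching the size convention of the median DDEG comparison count.
Summit centrality takes, per ±250 bp peak window, the best match (fewest
mismatches, then closest to center, then leftmost) and tests the count of
best matches whose center falls within ±50 bp of the summit against a
binomial null with p₀ = the fraction of valid placement positions that are
central (≈ 0.21 for a 19-bp motif in a 500-bp window). Windows without any
match are excluded from the denominator and the all-empty case returns an
explicit "no occurrences" status.

## ChIP peak filtering

Replicate consistency is a deterministic reciprocal-overlap filter (each
peak needs a partner covering ≥ 50% of both lengths; the record of the
higher-pfloat partner is kept, which also resolves multi-sub-peak records
to the strongest summit). This replaces a probabilistic irreproducible-
discovery-rate model on purpose: it is exact, order-free and sufficient for
planted-structure validation.

The condition-specificity filter computes, per Tm peak, the fraction *f* of
its bases covered by the union of overlapping mock peaks. `f ≤ 0.30`
retains; `f > 0.30` eliminates unless `pfloat_Tm / pfloat_mock > 3` against
the mock peak with the largest single overlap (ties to higher pfloat), in
which case the peak is retained and flagged rescued. Three conventions are
deliberate and configurable: the overlap denominator is the **Tm** peak
length (the assayed peak), the ratio is taken on the **−log10** scale (the
named column of the narrowPeak file), and both thresholds are strict. A
mock pfloat of zero with overlap rescues (ratio +∞) and is logged.
Retained ∪ eliminated always partitions the input; the filter is idempotent
and monotone in both thresholds (property-tested on 1000 random fixtures).

Retained peaks are merged across timepoints (≥ 1 bp overlap chains coalesce
to their span; summit/pfloat/name from the strongest member) and assigned
to every gene whose TSS lies within 1000 bp of the peak interval
(strand-agnostic, inclusive boundary: distance 1000 assigns, 1001 does
not). Peak location is classified by summit with precedence
promoter > gene body > downstream > distal intergenic.

## GRN integration

TF-bound gene sets flag nodes of a module's thresholded edge graph.
Connected components are labeled sub1, sub2, … by descending size
(singletons grouped as "isolated"). Hubs are the top `⌈0.10·n⌉` genes per
subnetwork by degree — ceiling because "top ≥ 10%" must include at least
that fraction — with lexicographic tie-breaks for determinism and the
percentile `rank/n` reported so borderline claims are checkable; an
optional curated gene list (phenotype/ER-stress annotation) intersects the
hub flags and is always an explicit input, never inferred. Enrichment and
set-overlap tests are upper-tail hypergeometric computed in log space via
`gammaln` + `logsumexp`, verified against exact rational arithmetic to
10⁻⁶ relative error in log p at the scale of the study's most extreme
overlap (p ≈ 10⁻²⁰³); term maps are flat gene → term inputs with no
ontology-graph propagation, and BH controls across terms at FDR 0.05.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design: genotypes Col0 (wild type),
bzip28 and bzip60 (TF-null), timepoints 0/12/24 h of ER stress recovery,
Tm vs mock, 3 RNA-seq replicates, 2 ChIP replicates per TF × condition ×
timepoint. Defaults, chosen once as realistic desk-scale conditions:

| parameter | default | why |
|---|---|---|
| genes | 2000 | desk-scale stand-in for ~22k Arabidopsis genes |
| baseline log2 mean / sd | 8.0 / 1.5 | median ≈ 256 counts, wide dynamic range |
| NB dispersion α | 0.02 | typical gene-wise RNA-seq dispersion |
| planted DEG fraction / effect | 0.4 / ±2.0 log2 | clear but not trivial induction |
| DDEG attenuation Δ | 2.0 (per mutant) | response abolished in the null mutant |
| modules | 4 × 60 genes, amplitude 2.0, noise 0.3 | recoverable latent structure |
| network conditions | 30 | enough columns for rank correlation |
| promoter length / GC | 1000 bp / 0.36 | 1-kb promoters, Arabidopsis GC |
| ERSE-I plant rates | 0.8 target / 0.05 background | strong planted enrichment |
| peaks per TF | 30 specific + 20 constitutive, 400 bp | summit on a planted ERSE-I |
| shared TF targets | 0.3 of specific | partially overlapping binding |
| replicate peak jitter | ±25 bp | exercises overlap logic |

One seed fans out to per-component generators through
`numpy.random.SeedSequence`, so identical configurations give byte-identical
files and reports.

Deliberate simplifications: treatment effects are constant across
timepoints (module latents carry the condition dependence); promoters are
i.i.d. letters, so there is no chromatin background, repeat structure or
positional nucleotide bias; ChIP peaks have clean rectangular intervals and
well-separated genes (5-kb slots), so the peak filter faces no ambiguous
nested-gene assignments; replicate noise is exchangeable. Passing tests
therefore demonstrate the correctness and calibration of the statistics
under the stated model, not robustness to real-data pathologies
(overdispersion heterogeneity, batch effects, peak shoulder overlap,
promoter composition bias).

Problem sizes in the test and acceptance runs (2000-gene pipeline, 440-gene
network scenario, 10⁵-gene null calibration, 1000 random peak fixtures) are
the package's chosen desk-scale defaults; every scenario scales up through
`SimulationConfig`.

## Known limitations

- The DEG stand-in is not bit-compatible with negative-binomial GLM tools;
  published DEG counts will not be reproduced on real data, only the
  thresholds and filters.
- The static tree cut does not emulate the dynamic hybrid algorithm's
  sub-cluster splitting; module counts on real data will differ from tools
  using it.
- The reciprocal-overlap replicate filter is not an IDR model and has no
  notion of signal-rank consistency.
- De novo motif discovery and motif-to-TF matching are out of scope; only
  the five canonical consensus elements are scanned.
- Coordinates assume one annotation record per gene; alternative TSSs are
  not modeled.
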