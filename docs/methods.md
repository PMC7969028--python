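# Methods

This note documents the models and procedures epimap implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the design
was genuinely open.

## Coordinates and formats

All coordinates are 0-based half-open (BED convention); `length =
end − start` everywhere.  Chromosome names are opaque strings.  The
methylation-coverage dialect used by this package is 0-based with an
explicit header; Bismark's native coverage files are 1-based, so the
reader takes `one_based=True` (CLI `--one-based`) to convert on load.
Strand "." is unstranded; unstranded gene models are rejected because a
promoter window cannot be anchored without an orientation.

## Signal quantification

A read contributes to every feature containing its **midpoint**.  This
choice (the read-to-feature rule is rarely stated in publications) makes
counts additive over non-overlapping tilings — the sum of bin counts
equals the number of reads in the tiled span — which in turn makes the
quantification oracle-checkable.  RPKM uses the feature's own length
(bin, peak or 4-kb promoter) and the sample's genome-wide mapped-read
count.  Consequences worth knowing:

* RPKM is scale-invariant: doubling every count and the depth leaves it
  unchanged, and subsampling preserves it in expectation.
* Peak filtering drops RPKM < 2 and **retains** exactly 2.0 (the
  exclusion is a strict inequality).
* Z-scores use the population SD; zero-variance rows map to all zeros
  rather than NaN.  Heatmap-matrix exports are sorted deterministically
  by WT H3K4me3 RPKM (descending) so repeated runs are byte-identical;
  randomised row order within groups can be had by shuffling the
  exported table under a seed.

TSS-anchored profiles bin read midpoints by anchor-relative offset
(default ±2 kb in 100-bp steps), orientation-flipping minus-strand
anchors, and scale each offset bin like a feature of length `step`
(RPKM-scaled coverage); the aggregate is the per-offset mean over
anchors.

## Promoter chromatin states

Promoters are ±2 kb around the annotated TSS, clipped to chromosome
bounds.  A mark is present iff promoter RPKM is **strictly** greater
than the threshold (default 1); at exactly 1 the mark is absent.  The
eight K4/K27/ub subsets form the state; the four-group label ignores ub
(A = K4 ∧ ¬K27, B = K4 ∧ K27, C = K27-only, D = neither).  One shared
threshold serves both the eight-state and four-group views; nothing in
the analysis motivates separate thresholds.

## Six-class bin taxonomy

What counts as a "significant change" per bin is operationalised as a
deterministic fold-change rule rather than a per-bin test: with
pseudocount c = 0.5, mark up iff (KO+c)/(WT+c) ≥ 2 ∧ KO ≥ 2 RPKM, down
by the genotype-mirrored rule, the RPKM floor echoing the peak-quality
bar.  The rule is symmetric by construction, so relabelling genotypes
swaps up↔down exactly and maps classes I↔IV, II↔V, III↔VI.  The
IV/V/VI ↔ down-pattern assignment mirrors I/II/III (IV = K27-down only,
V = both down, VI = ub-down only); this correspondence is an
interpretation, chosen for symmetry.  Bins where the two marks move in
opposite directions get an explicit `mixed` class rather than silent
exclusion, so the class table always partitions the bin set.

Covariates are resolved to bins as follows: methylation is the
unweighted mean CpG site level inside the bin; expression uses genes
whose body midpoint falls in the bin.  Genotype contrasts use unpaired
t tests for region-level covariates (different site sets per genotype)
and paired t tests for expression (the same genes measured twice).

## Methylome summaries

Site levels are methylated/(methylated+unmethylated) for sites with
coverage ≥ `min_coverage` (default 1, suited to the simulated
fixtures; real WGBS practice uses ≥ 3–5).  Element and ICR means are
**unweighted** over sites — each covered site counts once — matching
the "average of site levels" convention; a `weighted=True` option pools
by coverage instead.  A site may contribute to several element classes
(a gene-body site inside a CGI counts in both); `intergenic` collects
sites in no other class.  ICRs with no covered CpG are reported as
missing, never as zero.

Conversion efficiency is 1 − (pooled methylated calls / total calls)
over all contexts on the λ spike chromosome; under the binomial model
this estimator is unbiased, and the test suite verifies its mean over
200 simulation replicates.

Clustering metric and linkage are not uniquely determined by
convention; the field default — average linkage on 1 − Pearson
correlation over CpGs covered in every sample — is used and
config-exposed.  Samples with zero variance over the shared sites make
the correlation undefined and are rejected with an explicit error.
The dendrogram is exported as Newick with branch lengths from merge
heights.  5mC and 5hmC are not distinguished (bisulfite chemistry
cannot separate them).

## Differential expression and tests

A bare printed fold-ratio rule explodes as FPKM → 0, so the caller adds
a pseudocount ε = 0.1 to both terms and requires the higher genotype to
pass an expression floor (0.5 FPKM); both are config-exposed.  The t
tests are classical Student's: pooled-variance unpaired
(df = nₓ+nᵧ−2) and paired-on-differences, two-tailed p from the t
distribution.  Degenerate inputs are handled explicitly: zero variance
with equal means gives t = 0, p = 1; zero variance with unequal means
reports the underflow-safe minimum p rather than 0.  The suite checks
the unpaired p against a 20,000-replicate permutation oracle; agreement
within 0.02 holds for group sizes ≳ 8 (the permutation distribution is
too discrete below that).

## The synthetic-data generator

The generator emulates the statistical structure of a WT-vs-KO oocyte
multi-omic experiment; its defaults define the reference study
conditions used throughout the tests: 2 chromosomes × 5 Mb, 500 genes,
8 ChIP samples (4 marks × 2 genotypes) at 200,000 reads each, WGBS at
30× with 2 replicates per genotype, seed-determined everywhere.

**Window model.** The toy chromosomes stand for a window cut from a
notional genome of `effective_genome_size` (default 1 Gb, mouse-like).
Reads are emitted only inside the window while `total_mapped` records
the genome-wide depth the window implies
(`reads_per_sample × effective_genome_size / window`).  This is what
pins absolute RPKM where fixed thresholds are meaningful — background
≈ 0.5, enriched promoters/bins ≈ 4–5 — independent of the window size
chosen for a run.  Without it, a megabase-scale toy genome would put
*background* at RPKM ≈ 100 and every fixed threshold would be
vacuous.

**Reads** are fixed-length 150-bp single-end intervals (mirroring the
sequencing regime; pairing adds nothing to midpoint counts), sampled
from a mixture with weight 1 per background base and `enrichment_fold −
1` (default 8) extra per enriched base; `enrichment_fold = 1` is exactly
uniform.  Enrichment regions per mark: promoters of genes whose planted
state contains the mark (K4/K27/ub); bins of the planted change classes
(K27: WT in IV/V, KO in I/II; ub: WT in V/VI, KO in II/III); gene
bodies of expressed genes for K36 (per genotype).  Read counts are
Poisson-jittered around `reads_per_sample`.

**Methylation** follows alternating 200-kb hyper (0.8) / hypo (0.1)
domains.  Planted couplings, each an explicit switch:

* `couple_methylation` — gain classes I–III are placed only in
  hypermethylated domains and lose 0.5 in the KO; loss classes IV–VI
  only in hypomethylated domains, gaining 0.1.  Maternal ICRs (0.85)
  lose 0.3 in the KO; paternal ICRs stay at 0.05.  CGI promoters stay
  hypomethylated (0.05) in both genotypes.
* `couple_expression` — WT FPKM follows the promoter state (K4-only
  25, K4+ub 12, ub 4, every K27-containing state < 1, none 0.3; K27
  dominant-repressive), a quarter of K4-only genes are knocked down
  4-fold in the KO, and genes inside K27-gain (loss) bins are halved
  (×1.5) in the KO.
* `couple_k36` — H3K36me3 tracks gene bodies with FPKM ≥ 5, per
  genotype.

Sites sit on a fixed grid (default every 100 bp, 80/10/10
CpG/CHG/CHH) shared across samples so replicates have common CpGs;
coverage is Poisson(30) and methylated counts Binomial(coverage, p),
with p = 0.01 for non-CpG contexts and 1 − 0.995 on the λ spike
(2,000 sites).  Expression is log-normal around the planted means with
a mean-preserving σ = 0.1 (dispersion 0 returns the means exactly);
at this dispersion a planted 2-fold knock-down is called at the
1.5-fold threshold in > 95% of genes while false calls stay below 1%.

**Separability constraint.** Change classes are planted only in bins
that do not intersect any promoter.  Otherwise promoter-state reads of
the same mark would contaminate bin fold changes (an "unchanged" bin
holding a K27 promoter shows WT and KO signal) and, conversely, planted
bin enrichment would push the promoters of unrelated genes over the
state threshold; neither classifier could then be held to its planted
truth.  This is a property of the toy geometry (gene-dense 10-Mb
window), not a claim about real genomes.

**What the generator does not emulate** — and hence what passing tests
do *not* show about real data: fragment-size and GC biases, duplicate
reads, input/IgG background structure, broad non-canonical H3K4me3
domains, partially-methylated domains, allele-specific signal,
replicate-level biological variability in ChIP, and peak calling
itself (reference peak sets are emitted directly from the planted
truth).  Recovery rates near 100% reflect the planted effect sizes
(8-fold enrichment, 0.7 methylation contrast), chosen for comfortable
statistical separation at desk scale; they are properties of the
harness, not performance claims.

## Problem sizes used by tests and the acceptance script

The reference conditions above drive the promoter-state and bin-class
recovery checks.  Replicated checks use a reduced window so many
independent seeds can be run: methylome-clustering separation uses 100
seeded replicates of a 1-chrom/1-Mb genome (2 WT + 2 KO methylomes
each), and the coupling-propagation check uses 50 seeded replicates of
a 1-chrom/2-Mb genome with 100 genes and 50k reads per sample.  The
acceptance script reports clustering separation over 20 seeded
replicates.  These sizes are the package's choices for replicated
desk-scale runs; single-run checks always use the full reference
conditions.

## Known limitations

* The pipeline consumes aligned-read surrogates and peak calls; it
  contains no aligner, peak caller, or bisulfite caller.
* Venn-style overlap of two knockout contrasts requires a second
  expression contrast to be supplied; the default bundle carries one.
* `min_coverage=1` and unweighted site means are defaults for the
  simulated fixtures; analysts of real WGBS should raise the coverage
  floor and consider the weighted option.
* Multiple-testing correction across covariate panels is deliberately
  not applied (each panel reports a single planned contrast).
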