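# Methods

## Coordinate and strand conventions

All internal coordinates are 0-based half-open on the forward strand;
minus-strand features keep forward coordinates plus a strand flag, and all
distance arithmetic (UTR lengths, upstream/downstream windows) is done in
transcript orientation. Conversion to 1-based happens only in GFF3 and
site-table I/O. The position of a TSS is its +1 (first transcribed) base;
the position of a TEP is the last transcribed base. bedGraph (0-based
half-open, one file per strand) is the interchange format for end-count
and coverage tracks.

## Site calling and classification

A TSS candidate at p on one strand requires, with defaults:
`enriched[p] >= 10`, `(enriched[p]+1)/(unenriched[p]+1) >= 2` (the +1
pseudocount keeps zero unenriched counts finite), and `enriched[p]` maximal
within ±2 nt (ties resolve to the 5′-most position). TEP candidates use the
same height/local-maximum rule on the Term-seq track with 3′-most
tie-breaking. Replicates of a condition are pooled by summation before
calling, with the height threshold scaled by the replicate count.

Candidates from different conditions merge by single-linkage clustering
within ±5 nt; the cluster representative is the position with the highest
summed height (ties → 5′-most for TSSs, 3′-most for TEPs), condition
support is the union, and a site seen in every condition is constitutive.
Merging is idempotent.

Classification windows: primary/secondary TSSs compete within 5′-UTR
distances of 0–300 nt of a gene start on its sense strand (the start
position itself is included so leaderless transcripts classify as primary);
the strongest site per gene is P, the rest S. P vs S is decided by height,
not proximity. Remaining sites inside a sense-strand gene body are I;
within a gene body or ±100-nt flanks on the antisense strand, A; else N.
TEPs: P/S compete within 0–300 nt downstream of a gene's 3′ end
(boundary inclusive); non-P/S sites inside a primary-TSS-derived 5′-UTR
are C (genes without a mapped primary TSS cannot host C TEPs); antisense
gene-body overlap (no flanks) gives A; else N. Both classifications are
strict partitions and are asserted as such on every run. A transcript is
leaderless when its 5′-UTR is shorter than 10 nt — below the space needed
for a ribosome-binding site.

## RNA folding model

The terminator caller folds the 40-nt transcript window ending at each TEP
with an in-repo MFE engine rather than an external folding binary, so that
every prediction is exactly verifiable against exhaustive enumeration
under the identical energy model. The model: Watson-Crick + G·U pairs;
nearest-neighbour stack free energies; hairpin/bulge/internal-loop size
penalties with Jacobson-Stockmayer extrapolation
(`G(n) = G(max) + 1.75·R·T·ln(n/max)`); affine multiloops
(a = 3.4 kcal/mol, b = 0.4 per interior branch, unpaired bases free); no
dangles, terminal mismatches, asymmetry terms or special hairpins; minimum
hairpin loop 3 nt; two-loops capped at 10 unpaired bases (the standard
MAXLOOP restriction — larger two-loops are outside the model). Energies
are integer tenths of kcal/mol internally, making cross-implementation
equality exact. The stack table is a 30 °C-scaled variant of the published
37 °C values (stacks, being enthalpy-dominated, are strengthened by a
linear van't Hoff factor; loop penalties, being entropic, are left at
their tabulated values); only the 30 °C table is bundled and other
temperatures are rejected rather than approximated.

Because this energy scale is not that of any external folding engine,
absolute ΔG values are not comparable across engines. The HS/LS split
therefore defaults to the **median of the observed ΔG distribution** —
which is also how the −19 kcal/mol boundary used in practice for this
genome class was defined — rather than a hard-coded constant; a fixed
threshold can be supplied instead.

The U-content anchor ("following the stem-loop") is the 3′-most paired
base of the continuous helix closing the 3′-most hairpin of the MFE
structure; ≥3 U/T in the following 10 nt (transcript strand) types an HS
TEP as L-shaped (`HS_U_RICH`), otherwise I-shaped (`HS_U_LACK`).

Verification is two-tiered: (i) literal enumeration of every non-crossing
pair set, scored by a standalone loop-sum evaluator, for short sequences;
(ii) an exhaustive loop-decomposition search with memoized interval minima
and explicit multiloop branch enumeration — no affine V/WM matrices — that
scales to 40 nt and is itself anchored to tier (i). The production DP
matches both exactly (same integer ΔG) on every sequence tested.

## Readthrough

The readthrough fraction of a TEP is the mean normalized RNA-seq coverage
over (TEP, TEP+200] divided by the mean over (TEP−200, TEP], transcript-
oriented; it reads as a leakage fraction (low = strong termination), which
makes the expected ordering L-shaped < I-shaped < unstructured.
Replicate coverage tracks are put on a common scale by median-of-ratios
over gene-body counts and averaged first. TEPs with zero upstream signal
are excluded and counted rather than divided. Per-class summaries drop
fractions above the 95th percentile of the pooled (not per-class)
distribution.

## Normalization and reproducibility

`size_factors` is median-of-ratios: each library against the per-gene
geometric mean, median over genes with all-positive counts, computed on the
ratio scale (an even-count median interpolates arithmetically, not
geometrically). RPKM follows its definition. Replicate agreement is
Pearson r on raw counts over the union of nonzero positions (zeros
filled); binned and log2(1+x) modes are available since the choice of
transform is a convention, and a genome-wide variant pools both strands.
Constant tracks raise an error instead of returning NaN.

## TU assembly and the COG score

Walking each strand 5′→3′, every TSS pairs with the nearest downstream
same-strand TEP within 15 kb (a generous bacterial operon bound,
configurable) that does not reach past the gene block of the next primary
TSS. A TU's genes are the sense-strand genes fully contained in its span;
1 gene → monocistronic, ≥2 → polycistronic, none → cis-regulatory when the
TEP is C-class, intergenic otherwise. Cross-condition TU duplicates merge
when both endpoints agree within ±5 nt.

The functional-relatedness score of a gene set is
`max genes in one COG category / number of distinct categories present`,
COG-less genes excluded; the literal formula can exceed 1 when all genes
share a category, and a `per-gene` mode (bounded by 1, dividing by the
number of annotated genes) is available. The null model draws runs of k
consecutive same-strand genes (k sampled from the observed polycistronic
sizes) at random positions, rejecting strand-broken runs, and compares
score distributions with a two-sided Mann-Whitney U test.

## Synthetic data generator

The generator emulates the data *structure* of a two-condition
dRNA-seq/Term-seq/RNA-seq study of a high-GC methanotroph genome. Defaults
(the reference conditions): 100 kb at 65% GC, 60 genes grouped into
single-gene TUs and 2–4-gene operons (operon members share a COG
category), 2 conditions × 2 replicates, 75% of TUs constitutive and the
rest split evenly between condition-specific sets (simulated by zeroing
the other condition's peak), background 0.2 end-counts/nt, mean peak
height 200 with reproducible per-site lognormal strengths (σ = 1, drawn
once and shared across conditions/replicates — real site strengths span
orders of magnitude and are what drives the high replicate correlation of
real libraries), TEX enrichment 8×, purine initiation bias 0.9, 5′-UTRs
lognormal around a 63-nt median with 5% leaderless, 3′-UTRs lognormal
around 85 nt.

Terminator contexts: L-shaped (8–12 bp GC-only stem, 4–8 nt pair-poor
loop, ≥4-nt U-tract, TEP at the last U), I-shaped (same stem-loop, 10-nt
tail constrained to <3 Us, TEP ~5 nt past the stem), unstructured (no
planted hairpin), allocated in exact 0.15/0.35/0.50 proportions (largest
remainder, then shuffled) so that the realized structured fraction always
matches the mix — important because the HS/LS threshold is a median.
A 3-nt C spacer insulates each hairpin: C cannot pair U, so an A/G-rich
genomic flank cannot stack-extend the planted stem into the U-tract and
bury the tail that defines the L shape. Planted readthrough fractions are
0.05 (L), 0.10 (I) and 0.50 (unstructured); RNA-seq coverage is
piecewise-constant along each TU with a 300-nt readthrough tail, plus
Poisson noise. Counts are Poisson by default with a negative-binomial
overdispersion option; everything is byte-identical under a fixed seed.

What the generator does **not** emulate: read-level artifacts (mapping
bias, rRNA carryover, soft-clipping), processed 5′/3′ ends,
Rho-dependent termination, overlapping TUs, and correlated background —
so passing recovery tests demonstrates the correctness of the calling and
typing logic under the stated noise model, not performance on real
libraries.

## Problem sizes and numerical choices

The reference study (100 kb / 60 genes / ~33 TUs) keeps a full pipeline
run around five seconds while leaving every class populated; the COG
null-model analysis uses a larger operon-rich genome (600 kb, 360 genes,
75% operon fraction) so that ≥100 polycistronic TUs support the rank test.
Folding-oracle agreement is checked on 200 random 20–40-nt sequences at
65% GC. Ties in site calling are resolved 5′-most (TSS) or 3′-most (TEP);
equidistant gene assignments go to the lexicographically first gene id and
are logged. Degenerate inputs (constant correlation vectors, empty TEP
sets, zero upstream coverage, sites at contig edges) raise or are excluded
with a count, never silently NaN.

## Known limitations

* Absolute ΔG values are specific to the bundled energy table; only the
  median-based HS/LS split, not a fixed −19 kcal/mol, transfers across
  energy scales.
* An 8-bp GC stem (~−17 kcal/mol here) sits near the median of a 65%-GC
  background ΔG distribution, so on some seeds a single weak planted
  terminator can fall on the LS side of the split.
* The secondary-TEP window equals the primary window (300 nt); C-class
  TEPs require a mapped primary TSS; internal TSSs are sense-strand only,
  with antisense reported separately.
* TU pairing is greedy nearest-downstream; nested or overlapping TUs
  (e.g. internal starts giving suboperonic transcripts) are not modeled.
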