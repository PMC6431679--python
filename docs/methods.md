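# Methods

`subgenomics` analyses a pair of sibling tree genomes that share an
ancient whole-genome duplication (WGD): two homoeologous subgenomes per
species, asymmetrically fractionated, compared against each other, against
the sibling species, and against a pre-WGD outgroup.  Because the
analyses are defined on annotations, hit tables, expression matrices and
label maps — not on raw reads — the package ships a seeded generator
that produces complete synthetic studies with known truth, and every
analysis stage is validated against that truth.

## The simulated evolutionary model

An ancestral genome of `n_chromosome_pairs` chromosomes with
`genes_per_chromosome` genes each is duplicated at `wgd_time` (default
66 My, the Cretaceous–Paleogene boundary).  Post-WGD gene loss is a
run-deletion process: runs start per gene with probability
`p/deletion_run_mean` and extend geometrically (mean 1.5 genes,
"deletions involving one or few genes"), with the initiation probability
multiplied by `proximal_multiplier` (default 3) inside the central 10% of
each chromosome — proximal deletions are larger and more frequent.
Loss is asymmetric by construction: the marginal per-copy deletion
probability is 0.32 on the dominant subgenome and 0.51 on the
subdominant one, chosen so that subgenome retention matches reported
gene counts of a walnut-sized genome (≈18k vs ≈13k surviving copies from
a ≈27k-gene ancestor).  Deletion hazards are split exactly between the
shared branch (WGD → speciation at 8 My) and the two species branches,
so lineage-specific singleton loss is also simulated.

Structural rearrangements use the classic event codes (A/B/C inversions
of 2/3/>3 genes, D/E/F intra-chromosomal translocations, iT/T
inter-chromosomal, Dup, Del).  Requested counts are placed on branches R,
M or RM (shared) with configurable probabilities; events never overlap
and always keep two intact flanking anchor genes, which is what makes
them identifiable at all — real nested/overlapping events are handled by
the classifier's iterative peeling but are not generated.  Default
counts are the observed between-species spectrum
{C: 28, Dup: 21, F: 3, iT: 14}.

Coordinates are 1-based inclusive; gene starts are cumulative
exponential spacings with mean `mean_intergenic_bp` = 16.9 kb.  Distances
are always measured between start nucleotides.

## Collinear chains

Each query gene contributes its top hit; three or more genes are
collinear when their target starts on one chromosome are strictly
monotone (ascending or descending), successive starts differ by
< 0.5 Mb, and at most `max_interrupt` (default 3) consecutive query
genes are skipped between members.  A chain always absorbs the *next*
eligible gene; a gene is an interruption only if it cannot fit.  (Free
skipping would make the enumeration of maximal runs exponential and the
notion of "the" chain ill-defined.)  Chains are grown from left-to-right
seeds in both orientations, the longer orientation wins (ascending on
ties), and chains contained in other chains are dropped.  The summary
reports the percentage of query genes in at least one chain.

## Rearrangement classification and branches

Shared genes per chromosome pair define a rank permutation.  The
classifier first removes explainable non-permutation signals — unhit runs
flanked by target-adjacent anchors (Del), off-chromosome contiguous runs
(iT), runs of near-top-score duplicate hits out of collinear context
(Dup; the in-context run is the original) — then decomposes the
permutation into ±1 strips and iteratively undoes the smallest
explainable event: an in-place descending strip is an inversion (A/B/C
by size), a displaced ascending strip that fits a unique gap elsewhere
is an intra-chromosomal translocation (D/E/F).  Undoing outermost events
first lets nested events surface on later iterations.  A best hit below
70% of the genome-wide median best score is treated as non-orthologous,
because a gene whose orthologue was deleted falls back to its WGD
paralogue and would otherwise fake a translocation.

Branches are assigned by three-genome parsimony: the window (event genes
plus one flank on each side) is rank-ordered in query, target and
outgroup; the lineage whose order departs from the outgroup is derived;
shared derived order maps to the pre-divergence branch; missing outgroup
genes leave the event unassigned.  Rates divide the count of major
events (C, F, iT) by branch time in My.

## Fractionation statistics

Within a homoeologous pair, the chromosome with more genes is dominant;
pairs are reported in descending dominant-gene order.  Surviving
collinear paralogue pairs are the anchors; N+1 anchors delimit N
intervals, and every non-anchor gene falls in exactly one interval (or a
flank, excluded from the test but reported).  Counts are compared with a
two-tailed paired t-test (df = n−1); zero-variance differences are
flagged and reported at the exact limit (p = 1 at zero mean difference,
else p = 0).  2-Mb window counts are keyed to dominant-chromosome
coordinates, with subdominant singletons mapped through their interval's
dominant anchor.

## Molecular clock

Ka/Ks uses degeneracy site counting (per position, the synonymous
fraction of the non-stop single-nucleotide changes; synonymous +
nonsynonymous sites = 3 per codon exactly) and difference counting by
averaging over all mutation-path orderings per codon pair, excluding
paths through stops.  Two corrections are available: `NG86`
(one-parameter, Jukes–Cantor style) and the default `K2P-weighted`
(synonymous transitions and transversions separated, Kimura
two-parameter correction); saturation (non-positive log argument) is
flagged rather than silently clamped.  Codon alignments come from a
global protein alignment (BLOSUM62, gap open −11, extend −1)
back-translated so all gaps are codon-sized.

The clock is r = K/(2t); dating is t = k/(2r)/1e6 with percentile
(2.5/97.5) intervals over per-gene estimates.  The sequence simulator is
calibrated to this estimator: each codon's total synonymous substitution
flux equals `clock_rate_ks` times its current synonymous site count
(nonsynonymous likewise), with transition/transversion choice weighted
by `ts_tv_ratio` within each class and stop-creating changes forbidden.
Hence E[Ks] ≈ 2rt by construction and clock recovery is a genuine
round-trip test of the estimator, not of the simulator.

Ks mixtures are summarised by KDE mode detection on log(Ks) (Silverman
bandwidth, relative prominence 5%); the raw-scale KDE smears the
ortholog peak (~0.04) into the WGD peak (~0.33) at realistic bandwidths.
The NJ dendrogram on Ka distances (scikit-bio `nj`) stands in for
full ML phylogenetics, which is out of scope.

## Expression dominance

Pairs are differentially expressed when
(x_d + ε)/(x_s + ε) exceeds the strict two-fold threshold (ε = 0.1 FPKM;
both copies below ε → not-expressed).  Per chromosome pair, dominant vs
subordinate call counts are compared with a paired t-test across pairs;
per-dataset count tables are also emitted, since a pair inconsistently
called across datasets can be aggregated either way.  The generator
gives a configurable fraction of pairs (default 0.3) a 2.5-fold
dominant-copy boost under log-normal noise (σ_log = 0.2) across a
default 22 datasets; biased-fraction recovery is evaluated on per-pair
means across datasets, where single-dataset noise averages out.

## Landmarks

Telomere arrays are maximal runs of perfect CCCTAAA copies anchored at
the terminus (reverse complement at 3′ ends); the boundary is sharp when
no partial motif prefix follows the last full copy.  An off-by-default
tolerance mode (≤k mismatched bases per 10 copies, integer accounting)
bridges short insertions.  The subtelomere spans from the array to the
first gene start; the first three intergenic distances are reported.
Centromeres are single-linkage clusters (gap ≤ 100 kb, ≥10 copies) of a
12.5-kb retroelement; the generator plants 62 copies in a 3-Mb span plus
scattered background copies.  Repositioning between homoeologues is
classified from collinear anchors: same flanking anchors → conserved;
two arrays, or an array abutting a reversed-anchor run boundary (within
one median anchor spacing) → inversion-split; otherwise → translocated.
Equal-gene windows (default 20 per arm, remainder to the distal side)
feed a Spearman correlation of window rank against class proportion;
fixed-width density profiles feed Pearson correlations, undefined (and
flagged) below three windows.

## Optical-map trio

Label maps are strictly increasing nicking-site positions plus a length.
The aligner is a fitting dynamic programme over inter-label interval
chains: moves merge up to 3 labels on either map, score
`match_reward · (1 − relδ/tol)` (clipped at −2·reward) minus a penalty
per merged label, with free reference end gaps and both orientations
tried; defaults tol = 0.1, reward = penalty = 3.  Significance is a
200-permutation shuffle of the query's intervals; an alignment is
significant when its score is positive and p < 0.01 (null fitting scores
are strongly negative, ≈ −47 for 25-label queries).  Diploid (phased)
regions are intervals of one map covered by a near-identical smaller map
of the same set (≥60% labels matched, positive score); the additivity
check aligns both haplotypes of each phased region to the hybrid maps,
disregards the losing haplotype's length (ties keep haplotype 1 and are
flagged), and reports |hybrid − edited parent sum| as bp and percent.
Scaffolds go to the parent with the clearly better score (margin 5%);
near-ties are flagged ambiguous and <5-label scaffolds unalignable.

The generator draws an ancestral Poisson site process (default 10
labels/100 kb) shared by orthologous chromosomes, applies 15% per-species
site turnover, one phased region per chromosome covering
`phased_fraction` of its length with a 10%-diverged second haplotype,
and measures every map with per-interval relative noise (σ = 0.02); the
hybrid inherits haplotype 1.  Map length is the noisy interval sum, so
additivity holds only statistically — as in real data.

## What the generator does not emulate

Read-level sequencing and assembly error, molecule-level optical-map
assembly, TE family evolution, tandem-array gene families, gene gain,
segmental CNV polymorphism, expression correlation structure across
datasets, and GC/codon-usage heterogeneity.  Passing tests therefore
demonstrate correctness of the analysis logic under the stated
generative model, not robustness to annotation noise in real genomes.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to keep the
statistical checks well-powered while remaining quick: full default
studies of 8 chromosome pairs × 1000 ancestral genes for fractionation
and collinearity; 2 × 500 genes (≈2000-gene genomes) for rearrangement
recovery; 300 gene pairs × 300 codons for clock recovery; 2 × 300-gene
genomes (≈5-Mb chromosomes, ≈500 labels) for the trio; 100-replicate
power/size experiments and ≥100-case classification accuracy sweeps.

## Known limitations

The D/E/F move detector prefers the smallest displaced block; a
translocation and its complementary-block interpretation are genuinely
indistinguishable when both blocks are small.  Del events and
fractionation deletions are the same two-genome signal, separated only
by the outgroup.  The spreadsheet-style judgment calls of manual
rearrangement curation are approximated by deterministic rules, not
claimed identical.  The optical-map scoring model is a transparent
surrogate for proprietary vendor tooling, with parameters exposed rather
than matched.
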