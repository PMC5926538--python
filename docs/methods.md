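# Methods

This note documents the models, conventions and numerical choices behind
`syntelnc`, and what the synthetic benchmarks do and do not demonstrate.

## Coordinates, strands, annotations

All internal coordinates are 1-based inclusive (GTF convention); the only
0-based half-open surface is BED output. Strand is `+`, `-` or `.`
(unknown). Unknown strand is a first-class value because spliced-alignment
assemblers infer strand from splice sites and therefore leave mono-exonic
transcripts unstranded; every strand-sensitive operation states its
unknown-strand behaviour (filtering screens both strands, classification
reports `overlap_strand_unknown`, mapping tries both target strands, ORF
search optionally scans the reverse complement). Both GTF 2.2 and GFF3 are
parsed through one reader; source biotype strings map into the closed set
{protein_coding, pseudogene, lncRNA, other} via a configurable table, so an
Ensembl-style GTF and an NCBI-style GFF3 need no dialect-specific code.

## Candidate filtering

Length means summed exon length (transcript length), not genomic span,
consistent with the "more than 200 nucleotides" definition of a lncRNA. The
mono-exonic threshold is ≥ 500 bp, since ~200 bp could be spanned by a
single read pair. Overlap with protein-coding/pseudogene annotation is
measured on genomic spans and tolerated up to 1 bp on the same strand;
unknown-strand models are screened against both strands (conservative:
fewer false lncRNAs). Exclusion decisions carry exactly one reason — the
first failing rule in a fixed cascade — so re-running on permuted input is
reproducible. The CPAT probability direction is ambiguous in common usage;
the default treats *coding probability < 0.58* as the non-coding verdict
(conventional CPAT semantics), with `cpat_higher_is_noncoding=True`
honouring the literal opposite reading. CPC uses a strict `< −0.5`;
homology E-values at exactly 10⁻⁵ count as hits. The "previously
protein-coding" filter is an explicit id list, not a homology search.

## Positional classification

Overlap with a known gene takes precedence (largest overlap wins ties).
Within 5 kb of the nearest TSS, up/downstream is defined relative to the
nearest gene's transcription direction (model 5′ of the gene's TSS =
upstream); a model or gene with unknown strand is reported as same-strand.
TSS positions come from per-transcript starts when the reference has
transcripts, else gene starts (`tss_source` selects explicitly). Distance
between a model and a TSS is the minimum over the model's endpoints, zero
if the TSS falls inside the span. Intergenic bins are half-open
([5,10), [10,20), [20,50), [50,100), [100,500) kb, [500 kb,1 Mb), [1 Mb,∞))
so every distance maps to exactly one bin.

## Synteny blocks

Triples are built per chromosome over protein-coding genes carrying a
symbol, sorted by start; symbol-less genes are skipped entirely — they
neither anchor nor break adjacency — because symbol identity is the only
cross-species key available. First/last genes have no triple. Matching
demands the identical ordered symbol triple (upper-cased exact match);
duplicate symbol triples within a species (tandem arrays) are dropped with
a warning to avoid ambiguous blocks. `allow_reversed` (off by default)
additionally matches reverse-ordered triples for oppositely oriented
assemblies, with the position slots swapped accordingly. A lncRNA occupies
a block position when its genomic span is fully contained in the intergenic
interval (containment fraction configurable). A conserved position is one
occupied in both species; block-percentage reporting counts blocks with at
least one conserved position, to two decimals.

## Global alignment and the 20-residue run criterion

The aligner is an affine-gap (Gotoh) Needleman–Wunsch with EMBOSS-needle
default scoring pinned explicitly: match +5, mismatch −4, a gap of length L
costing 10 + 0.5·L, and free terminal gaps. These constants make every
attainable score a multiple of 0.5, hence exact in binary floating point,
so traceback decisions use exact equality. The horizontal-gap state is
evaluated as a running maximum of `best + 0.5·k` over columns — equivalent
to the textbook recursion because merging two same-direction gaps never
beats one longer gap — which lets each row be computed with vectorised
array operations (≈ 60 ms for a 600 × 2500 problem). Traceback ties resolve
diagonal > up > left, and gap closure is preferred over extension on a tie.

Acceptance requires a run of ≥ 20 alignment columns that are exact base
matches with no gap in either row; `N` never matches anything, including
`N`, since a run is evidence of sequence identity. Both target strands are
attempted (the higher run wins; tie → plus strand). The inferred locus is
the aligned target extract after trimming terminal gap columns; an
alternative `extract="run"` mode returns only the span of the best run. An
accepted alignment implies the two sequences share an exact 20-mer; the
converse need not hold. Note that among co-optimal alignments of unrelated
sequences the run length is not unique, so run-length symmetry under
reverse complement is guaranteed only when the optimum is unique (e.g.
substitution-diverged homologs).

## Expression statistics

Transcript TPM are summed to gene level per sample; tissue profiles are
replicate means. Level bins are half-open ([1,10), [10,50), ≥ 50 on the
across-sample mean) so the partition is total — the printed forms of such
bins traditionally leave the value 10 unassigned. τ is computed on
untransformed per-tissue means (a log2(x+1) option exists); an all-zero
profile has undefined τ, reported as missing. The mean/median ratio divides
the across-sample mean by the across-tissue median, substituting 0.01 for a
zero median. PEM clamps tissue means below 1 to 1, takes log₂, and centres
by the across-tissue mean of those logs, so PEM sums to zero per gene.
Category evaluation order is fixed: not detected → tissue specific (one
tissue > 0, all others exactly 0) → tissue enriched (top tissue ≥ 5× every
other) → group enriched (every tissue of a predefined ≥ 2-tissue group ≥ 5×
every outside tissue — the strictest reading; a group-mean variant is a
config option) → tissue enhanced (≥ 5× the mean of detectably expressed
tissues) → expressed in all (> 1 TPM everywhere) → mixed. Reproducible
detection supports two modes: ≥ 1 estimated count in every replicate of the
top-mean-TPM tissue (ties broken lexicographically), or > 0.01 TPM in every
individual.

## Co-expression network and Markov clustering

Pearson r is computed on per-sample TPM without transformation (a
`log2p1` option exists); edges keep signed r ≥ 0.95, so anti-correlations
are discarded. Zero-variance genes are excluded with a logged count. MCL
runs on the weighted adjacency plus unit self-loops, column-normalised;
each iteration applies expansion (matrix power 2), inflation (elementwise
power, default 2.2, renormalised), and pruning of entries < 10⁻⁵ with
renormalisation; convergence is a max-change < 10⁻⁶ within 100 iterations
(non-convergence returns the current clustering flagged). Clusters are read
from attractor rows (nonzero diagonal), merging overlapping supports; nodes
are processed in sorted order so insertion order is irrelevant. Pruning and
self-loop settings are implementation-defined, as typical MCL front-ends
delegate them to the tool.

## Proximity randomisation tests

Genomic distance is the gap between nearest interval ends (0 for overlap or
abutment), using full gene spans. For a lncRNA with y same-chromosome
protein-coding cluster members, each of s = 1000 subsets draws y genes
without replacement from all protein-coding genes on that chromosome. Two
p-values are reported. `p_literal` = (s − q + 1)/(s + 1), with q the number
of subsets whose nearest-gene distance the observed value *exceeds*, is that
counting formula reproduced exactly; it approaches 1 when the lncRNA is
unusually *close* to its cluster, i.e. it points opposite to the usual
small-p-means-enriched convention. `p_empirical` = (#{subset distance ≤
observed} + 1)/(s + 1) is the standard one-sided add-one permutation
p-value for "the observed distance is unusually small"; significance calls
use it, ties counting toward the tail (conservative). Each lncRNA gets its
own RNG stream derived from a CRC of its id plus the global seed, so
results are order- and parallelism-independent. The analogous correlation
test compares |Pearson r| with the nearest coding gene against 1000 random
same-chromosome coding genes (without replacement where the pool allows,
logged otherwise). A Benjamini–Hochberg column is emitted as a convenience
but never gates results.

## Reconstruction reproducibility

Merging is a deterministic, simplified reimplementation of an assembly
merge rather than a wrapper around an external tool: multi-exon transcripts
collapse by exact (chrom, strand, intron chain) with outermost termini;
mono-exon transcripts single-linkage cluster at ≥ 95% reciprocal overlap,
merged to the union extent. "Precisely reconstructed" means identical
intron chain (multi-exon) or ≥ 95% reciprocal overlap with a merged
mono-exon model; both thresholds are configurable, and the mono-exon rule
is implementation-defined since exactness has no natural meaning for
unspliced models. Subsets are enumerated canonically (subset k contains
individual i, sorted by id, iff bit i of k is set), capped at n = 16.
Because merging is a union, reconstruction is monotone over subset
inclusion; "reconstructed in all subsets" is therefore equivalent to
"reconstructed in every singleton", which the tests assert as a
cross-check.

## Synthetic data: what it emulates, and what it does not

The genome generator lays out symbol-sharing protein-coding genes (2–3
exons each) in conserved order on both genomes, locally permuting 3-gene
windows in species B at the rearrangement rate; background intergenic
sequence is i.i.d. uniform and independent between species, so cross-species
alignment signal comes only from the planted lncRNAs. Each planted lncRNA
(default 40 per pair, 500–1000 bp — long enough that the mono-exonic
retention rule keeps a clean candidate) occupies one intergenic slot ~30 bp
from one flanking gene, emulating enhancer-associated lncRNA geometry; its
species-B copy carries independent substitutions at `divergence_mu`
(default 5%, a plausible divergence for closely related ruminant genomes;
indels are a separate rate, default 0, because the gapless run criterion
makes substitution-only the clean recovery regime). Capture by "assembly"
is an independent Bernoulli per species (default 0.7), mirroring the
stochastic sampling of lncRNAs by RNA-seq.

Expression tables are generated at transcript level over a 10-tissue,
6-group panel with 4 replicates: housekeeping genes share a flat profile,
tissue-specific genes are nonzero in exactly one tissue, co-expressed
lncRNA–mRNA pairs share a lognormal latent tissue profile (sd 2.0) with
multiplicative replicate noise (sd 0.15 — about 15% replicate-level
variation, chosen so that shared-profile pairs genuinely exceed the 0.95
correlation threshold the network stage uses; at substantially higher
noise no method could place them in one cluster). Columns are normalised
to TPM (sum 10⁶) and est_counts are derived consistently with
TPM × effective length. The dedicated program-matrix generator uses
replicate noise 0.1 for the same reason. Per-library captures drop or
truncate each transcript independently (default dropout 0.3).

Each generator draws from its own RNG stream (`seed + fixed offset`), so
adding one generator never reshuffles another's output, and all outputs are
byte-identical under a fixed seed.

What passing the synthetic benchmarks shows: the filters implement their
stated predicates exactly; the aligner is optimal (verified against
exhaustive enumeration and an independent library implementation); the run
criterion separates 5%-diverged orthologs (≥ 95% recovered at ≥ 300 nt)
from random sequence (≤ 1% accepted) with the claimed margins; the
specificity statistics satisfy their defining identities; MCL recovers
planted disjoint programs; the permutation test is calibrated under the
null and powered for adjacent planted pairs; reconstruction counting is
exact over all 63 subsets. What it does not show: performance on real
assemblies with fragmented or chimeric models, paralogy and repeat-driven
false synteny, indel-dominated divergence, GC/repeat compositional
structure, or library-level coverage effects — none of which the generators
model. Problem sizes (3–5 chromosomes, tens of genes per chromosome,
~200 planted pairs for rate estimates, s = 1000, 500 null replicates) were
chosen as the smallest giving stable estimates at the stated margins.

## Known limitations

* Symbol identity is the only orthology signal; paralog shuffling within a
  symbol set is invisible beyond the duplicate-triple exclusion.
* The aligner materialises full score matrices (four float64 matrices of
  (|q|+1)×(|t|+1)), fine at intergenic scale but not for megabase targets.
* The literal (r+1)/(s+1) p-value formula is reported but intentionally not
  "fixed"; consumers must choose the column that matches their convention.
* MCL cluster ids are deterministic but arbitrary (ordered by size, then
  lexicographically smallest member).
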