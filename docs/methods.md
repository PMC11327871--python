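# Methods

This note records the models, conventions and design decisions behind
atlaskit, in the spirit of a statistical-software methods appendix. It
states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and annotation model

All in-memory coordinates are 0-based half-open; GTF I/O converts
to/from the format's 1-based fully-closed convention at the boundary.
The TSS of a transcript is its 5' end: the minimal exon start on the
'+' strand, the maximal (exclusive) exon end on the '−' strand. Using
the exclusive end as the '−' TSS keeps all arithmetic in one
convention; note that distances between a '+' TSS (a base coordinate)
and a '−' TSS (one past a base) are therefore defined on half-open
coordinates, which can differ by 1 bp from "between-base" arithmetic
done on 1-based positions.

GTF attribute values have no standard escaping; reserved characters
(`;`, `"`, `%`, tab, newline) inside values are percent-encoded on
write and decoded on parse, so annotations round-trip exactly even with
punctuation in gene names. Exons that overlap within one transcript are
merged at construction (some sources emit duplicated exon records).
Genes lacking an explicit `gene` feature are reconstructed as envelopes
of their transcripts and tracked in `Annotation.reconstructed_gene_ids`.

Biotypes collapse to five classes — `pcg`, `lnc`, `mirna`, `smallrna`
(snoRNA, snRNA, sRNA, tRNA, rRNA, scaRNA), `other` — through an
explicit mapping covering the RefSeq/Ensembl vocabularies; unmapped raw
labels fall back to `other` with a warning rather than failing, since
sources routinely invent labels.

## Sequential merge

Sources are merged in a stated priority order (most reliable first),
iterating biotype classes in a configurable order (default
`pcg, lnc, mirna, smallrna, other`: coding annotations are the most
consistently supported, so they anchor the atlas). A candidate is
rejected when it shares ≥ 1 exonic base pair, on the same strand, with
any already-retained gene — computed on the exon union over all of the
gene's transcripts, which is equivalent to any-transcript overlap for a
≥ 1 bp criterion. Two scopes are offered: `any_class` (default; a
candidate overlapping *any* retained gene is rejected) and
`same_class` (only same-biotype overlaps reject), because "aggregated
by biotype class" admits both readings; both are tested.

A rejected gene is recorded against the retained gene with the largest
shared exonic bp (ties: lowest chrom, start, gene_id). Whole genes are
rejected, never individual transcripts. Repeatability of a retained
locus is the set of sources with ≥ 1 bp same-strand exonic overlap,
including its own. Duplicate gene ids across sources are namespaced
`source:gene_id` with a warning.

Invariants enforced by tests: retained set has zero pairwise same-
strand exonic overlap (brute-force all-pairs check), every input gene
is retained or appears in exactly one correspondence row, promoting a
source in the priority order never reduces its retained count, and
identical inputs give byte-identical outputs.

## Expression normalization and aggregation

TPM is computed as reads per kilobase rescaled to 1e6 per sample
(all-zero samples stay zero and are flagged). TMM scaling factors are
implemented natively: per-gene log2 fold changes (M) and mean log2
abundances (A) versus a reference sample are doubly trimmed (defaults
0.30 on M, 0.05 on A — the standard values, exposed as parameters),
averaged with inverse delta-method variances, and the factors rescaled
to geometric mean 1. The reference defaults to the sample whose
library-size-scaled 75th percentile is closest to the mean of those
percentiles. Agreement with the standard R reference implementation was
verified to ~1e-10 on a 100-gene simulation whose expected factors are
frozen in the test suite.

"TMM expression" in the expressed-gene rule means CPM computed on
TMM-effective library sizes (library size × factor), the standard
meaning in differential-expression practice.

Tissue profiles use the two-stage median — median across samples within
each (tissue, project), then median of project medians per tissue — so
large projects cannot dominate a tissue. Medians of even counts are
midpoints. Tissues with no samples are absent from profiles, not zero.

The expressed flag requires both the tissue-median condition
(≥ 0.1 TPM somewhere) and a per-sample condition (some (tissue,
project) where ≥ 50% of samples jointly reach ≥ 6 reads, TPM ≥ 0.1,
TMM-CPM ≥ 0.1; "at least 50%" is inclusive, so 2 of 4 qualifies). By
default the two conditions may hold in different tissues; a
`strict_same_tissue` mode requires them to coincide. The flag is
monotone in counts/TPM and invariant to globally rescaling all
libraries, both property-tested.

## Tissue specificity

τ is computed over all tissues in the profile (not only expressed
ones); an option to restrict would only raise τ for sparsely expressed
genes and is left to the caller via profile filtering. τ is undefined
(null) for an all-zero profile; flags treat undefined as 0. The log10
variant uses log10(x + 1): the +1 pseudocount keeps zeros at zero and
is exposed as a parameter. τ ≥ 0.90, inclusive, flags tissue
specificity.

Break detection ranks tissues by decreasing median (ties broken by
tissue name; a tie has FC 1 and never breaks) and splits where the
consecutive ratio is ≥ 2 (inclusive). Tissues below the 0.1 TPM
expression floor are excluded from the scan — a ratio against ~0 would
make everything look specific — and form one trailing group behind an
implicit break whose recorded FC is the observed ratio (infinite over
zero). Scanned breaks always have FC ≥ the threshold; the implicit
boundary FC may not, which is the price of keeping "groups partition
all tissues" true. First-break statistics compare the first two groups
three ways (min/max, max/max, median/median) and are null when no break
exists or a denominator is zero.

## Pair classification

Partner search minimizes TSS-to-TSS distance over all transcript pairs
within a 100 kb window; a candidate whose span overlaps the focal span
(any strand) qualifies regardless of TSS distance and takes precedence.
Category is genic iff spans overlap on any strand. Orientation: sense
for equal strands; for opposite strands, divergent (head-to-head) when
the '−' gene's TSS lies left of the '+' gene's TSS, convergent
(tail-to-tail) otherwise. For overlapping antisense pairs this TSS rule
is a pure convention — a '−' TSS left of a '+' TSS cannot overlap it,
so genic antisense pairs always resolve to convergent; such records
carry a `genic_antisense_by_tss` flag and no claim of fidelity to any
external classifier's internals. Genic sub-labels add exonic/intronic
(exon unions intersect or not) × nested/overlapping (one span contained
in the other or not). Intergenic distance is TSS-to-TSS per the window
criterion; the span gap is reported alongside for transparency.

## Co-expression

Kendall's τ-b (tie-corrected) is the default: per-tissue medians
contain ties (zeros) and rank correlation is invariant to the monotone
transforms routinely applied to TPM. Spearman is available, as reported
correlations in atlas front-ends are often ρ. Correlation is null for
constant vectors or fewer than 3 points. Implementation delegates to
scipy; the test suite checks it against an independent O(n²)
concordant/discordant counter to 1e-12 on heavily tied vectors.
Top-k ranking orders by descending correlation (nulls last, ties by
gene id) and flags same-chromosome and within-100 kb partners from the
annotation.

## Synthetic data generator

The generator emulates the *structure* of a large multi-source tissue
atlas at desk scale. Defaults (one tenth of a typical atlas design):
3 sources of 300/120/80 genes on 3 chromosomes, overlap fractions
0/0.4/0.4 versus source 1, 8 tissues × 4 projects × 3 samples, 20
planted 50-fold tissue-specific genes, 5 planted co-expressed pairs
realized geometrically (divergent at 3,079 bp and 100 bp, convergent,
sense, nested-intronic) and in expression.

Expression model: per-gene baseline TPM ~ LogNormal(log 50, 1.0) —
centred on a comfortably expressed level so planted-signal recovery
measures the metrics, not dropout; per-sample replicate noise LogNormal
sdlog 0.3 (~1.35× scatter, typical of homogeneous projects); planted
pair genes share a per-tissue latent factor of sdlog 2.0 (~50× dynamic
range, the regime of strongly regulated genes) at latent correlation
0.999, with their baselines pinned in the well-expressed range —
near the detection floor counting noise would swamp the latent factor
and the declared correlation would not actually be present in the
emitted data. These three values were calibrated jointly, once, by a
power analysis of Kendall recovery: with 8 tissues τ moves in 1/28
steps and ~1 of 420 null genes exceeds τ ≈ 0.79 per focal gene, so a
recoverable planted pair must keep expected rank inversions well below
3; the chosen spread/noise/ρ combination achieves zero directed top-10
misses over 200 planted-pair lookups across 20 seeds. Counts are
multinomial given the length-weighted TPM composition and a library
size drawn log-uniformly over one decade (5e5–5e6) to exercise TMM.

What the generator does **not** emulate: dropout and zero inflation of
lowly expressed genes, project-level batch effects, sex/age effects
beyond metadata labels, realistic chromosome-scale gene density,
isoform-level variation, and the compositional extremes of real
libraries. Passing planted-recovery tests therefore demonstrates that
the metrics and rankings recover clean planted structure, not that they
are robust to every artefact of real RNA-seq.

TPM compositionality is visible even in synthetic data: planted
tissue-specific genes imprint a shared per-tissue denominator dip on
all other genes, and ρ=0 pair genes correlate weakly through the shared
denominator. Tests account for this explicitly rather than pretending
TPM vectors are independent.

## Problem sizes

The default verification battery (test suite and acceptance script)
uses 1,000 random profiles for the τ oracle, 500 tied vectors (n ≤ 200)
for the Kendall oracle, 50 random three-source fixtures for merge
exclusivity/conservation, a 500-gene annotation for brute-force
closest-partner comparison, and the default 420-gene / 96-sample
fixture for planted-signal recovery — sizes chosen so the whole battery
runs in seconds while keeping every check at full strictness.

## Known limitations

- GFF3 is not parsed; convert to GTF first.
- Merging rejects whole genes; partially overlapping genes are never
  split at the transcript level, so a fused model in a high-priority
  source shadows distinct models in later ones (they remain visible in
  the correspondence table).
- Orientation of overlapping antisense pairs is a convention (above).
- The expressed-gene rule needs raw counts; TPM-only datasets can
  compute profiles and τ but not the expressed/highly-expressed flags.
- Kendall τ over few tissues is coarsely quantized (1/28 steps at 8
  tissues); top-k lists at small T should be read with that granularity
  in mind.
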