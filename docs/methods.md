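# Methods

This note documents the models and procedures implemented in `isoforge`, the
parameters that matter, the design decisions taken where the problem was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## FLNC classification

A read of insert is searched for the 5′ primer within the leading window and
for the reverse complement of the 3′ primer within the trailing window, both
by Hamming distance (defaults: `max_mismatch = 2`, `search_window = 100` bp).
Vendor Iso-Seq pipelines do this with proprietary aligner heuristics; a
transparent fixed-window Hamming matcher is used here so behaviour is exactly
testable. The polyA signal is a run of ≥ `min_polyA_run = 20` A's immediately
upstream of the 3′-primer match, tolerating one non-A per ten bases. Reads
shorter than `min_length = 300` bp are filtered first, before any other call;
reads with all three signals plus at least one additional interior primer
match are full-length chimeric; all three signals with a clean interior is
FLNC; anything else is non-full-length. This precedence (short → chimera →
FLNC → non-FL) makes the four classes a partition. The length cutoff and
polyA rule are package choices: library reports in this field state the
filtered-short class without the cutoff used.

Library summaries count signal presence per read; aggregate summaries are
fieldwise sums with an FLNC-count-weighted mean insert length. Note that
vendor "number of 5′/3′ reads" columns can double-count in ways their
pipelines define; here each read contributes at most once per signal.

## Transcript collapse and completeness

Redundant isoforms are collapsed in coordinate space rather than by sequence
identity clustering: multi-exon models merge when their intron chains are
identical and their terminal ends differ by at most `fuzz_end = 50` bp
(single linkage); the representative spans the extremal ends, so the union of
exonic bases is invariant under collapse. Mono-exon models merge at
reciprocal overlap ≥ 0.95, a common long-read cutoff. Coordinate-space
collapse is deterministic and alignment-free, and the downstream analyses
consume models, not sequences.

N50 is the largest length L such that transcripts of length ≥ L account for
at least half the summed length. Ex90N50 applies the same statistic to the
smallest expression-ranked transcript set reaching ≥ 90 % of total TPM (ties
broken by length, then identifier, for determinism). Ex90N50 is *not*
guaranteed ≤ N50; only the definition is asserted, against a brute-force
scan in the tests.

## Annotation refinement

**Split genes.** A transcript alignment supports merging a set of annotated
genes when its exons overlap the exonic bases of ≥ 2 same-strand genes by
≥ `min_exonic_overlap = 30` bp each (no threshold is standard; 30 bp rejects
incidental boundary touches). Proposals are connected components of the
gene–gene support graph, so they partition the genes they touch; support from
a single read suffices by default (`min_support = 1`, configurable).

**Novel isoforms.** The trichotomy is: unmapped (no alignment), intronic
(entirely inside one intron of a same-strand gene), intergenic (no exonic
overlap with any gene). Same-strand exonic overlap disqualifies an isoform
from being novel. Two tie rules are fixed: intronic takes precedence over
intergenic (more specific), and antisense exonic overlaps are categorized
intergenic with an `antisense_flag`, preserving the three-way totals without
losing strand information.

**lncRNA triage.** Channel one is an input homology-flag table (so a real
BLAST run against a protein database can be slotted in without code change);
channel two calls an isoform coding when its longest ATG-initiated stop-free
reading frame, over the three frames of both strands, reaches
`orf_min_codons = 100` codons — the conventional lncRNA ORF cutoff, standing
in for trained coding-potential classifiers. The Venn partition crosses the
two channels; the lncRNA set is the union of isoforms flagged by either.

## Alternative-splicing events

Events are local differences between isoform pairs of one locus, deduplicated
by `(type, chrom, strand, anchor coordinates)` so the same event witnessed by
several pairs counts once (event-centric totals, as in SUPPA-style outputs):

* **ES** — an internal exon of one isoform is spliced out by a single intron
  of the other; anchors are the flanking donor, the exon, and the acceptor.
* **IR** — one isoform's exonic block strictly covers the other's intron;
  anchors are the retained intron.
* **A5/A3** — two overlapping introns share exactly one boundary; the
  variable stretch between the differing boundaries must be entirely exonic
  in the isoform carrying the shorter intron. Without this condition, every
  exon-skipping pair would also emit spurious A5/A3 events (the skip intron
  shares each boundary with one flanking intron of the inclusion isoform).
  Labels are strand-aware: the donor is the intron's 5′ end in transcription
  direction, so reversing the strand swaps A5 and A3 and fixes ES/IR/AE.
* **AE** — two non-overlapping internal exons between the same flanking
  splice sites, each absent from the other isoform (the mutually-exclusive
  reading of "alternative exon", the standard five-type set).

Alternative first/last exons are recognised but reported outside the
five-type totals. Summary percentages are integer-rounded half-up (exact
decimal arithmetic, no float rounding artifacts); tissue isoform shares use
the same rule at 2 decimals. One known anchor inconsistency in published
five-tissue shares (a flower share printing 0.01 below the value implied by
its own counts) is left as computed, not "corrected".

## Ks estimation and WGD dating

NG86 with unweighted pathways: per codon, the synonymous-site fraction at
each position is the number of the three possible single-nucleotide changes
that preserve the amino acid, divided by 3 (changes to stop codons count as
nonsynonymous); site totals are averaged over the two sequences, so
S + N = 3 × codons used, exactly. Differences between codons differing at
k > 1 positions are averaged over all k! substitution orders, excluding
pathways through stop codons; if every pathway for a codon pair hits a stop,
that codon pair is dropped from both difference and site counts and reported.
Codon columns containing gaps or ambiguity codes are removed pairwise
(complete deletion). Proportions are corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is flagged saturated and the estimate left
undefined. Only the standard genetic code is supported. The implementation
agrees to machine precision with an exhaustive site/pathway enumerator and
with Biopython's NG86 reference on random pairs (test suite).

The Ks-distribution peak is the mode of a Gaussian KDE (Silverman bandwidth
by default) inside an analysis window of (0.05, 2.0): the low cutoff excludes
very recent — typically tandem — duplicates, the high cutoff saturated
estimates; both ends and the bandwidth are configurable because published
analyses rarely state their windowing. At least 30 usable values are
required. Dating uses T = Ks/(2r); the conventional plant rate
r = 6.5 × 10⁻⁹ substitutions · site⁻¹ · year⁻¹ puts a Ks mode of 0.34 at
26.15 million years. Paralog-pair identification (ortholog clustering) is out
of scope: pairs arrive as aligned-CDS FASTA files.

## Expression

TPM divides each count by transcript length and normalizes the rates to 10⁶
per sample (sum is exact to machine precision and invariant to uniform count
scaling); FPKM is counts × 10⁹ / (length × mapped total) and is not. Effective
length is the plain transcript length — no fragment-length correction — so the
quantities are exactly testable. Replicate concordance is Pearson r on
log2(TPM + 1); the transform is configurable since published methods often
state the coefficient but not the scale. Representative isoforms per gene are
the longest, with mean-TPM then identifier tie-breaks; "longest with the
highest expression" is ambiguous when the two conflict, so both orderings are
selectable (`prefer="length"` default, `prefer="expression"`). Tissue profiles
are replicate means of TPM.

## Synthetic data: what it emulates, and what it does not

The generator lays out genes sequentially on `n_chromosomes` random
chromosomes with random strands and intergenic gaps, then plants, with one
seeded RNG stream: split genes (a 6-exon gene emitted as two 3-exon fragment
annotations, plus the full-span long-read model), one two-isoform locus per
requested AS event (geometry chosen so exactly one event of the requested
type arises), intronic and intergenic novel transcripts, unmapped isoforms,
and designed coding/noncoding sequences (noncoding sequences avoid ATG and
CAT substrings, so they carry no start codon on either strand). Reads are
primer + insert + 30-nt polyA + primer with substitution errors only
(default rate 0.01; downstream stages consume alignments, not raw mapping, so
indel realism is unnecessary); chimeras concatenate two full read units;
non-full-length reads drop the polyA or the 5′ primer; short reads use an
80-bp insert. Counts are negative binomial (dispersion 0.1) around per-tissue
log-normal means shared across replicates, with the five-tissue × three-
replicate design as default. Paralog pairs evolve from a random CDS along two
lineages, each receiving Poisson(S₀ · target/2) synonymous substitutions
placed uniformly over the synonymous changes available in the current
sequence; substitutions creating stops are redrawn. Synonymous-only evolution
is deliberate: nonsynonymous changes are irrelevant to Ks recovery and would
only perturb the site counts.

Consequences for interpretation: passing the planted-truth tests shows the
*logic* of each stage is correct under clean structural signals. The
generator does not emulate sequencing-chemistry error profiles, indels,
alignment ambiguity, degraded or truncated cDNAs, expression-dependent read
sampling, or incomplete splice-site annotation — so recovery of 1.0 at zero
noise says nothing about accuracy on real libraries with those artifacts.
Default problem sizes (40 genes, 3 events per type, 60 paralog pairs of 300
codons, 15 samples) keep a full run under a second while every planted
category is populated; parameter-recovery checks use 200 pairs × 300 codons.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally; GFF3 is converted at the I/O
boundary (1-based inclusive), BED12 written 0-based half-open. Percent
rounding is half-up via exact decimals. Empty inputs raise (`summarize` on no
records, stats on no models, peak on < 30 values, TPM on all-zero counts);
zero-variance samples yield NaN correlations rather than errors. All outputs
are plain TSV/JSON; the pipeline report is byte-deterministic for a fixed
config, and the artifact manifest (checksums + timestamp) is the only file
that differs between identical reruns.
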