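# Methods

## Problem and model

Annotation lift-over transfers gene models from a well-annotated reference
genome to a target assembly via sequence homology. `protlift` consumes two
independent candidate annotations of the same target — a DNA-alignment
lift-over (gene → mRNA → exon/CDS with UTRs) and a protein-to-genome
alignment (mRNA → CDS only) — and emits one merged annotation per locus.
The objective is explicit: maximize the (gap-compressed) identity of each
annotated transcript's translation to its reference protein, while keeping
the DNA candidate's UTRs and non-coding features wherever the coding
evidence ties.

The merge is a two-step protein-maximization procedure (chaining, then ORF
search), preceded by transcript pairing and followed by locus/copy
resolution. Each step is described below with the numerical choices that
matter.

## Identity metrics

**DNA identity** — global Needleman–Wunsch with match +1, mismatch −3, gap
open 2, gap extend 2; identity = matching bases / alignment columns, gap
columns included in the denominator (the BLAST convention).

**Protein identity** — global alignment under BLOSUM62 with gap open 11,
extend 2. Identity = exact residue matches / columns, where each *maximal
run of reference-side gap columns counts once* (gap compression). This
stops a target protein that maps longer than the reference — repeat
expansions, or a truncated reference — from being penalized once per extra
residue. The target protein is truncated at its first stop codon *before*
alignment: residues downstream of a premature stop cannot count as matches,
and the uncovered reference tail stays in the denominator, so a
half-protein scores roughly the fraction of the reference it covers. (The
alternative reading — discarding all alignment columns after the stop —
would shrink the denominator and *reward* truncation, inverting the
objective that both the chaining and the ORF search optimize.)

**Partial identity** — the same gap-compressed formula restricted to the
alignment columns covering a reference-residue interval; reference-gap runs
attach to the residue on their 5′ side. This is the per-block score used by
the chaining step.

Gap-cost convention throughout: the open penalty applies to the first gap
residue and the extend penalty to each additional one (a gap of length
*L* costs open + (*L*−1)·extend). Scores for nonstandard symbols: `X`
scores 0 against everything; `*` scores +1 against `*` and −4 otherwise
(the stop rule wins for `X` vs `*`). The alignment engine is
Bio.Align.PairwiseAligner; its traceback is deterministic for a given
input, and co-optimal alignments may differ in match count, which is why
the test oracles enumerate all optimal alignments rather than pin one
traceback path.

## Pairing

A protein-based transcript matches a DNA-based transcript when (1) their
loci overlap on the same contig and strand, and (2) the protein-based locus
overlaps no *other* DNA-based gene locus except those the matched locus
itself overlaps. Candidates spanning two or more distinct DNA-based gene
loci are removed as read-throughs regardless of identity. Among survivors
the highest protein identity wins; ties break to the leftmost genomic
start. "Overlap" means ≥ 1 shared base, strand-aware, against gene spans.
Multiple mappings of one reference transcript are recognized by a
configurable id-suffix pattern (default `_ditto<N>`); DNA-based extra
copies by an `extra_copy_number` attribute or a `_<N>` id suffix.

## Chaining

Both candidate CDS chains are translated in full — internal stops stay in
the sequence as `*` residues — and aligned to the reference protein. Each
CDS's nucleotide extent becomes a complete-codon interval on its own
translation (a CDS ending mid-codon contributes its partial codon to the
next group), which the alignment columns convert into a cumulative count of
aligned reference residues; walking columns past query-side gaps is what
the cigar-adjustment step amounts to. Group boundaries are the interior
positions where both chains' cumulative counts coincide at a CDS end; the
final group always ends at the last CDS of both. Per block, the group with
the higher partial identity is selected, ties going to the DNA source so
that UTRs propagate; selected groups are concatenated, coordinates
defensively trimmed at source-switch junctions (never needed on the
generated worlds), and CDS phases recomputed from cumulative length. When
the candidates disagree on contig or strand, or one is absent, the DNA
candidate (or the survivor) is used whole.

Keeping internal stops in the aligned translation is essential: blocks
downstream of a premature stop must remain comparable, otherwise the chain
could never return to the DNA candidate after one bad block.

Merged exons follow the winning source per block — DNA blocks keep that
candidate's exons (with UTRs), protein blocks use their CDS intervals as
exons — with the DNA candidate's terminal UTR segments re-attached when a
terminal block went to the protein side, and touching intervals merged.

## Mutation classification and ORF repair

A mapped transcript is **identical** only when its spliced transcript DNA
(UTRs included) equals the reference's. Otherwise categories come from the
CDS: indel events from an affine-gap DNA alignment (match 1, mismatch −2,
open 5, extend 1 — a real opening cost keeps one mutational event as one
cigar run, which the linear-gap identity scoring does not guarantee), with
length mod 3 separating in-frame insertions/deletions from frameshifts;
codon-by-codon comparison separating synonymous from non-synonymous
substitutions when no indel is present; **stop gain** = a stop anywhere
before the end of the target translation (an in-frame deletion that merely
moves the terminal stop is not a gain); **stop loss** = a translation that
never stops while the reference does; **start loss** = the target CDS not
beginning with ATG while the reference does (first-codon check only). A
substitution that creates a stop is reported as stop gain, not additionally
as non-synonymous. Every non-identical transcript gets at least one
category.

Transcripts with a deleterious category (frameshift, stop gain/loss, start
loss) enter the ORF search: in each of the three frames of the spliced
transcript the longest ATG-initiated ORF is retained (ties: leftmost
start; no in-frame stop: the ORF runs to the last complete codon — the
stop-loss case). Search domain = the exon-level spliced sequence when exons
exist (so rescues can reach into either UTR), else the CDS chain itself.
Candidates are ranked by protein identity to the reference; frame ties
prefer the annotation's current frame, then frame 0 < 1 < 2. The CDS is
rewritten via the segment map when the best candidate's identity strictly
exceeds the current annotation's, **or** equals it while the candidate is a
well-formed start-to-stop frame and the current annotation is not. The
tie clause is needed because gap compression makes two canonical repairs
identity-neutral: extending a lost stop into the 3′ UTR (one compressed
overhang run either way) and trimming a CDS to a premature stop (the
translation is unchanged). A strictly-greater-only rule would leave both
malformed annotations in place. Post-repair identity can never drop — the
update is guarded — and the pipeline reports the *pre-repair*
classification, i.e. the mutations observed at the locus.

## Locus and copy resolution

Accepted gene loci are stored in per-contig interval trees. Overlap
fraction = shared bases / min(span lengths); a new locus is admitted when
every overlap with an accepted locus is ≤ 0.10 or the two source genes
already overlap in the reference (whitelist). Strand is ignored for
overlap (a locus blocks both strands). DNA-based extra copies additionally
need transcript-level DNA identity ≥ the `sc` threshold (default 0.95) and
are admitted best-identity-first, so results do not depend on input order.
Protein-only loci face the pseudogene filters: single-CDS candidates are
accepted only for single-CDS reference genes (the processed-pseudogene
guard — an intronless retrocopy of a multi-exon gene fails it), and the
summed CDS length must be 0.9–1.5× that of the reference gene's longest
isoform (by coding length). Accepted protein-only loci get a gene parent
copied from the reference gene and carry no UTRs. The first copy of an
otherwise unmapped gene keeps the reference id; extras get `_1`, `_2`, …
in (contig, start) order with an `extra_copy_number` attribute.

## Feature census

Genes are classed by their `gene_biotype`/`gene_type` attribute:
`protein_coding` (type `gene` + biotype `protein_coding`), `non_coding`
(`lncRNA`/`ncRNA`), everything else — pseudogenes, miRNA, tRNA, … —
`others`. Transcripts are classed by their own feature type *and* the
parent gene's class (an mRNA under a pseudogene is `others`). Counts are
split single-copy / multi-copy genes / extra loci.

## Synthetic worlds

The generator builds one gene per scenario on its own contig: 3–8 exons
(7 for the worked chaining example), 12–20 codons of CDS per exon, introns
of 45–90 nt rounded to a multiple of 3, 24-nt UTRs, 150-nt flanks —
contigs of a few kb, so the full suite runs in seconds. Genome mutations
(indels, premature stops, start/stop losses) are written into the target
sequence; aligner failure modes (missed splice sites, retained introns,
skipped exons, pseudogene hits) are planted as coordinate corruptions in
the candidate annotations, without running any aligner. Constraints that
make the truth tables exact rather than probabilistic: coding filler
codons are never ATG or a stop; every off-frame ATG in the spliced
transcript is scrubbed (otherwise a chance off-frame ATG can recover the
C-terminal half of a frameshifted protein and the expected repair is
ambiguous); UTRs carry planted in-frame stops/starts only where a scenario
needs them; the premature stop of the frameshift scenario sits mid-protein
so the frame-0 truncation dominates any off-frame ORF; the start-loss
(upstream rescue) scenario deletes the start codon rather than
substituting it, since under gap compression an upstream-start ORF
strictly beats the broken annotation only when the reference methionine is
recovered as a match. The tandem-duplicate copy differs from its source
only at six UTR positions (transcript identity ≈ 0.97, protein untouched).

What the worlds deliberately do not model: realistic splice-site motifs or
repeat content (candidates are planted, not aligned), multi-isoform genes,
minus-strand scenario genes (strand handling is exercised at the unit
level), overlapping gene neighborhoods beyond the planted cases, and
sequencing error. Passing tests therefore demonstrate the reconciliation
logic — not the behavior of the upstream aligners on real genomes.

## Degenerate inputs and tie-breaks

Empty sequences are alignment errors; a protein that is empty after stop
truncation scores identity 0. A CDS mapping entirely into a reference gap
gets a zero-width interval and is absorbed by its neighbor group. Zero
shared interior boundaries yield a single comparison block spanning both
chains. Partial-identity spans of zero width score 0. All iteration orders
are sorted, every random draw flows from an explicit seed, and two runs on
identical inputs produce byte-identical outputs.

## Problem sizes

Test and acceptance workloads use 14-scenario worlds (~40 kb of reference
across 15 contigs, one transcript per gene); the dominance property is
measured on 210 generated transcript pairs and the identity oracles on
1000 random instances of ≤ 12 residues with exhaustive co-optimal
enumeration. The full pytest suite runs in a few seconds; the acceptance
script in about one second.
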