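# protlift

Reconcile two homology-based annotations of a newly assembled genome — one
produced by **DNA alignment** (Liftoff-style: full gene → mRNA → exon/CDS
hierarchies with UTRs) and one by **protein-to-genome alignment**
(miniprot-style: bare mRNA → CDS) — into a single annotation that maximizes
protein identity to the reference.

Neither aligner family dominates. DNA alignment transfers UTRs and
non-coding genes but breaks open reading frames when the target sequence
diverges (wrong acceptor sites, frameshifts). Protein alignment preserves
reading frames across much larger evolutionary distances but misses small
exons, retains introns, cannot see UTRs, and happily lands on processed
pseudogenes. `protlift` is for genome annotators who already have both
candidate annotations and want the best of each at every locus.

## The method

For each reference transcript with protein $P$ and the two candidate
translations $Q_L$ (DNA-based) and $Q_M$ (protein-based):

1. **Pairing.** Each protein-based mapping is matched to the DNA-based
   locus it overlaps; mappings that also overlap unrelated gene loci, or
   that span two loci ("read-throughs"), are removed, and among multiple
   mappings the one with the highest protein identity is kept.
2. **Chaining.** $Q_L$ and $Q_M$ are globally aligned to $P$ (BLOSUM62,
   gap open 11, extend 2). Each candidate's CDS boundaries are projected
   onto $P$ through its alignment, and the two CDS lists are partitioned
   into paired groups $GL_i$ / $GM_i$ that end wherever the cumulative
   number of aligned reference residues agrees. Per block the group with
   the higher *partial identity* is selected ($GSEL_i$; ties favor the
   DNA candidate so UTRs survive), and the selections are concatenated
   into the merged CDS chain.
3. **ORF repair.** Transcripts classified with a deleterious mutation
   (frameshift, stop gain, stop loss, start loss) get a three-frame ORF
   search over the spliced transcript (UTRs included). The longest
   ATG-initiated ORF per frame is scored against $P$ and the CDS is
   rewritten when that does not lower identity — moving starts past
   premature stops, or extending the CDS to a new stop in the 3' UTR.
4. **Copy resolution.** Accepted loci live in an interval registry; new
   loci may overlap existing ones by at most 10% unless the source genes
   already overlap in the reference. DNA-based extra copies must meet a
   sequence-identity threshold (default 0.95); protein-only loci face two
   pseudogene filters — a single-CDS candidate needs a single-CDS source
   gene, and its coding length must be 0.9–1.5× the source's longest
   isoform.

Protein identity is **gap-compressed**: exact matches over alignment
columns, with each maximal run of reference-side gaps counted once, and the
target protein truncated at its first stop codon before alignment. DNA
identity is BLAST-style (matches over all columns; match 1, mismatch −3,
gap open/extend 2).

## A worked example

`examples/01_chain_two_annotations.py` builds a seven-exon gene where the
DNA candidate has a bad splice junction between CDS 3 and 4 (premature
stop) and the protein candidate fused its last two CDSs across an intron:

```
transcript T-combined_errors-0: 7 DNA-based CDSs vs 6 protein-based CDSs -> 5 blocks

block 1: reference residues (0, 16)  dna_id=1.000  prot_id=1.000  <-- winner: dna
block 2: reference residues (16, 32)  dna_id=1.000  prot_id=1.000  <-- winner: dna
block 3: reference residues (32, 70)  dna_id=0.947  prot_id=1.000  <-- winner: prot
block 4: reference residues (70, 82)  dna_id=1.000  prot_id=1.000  <-- winner: dna
block 5: reference residues (82, 113)  dna_id=1.000  prot_id=0.969  <-- winner: dna

merged chain: ['cds1', 'cds2', 'mpcds3', 'mpcds4', 'cds5', 'cds6', 'cds7']
merged protein identity vs reference: 1.0000
```

Block 3 is the DNA candidate's broken junction (partial identity 0.947,
dragged down by the mis-spliced codons) and block 5 is the protein
candidate's retained intron (0.969); taking the winner of every block
recovers the reference protein exactly — identity 1.0 — although neither
input annotation encodes it. `examples/02_orf_repair.py` shows the ORF
search rescuing a premature-stop transcript (identity 0.9444 after moving
the start codon), and `examples/03_full_pipeline.py` runs every planted
scenario end to end.

## Command line

```bash
protlift simulate --scenarios all --seed 1 -o world/     # synthetic inputs
protlift run --ref-fasta world/ref.fa --ref-gff world/ref.gff3 \
    --target-fasta world/target.fa --dna-gff world/dna_candidate.gff3 \
    --prot-gff world/prot_candidate.gff3 -o out --copies
```

`run` writes `out.gff3` (merged annotation with `protein_identity`,
`dna_identity`, `mutation` and `extra_copy_number` attributes),
`out.mutations.tsv`, `out.unmapped.tsv` and `out.census.json`.

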