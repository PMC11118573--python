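"""End-to-end reconciliation pipeline and feature census.

``run_objects`` drives the full flow on in-memory objects (the form the
tests use); ``run`` wraps it with file I/O for the command line: read the
reference genome/annotation and the two candidate annotations, pair
transcripts, chain CDS groups, classify mutations, repair ORFs, resolve
overlapping loci and extra copies, then write the merged GFF3 plus the
mutation/identity report, the unmapped-feature list and a feature census.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from . import annot_io, copy_resolver, pairing
from .annot_io import AnnotationDB, FeatureRecord, GenomeSequence
from .chaining import ChainSelection, order_5p_to_3p, reconcile_pair
from .copy_resolver import (DnaCopyCandidate, LocusRegistry,
                            ProtCopyCandidate, admit_dna_copies,
                            admit_prot_copies, assign_copy_ids,
                            synthesize_gene_parent)
from .identity import align_dna, dna_identity, protein_identity
from .orf_polish import classify_mutations, orf_repair
from .seqtools import cds_phases, extract_spliced, translate

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    ref_fasta: str = ""
    ref_gff: str = ""
    target_fasta: str = ""
    dna_gff: str = ""
    prot_gff: str = ""
    out_prefix: str = "protlift"
    sc_threshold: float = 0.95
    overlap_fraction: float = 0.10
    ratio_bounds: tuple[float, float] = (0.9, 1.5)
    feature_types: tuple[str, ...] = ("gene", "pseudogene")
    copies: bool = False
    drop_suffixes: tuple[str, ...] = ()
    drop_biotypes: tuple[str, ...] = ()
    suffix_pattern: str = pairing.DEFAULT_SUFFIX_PATTERN
    ref_dialect: str = "gff3"

    def __post_init__(self):
        if not (0 < self.sc_threshold <= 1) or not (0 < self.overlap_fraction <= 1):
            raise ValueError("thresholds must be in (0, 1]")
        if self.ratio_bounds[0] >= self.ratio_bounds[1]:
            raise ValueError("ratio bounds must be increasing")


@dataclass
class TranscriptResult:
    transcript_id: str
    gene_id: str
    status: str
    categories: set[str] = field(default_factory=set)
    dna_identity: float | None = None
    protein_identity: float | None = None
    repaired: bool = False
    winners: list[str] = field(default_factory=list)
    protein: str = ""


@dataclass
class RunResult:
    out_db: AnnotationDB
    results: list[TranscriptResult]
    unmapped: list[tuple[str, str, str]]        # (level, id, reason)
    copy_decisions: list[copy_resolver.CopyDecision]
    census: dict
    pairs: dict


# -- helpers -------------------------------------------------------------

def _spliced_dna(genome: GenomeSequence, intervals, strand: str) -> str:
    return extract_spliced(genome, intervals, strand).dna


def _strip_stop(protein: str) -> str:
    return protein[:-1] if protein.endswith("*") else protein


def _ref_transcript_seqs(ref_genome, ref_db, tx: FeatureRecord):
    """(tx_dna, cds_dna, protein) for a reference transcript; the protein is
    the full CDS translation with its terminal stop stripped."""
    g = ref_genome[tx.seqid]
    cds = order_5p_to_3p(ref_db.cds_of(tx.feature_id), tx.strand)
    exons = ref_db.exons_of(tx.feature_id)
    tx_iv = [(f.start, f.end) for f in (exons or cds)] or [(tx.start, tx.end)]
    tx_dna = _spliced_dna(g, tx_iv, tx.strand)
    if not cds:
        return tx_dna, "", ""
    phase = cds[0].phase or 0
    cds_dna = extract_spliced(
        g, [(c.start, c.end) for c in cds], tx.strand).dna[phase:]
    return tx_dna, cds_dna, _strip_stop(translate(cds_dna))


def build_merged_exons(selection: ChainSelection, dna_exons: list[FeatureRecord],
                       dna_cds: list[FeatureRecord], strand: str,
                       ) -> list[tuple[int, int]]:
    """Exon intervals for a merged transcript.

    Blocks won by the DNA candidate keep that candidate's exons (which carry
    the UTRs); blocks won by the protein candidate use its CDS intervals as
    exons. The DNA candidate's terminal UTR segments are re-attached when a
    terminal block went to the protein side, then touching intervals merge.
    """
    intervals: set[tuple[int, int]] = set()
    for grp in selection.selected:
        for cds in grp.cds_list:
            if grp.source == "dna":
                homes = [x for x in dna_exons
                         if x.start <= cds.start and cds.end <= x.end]
                intervals.add((homes[0].start, homes[0].end) if homes
                              else (cds.start, cds.end))
            else:
                intervals.add((cds.start, cds.end))
    if dna_cds and dna_exons and selection.winners:
        lo_cds = min(c.start for c in dna_cds)
        hi_cds = max(c.end for c in dna_cds)
        first_is_prot = selection.winners[0] == "prot"
        last_is_prot = selection.winners[-1] == "prot"
        left_utr = (min(x.start for x in dna_exons), lo_cds - 1)
        right_utr = (hi_cds + 1, max(x.end for x in dna_exons))
        if (first_is_prot if strand == "+" else last_is_prot) \
                and left_utr[0] <= left_utr[1]:
            intervals.add(left_utr)
        if (last_is_prot if strand == "+" else first_is_prot) \
                and right_utr[0] <= right_utr[1]:
            intervals.add(right_utr)
    for cds in selection.merged_cds:
        if not any(s <= cds.start and cds.end <= e for s, e in intervals):
            intervals.add((cds.start, cds.end))
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _emit_transcript(out_db: AnnotationDB, gene_id: str, tx_id: str,
                     template: FeatureRecord, seqid: str, strand: str,
                     exon_ivs, cds_ivs, phase0: int, attrs: dict) -> None:
    span_src = exon_ivs or cds_ivs
    span = (min(s for s, _ in span_src), max(e for _, e in span_src))
    out_db.add(template.copy(feature_id=tx_id, seqid=seqid, start=span[0],
                             end=span[1], strand=strand, parent_id=gene_id,
                             attributes={**template.attributes, **attrs}))
    for i, (s, e) in enumerate(sorted(exon_ivs), 1):
        out_db.add(FeatureRecord(f"{tx_id}.exon{i}", "exon", seqid, s, e,
                                 strand, parent_id=tx_id))
    ordered = sorted(cds_ivs, reverse=(strand == "-"))
    phases = cds_phases([e - s + 1 for s, e in ordered], phase0)
    for i, ((s, e), ph) in enumerate(zip(ordered, phases), 1):
        out_db.add(FeatureRecord(f"{tx_id}.cds{i}", "CDS", seqid, s, e,
                                 strand, phase=ph, parent_id=tx_id))


def _fmt(x: float) -> str:
    return f"{x:.4f}"


# -- main flow -----------------------------------------------------------

def run_objects(ref_genome: dict[str, GenomeSequence], ref_db: AnnotationDB,
                target_genome: dict[str, GenomeSequence], dna_db: AnnotationDB,
                prot_db: AnnotationDB, config: RunConfig | None = None,
                ) -> RunResult:
    cfg = config or RunConfig()
    ref_db = annot_io.filter_reference(ref_db, list(cfg.drop_suffixes),
                                       list(cfg.drop_biotypes))
    for tx in ref_db.transcripts():
        if tx.seqid not in ref_genome:
            raise ValueError(f"reference genome lacks seqid {tx.seqid!r}")

    pairs = pairing.match_transcripts(dna_db, prot_db, cfg.suffix_pattern)
    out_db = AnnotationDB()
    results: list[TranscriptResult] = []
    unmapped: list[tuple[str, str, str]] = []
    prot_only_cands: list[dict] = []
    registry = LocusRegistry(ref_db)

    ref_genes = sorted((g for g in ref_db.genes()
                        if (g.source_type or "gene") in cfg.feature_types),
                       key=lambda g: (g.seqid, g.start, g.feature_id))

    for gene in ref_genes:
        emitted: list[str] = []
        for tx in ref_db.transcripts_of(gene.feature_id):
            res = _process_transcript(
                ref_genome, ref_db, target_genome, dna_db, prot_db, pairs,
                gene, tx, out_db, prot_only_cands, cfg)
            if res.status == "unmapped":
                unmapped.append(("transcript", tx.feature_id, "no_candidate"))
                results.append(res)
            elif res.status == "prot_only":
                pass        # decided in the copy-resolution stage
            else:
                results.append(res)
                emitted.append(res.transcript_id)
        if emitted:
            _emit_gene(out_db, dna_db, gene, emitted, registry)

    copy_decisions = _resolve_copies(
        ref_genome, ref_db, target_genome, dna_db, prot_db, prot_only_cands,
        pairs, registry, out_db, results, cfg)

    rejected = {d.candidate_id: d for d in copy_decisions if not d.accepted}
    for item in prot_only_cands:
        cand_id = item["pair"].chosen_prot_id or item["pair"].prot_candidate_ids[0]
        if cand_id in rejected:
            unmapped.append(("transcript", item["tx"].feature_id,
                             "filtered:" + ";".join(rejected[cand_id].reasons)))

    mapped_gene_ids = {g.attributes.get("ref_gene_id") for g in out_db.genes()}
    for gene in ref_genes:
        if gene.feature_id not in mapped_gene_ids:
            unmapped.append(("gene", gene.feature_id, "no_candidate"))

    census_dict = census(out_db, ref_db)
    out_db.finalize()
    return RunResult(out_db, results, unmapped, copy_decisions, census_dict,
                     pairs)


def _process_transcript(ref_genome, ref_db, target_genome, dna_db, prot_db,
                        pairs, gene, tx, out_db, prot_only_cands, cfg,
                        ) -> TranscriptResult:
    tx_id = tx.feature_id
    ref_tx_dna, ref_cds_dna, ref_protein = _ref_transcript_seqs(
        ref_genome, ref_db, tx)
    pair = pairs.get(tx_id)
    if pair is None or pair.status == "unmapped":
        return TranscriptResult(tx_id, gene.feature_id, "unmapped")

    coding = bool(ref_cds_dna)
    if coding and pair.prot_candidate_ids:
        pairing.resolve_multicopy(pair, ref_protein, target_genome, dna_db,
                                  prot_db)
    if pair.status == "unmapped":
        return TranscriptResult(tx_id, gene.feature_id, "unmapped")

    if not coding:
        return _passthrough_noncoding(target_genome, dna_db, pair, gene, tx,
                                      ref_tx_dna, out_db)

    if pair.status == "prot_only":
        prot_only_cands.append({
            "pair": pair, "gene": gene, "tx": tx, "ref_protein": ref_protein,
            "ref_tx_dna": ref_tx_dna, "ref_cds_dna": ref_cds_dna})
        return TranscriptResult(tx_id, gene.feature_id, "prot_only")

    dna_tx = dna_db[pair.dna_tx_id]
    seqid, strand = dna_tx.seqid, dna_tx.strand
    genome = target_genome[seqid]
    dna_cds = order_5p_to_3p(dna_db.cds_of(pair.dna_tx_id), strand)
    dna_exons = dna_db.exons_of(pair.dna_tx_id)
    prot_cds = (order_5p_to_3p(prot_db.cds_of(pair.chosen_prot_id), strand)
                if pair.chosen_prot_id else [])
    if not dna_cds and not prot_cds:
        return TranscriptResult(tx_id, gene.feature_id, "unmapped")
    dna_phase = (dna_cds[0].phase or 0) if dna_cds else 0
    prot_phase = (prot_cds[0].phase or 0) if prot_cds else 0

    selection = reconcile_pair(ref_protein, genome, dna_cds, prot_cds, strand,
                               dna_phase, prot_phase)
    exon_ivs = build_merged_exons(selection, dna_exons, dna_cds, strand)
    cds_ivs = sorted((c.start, c.end) for c in selection.merged_cds)
    phase0 = dna_phase if (selection.winners and selection.winners[0] == "dna") \
        else prot_phase

    tgt_cds_dna = _spliced_dna(genome, cds_ivs, strand)[phase0:]
    tgt_tx_dna = _spliced_dna(genome, exon_ivs, strand)
    report = classify_mutations(tx_id, ref_tx_dna, tgt_tx_dna, ref_cds_dna,
                                tgt_cds_dna)

    repaired = False
    if report.deleterious and exon_ivs:
        spliced = extract_spliced(genome, exon_ivs, strand, tx_id)
        five_prime = cds_ivs[0][0] if strand == "+" else cds_ivs[-1][1]
        frame = (spliced.genomic_to_offset(five_prime) + phase0) % 3
        rep = orf_repair(spliced, cds_ivs, tgt_cds_dna, ref_protein, report,
                         current_frame=frame)
        if rep.changed:
            repaired = True
            cds_ivs, phase0 = rep.cds_intervals, 0
            tgt_cds_dna = _spliced_dna(genome, cds_ivs, strand)

    final_protein = _strip_stop(translate(tgt_cds_dna))
    pid = protein_identity(ref_protein, final_protein) if final_protein else 0.0
    did = dna_identity(align_dna(ref_tx_dna, tgt_tx_dna))

    attrs = {"ref_gene_id": gene.feature_id,
             "mutation": ";".join(sorted(report.categories)),
             "dna_identity": _fmt(did), "protein_identity": _fmt(pid)}
    _emit_transcript(out_db, gene.feature_id, tx_id, tx, seqid, strand,
                     exon_ivs, cds_ivs, phase0, attrs)
    return TranscriptResult(tx_id, gene.feature_id, pair.status,
                            report.categories, did, pid, repaired,
                            list(selection.winners), final_protein)


def _passthrough_noncoding(target_genome, dna_db, pair, gene, tx,
                           ref_tx_dna, out_db) -> TranscriptResult:
    tx_id = tx.feature_id
    if pair.dna_tx_id is None:
        return TranscriptResult(tx_id, gene.feature_id, "unmapped")
    dna_tx = dna_db[pair.dna_tx_id]
    exon_ivs = [(x.start, x.end) for x in dna_db.exons_of(pair.dna_tx_id)] \
        or [(dna_tx.start, dna_tx.end)]
    tgt_tx_dna = _spliced_dna(target_genome[dna_tx.seqid], exon_ivs,
                              dna_tx.strand)
    did = dna_identity(align_dna(ref_tx_dna, tgt_tx_dna))
    cats = {"identical"} if ref_tx_dna == tgt_tx_dna else {"synonymous"}
    attrs = {"ref_gene_id": gene.feature_id, "dna_identity": _fmt(did),
             "mutation": ";".join(sorted(cats))}
    _emit_transcript(out_db, gene.feature_id, tx_id, tx, dna_tx.seqid,
                     dna_tx.strand, exon_ivs, [], 0, attrs)
    return TranscriptResult(tx_id, gene.feature_id, "dna_only", cats, did)


def _emit_gene(out_db, dna_db, gene, emitted_tx_ids, registry) -> None:
    spans = [(out_db[t].start, out_db[t].end) for t in emitted_tx_ids]
    start, end = min(s for s, _ in spans), max(e for _, e in spans)
    first = out_db[emitted_tx_ids[0]]
    template = dna_db.get(gene.feature_id) or gene
    out_db.add(template.copy(
        feature_id=gene.feature_id, seqid=first.seqid, start=start, end=end,
        strand=first.strand, parent_id=None,
        attributes={**gene.attributes, "ref_gene_id": gene.feature_id}))
    registry.add(gene.feature_id, gene.feature_id, first.seqid, start, end)


def _resolve_copies(ref_genome, ref_db, target_genome, dna_db, prot_db,
                    prot_only_cands, pairs, registry, out_db, results, cfg):
    decisions: list[copy_resolver.CopyDecision] = []

    # DNA-based extra copies (Liftoff-style suffixed/attributed subtrees)
    if cfg.copies:
        dna_candidates = []
        for g in sorted(dna_db.genes(), key=lambda g: (g.seqid, g.start)):
            if g.attributes.get("extra_copy_number", "0") == "0" \
                    or g.feature_id in out_db.features:
                continue
            ref_gene_id = pairing.base_id(g.feature_id,
                                          pairing.COPY_SUFFIX_PATTERN)
            if ref_gene_id not in ref_db.features:
                continue
            ident = _copy_dna_identity(ref_genome, ref_db, target_genome,
                                       dna_db, ref_gene_id, g)
            dna_candidates.append((g, ident, DnaCopyCandidate(
                g.feature_id, ref_gene_id, g.seqid, g.start, g.end, ident)))
        if dna_candidates:
            decs = admit_dna_copies([c for _, _, c in dna_candidates],
                                    registry, cfg.sc_threshold,
                                    cfg.overlap_fraction)
            decisions.extend(decs)
            by_id = {c.gene_id: (g, i) for g, i, c in dna_candidates}
            for d in decs:
                if d.accepted:
                    g, ident = by_id[d.candidate_id]
                    _emit_dna_copy(out_db, dna_db, g, ident, results)

    # protein-only loci: primary annotation attempts for genes the DNA
    # candidate missed, plus (with -copies) leftover protein mappings that
    # were dropped during pairing
    prot_candidates: list[tuple[dict, str]] = []
    for item in prot_only_cands:
        pair = item["pair"]
        chosen = pair.chosen_prot_id or pair.prot_candidate_ids[0]
        prot_candidates.append((item, chosen))
        if cfg.copies:
            for cid in pair.prot_candidate_ids:
                if cid != chosen:
                    prot_candidates.append((item, cid))
    if cfg.copies:
        consumed = {cid for _, cid in prot_candidates}
        for p in pairs.values():
            if p.status == "both":
                consumed.update(p.prot_candidate_ids)
        for ptx in sorted(prot_db.transcripts(),
                          key=lambda t: (t.seqid, t.start, t.feature_id)):
            if ptx.feature_id in consumed:
                continue
            base = pairing.base_id(ptx.feature_id, cfg.suffix_pattern)
            ref_tx = ref_db.get(base)
            if ref_tx is None or ref_tx.parent_id is None \
                    or not ref_db.cds_of(base):
                continue
            gene = ref_db[ref_tx.parent_id]
            ref_tx_dna, ref_cds_dna, ref_protein = _ref_transcript_seqs(
                ref_genome, ref_db, ref_tx)
            prot_candidates.append(({"pair": None, "gene": gene, "tx": ref_tx,
                                     "ref_protein": ref_protein,
                                     "ref_tx_dna": ref_tx_dna,
                                     "ref_cds_dna": ref_cds_dna},
                                    ptx.feature_id))

    pcands = []
    for item, cand_id in prot_candidates:
        c = prot_db[cand_id]
        cds = prot_db.cds_of(cand_id)
        pcands.append((item, cand_id, ProtCopyCandidate(
            cand_id, item["gene"].feature_id, c.seqid, c.start, c.end,
            len(cds), sum(x.length for x in cds))))
    if pcands:
        decs = admit_prot_copies([p for _, _, p in pcands], registry, ref_db,
                                 cfg.overlap_fraction, cfg.ratio_bounds)
        decisions.extend(decs)
        by_id = {cid: item for item, cid, _ in pcands}
        accepted = [registry.entries[d.candidate_id] for d in decs if d.accepted]
        taken = {g.feature_id for g in out_db.genes()}
        idmap = assign_copy_ids(accepted, taken)
        for d in decs:
            if d.accepted:
                new_gene_id, ordinal = idmap[d.candidate_id]
                _emit_prot_copy(out_db, prot_db, ref_db, target_genome,
                                by_id[d.candidate_id], d.candidate_id,
                                new_gene_id, ordinal, results)
    return decisions


def _copy_dna_identity(ref_genome, ref_db, target_genome, dna_db,
                       ref_gene_id, copy_gene) -> float:
    """Transcript-level DNA identity of an extra-copy locus vs its source."""
    ref_txs = ref_db.transcripts_of(ref_gene_id)
    copy_txs = dna_db.transcripts_of(copy_gene.feature_id)
    if not ref_txs or not copy_txs:
        return 0.0
    ref_tx_dna, _, _ = _ref_transcript_seqs(ref_genome, ref_db, ref_txs[0])
    ct = copy_txs[0]
    ivs = [(x.start, x.end) for x in dna_db.exons_of(ct.feature_id)] \
        or [(c.start, c.end) for c in dna_db.cds_of(ct.feature_id)]
    tgt = _spliced_dna(target_genome[ct.seqid], ivs, ct.strand)
    return dna_identity(align_dna(ref_tx_dna, tgt))


def _emit_dna_copy(out_db, dna_db, copy_gene, ident, results) -> None:
    k = copy_gene.attributes.get("extra_copy_number", "1")
    ref_gene_id = pairing.base_id(copy_gene.feature_id,
                                  pairing.COPY_SUFFIX_PATTERN)
    for rec in dna_db.subtree(copy_gene.feature_id):
        out = rec.copy()
        if out.ftype in ("gene", "transcript"):
            out.attributes.setdefault("extra_copy_number", k)
            out.attributes["dna_identity"] = _fmt(ident)
        if out.ftype == "gene":
            out.attributes["ref_gene_id"] = ref_gene_id
        out_db.add(out)
    for txr in dna_db.transcripts_of(copy_gene.feature_id):
        results.append(TranscriptResult(txr.feature_id, copy_gene.feature_id,
                                        "dna_copy", {"extra_copy"}, ident))


def _emit_prot_copy(out_db, prot_db, ref_db, target_genome, item, cand_id,
                    new_gene_id, ordinal, results) -> None:
    cand_tx = prot_db[cand_id]
    genome = target_genome[cand_tx.seqid]
    cds = order_5p_to_3p(prot_db.cds_of(cand_id), cand_tx.strand)
    phase = cds[0].phase or 0
    cds_ivs = sorted((c.start, c.end) for c in cds)
    tgt_cds_dna = _spliced_dna(genome, cds_ivs, cand_tx.strand)[phase:]
    prot = _strip_stop(translate(tgt_cds_dna))
    pid = protein_identity(item["ref_protein"], prot) if prot else 0.0
    did = dna_identity(align_dna(item["ref_cds_dna"], tgt_cds_dna))
    report = classify_mutations(item["tx"].feature_id, item["ref_cds_dna"],
                                tgt_cds_dna, item["ref_cds_dna"], tgt_cds_dna)

    gene = synthesize_gene_parent(ref_db, item["gene"].feature_id, new_gene_id,
                                  cand_tx.seqid, cand_tx.start, cand_tx.end,
                                  cand_tx.strand)
    gene.attributes["ref_gene_id"] = item["gene"].feature_id
    if ordinal:
        gene.attributes["extra_copy_number"] = str(ordinal)
    out_db.add(gene)
    tx_id = item["tx"].feature_id if ordinal == 0 \
        else f"{item['tx'].feature_id}_{ordinal}"
    attrs = {"ref_gene_id": item["gene"].feature_id,
             "mutation": ";".join(sorted(report.categories)),
             "dna_identity": _fmt(did), "protein_identity": _fmt(pid)}
    if ordinal:
        attrs["extra_copy_number"] = str(ordinal)
    _emit_transcript(out_db, new_gene_id, tx_id, item["tx"], cand_tx.seqid,
                     cand_tx.strand, cds_ivs, cds_ivs, phase, attrs)
    results.append(TranscriptResult(tx_id, new_gene_id, "prot_only",
                                    report.categories, did, pid,
                                    protein=prot))


# -- census --------------------------------------------------------------

_NONCODING = {"lncRNA", "lnc_RNA", "ncRNA"}


def _gene_class(rec: FeatureRecord) -> str:
    bt = annot_io.gene_biotype(rec)
    if (rec.source_type or "gene") == "gene" and bt == "protein_coding":
        return "protein_coding"
    if bt in _NONCODING:
        return "non_coding"
    return "others"


def _tx_class(rec: FeatureRecord, parent_class: str) -> str:
    t = rec.source_type or "transcript"
    if t == "mRNA" and parent_class == "protein_coding":
        return "protein_coding"
    if t in _NONCODING and parent_class == "non_coding":
        return "non_coding"
    return "others"


def census(out_db: AnnotationDB, ref_db: AnnotationDB) -> dict:
    """Counts per level (gene/transcript) and class
    (protein_coding/non_coding/others), split single-copy / multi-copy
    genes and extra loci."""
    loci_by_ref: dict[str, list[FeatureRecord]] = {}
    for g in out_db.genes():
        ref_id = g.attributes.get("ref_gene_id", g.feature_id)
        loci_by_ref.setdefault(ref_id, []).append(g)

    out = {lvl: {cls: {"single_copy": 0, "multi_copy": 0, "extra_copy": 0,
                       "total": 0}
                 for cls in ("protein_coding", "non_coding", "others")}
           for lvl in ("gene", "transcript")}
    for ref_id, loci in sorted(loci_by_ref.items()):
        ref_gene = ref_db.get(ref_id) or loci[0]
        cls = _gene_class(ref_gene)
        gb = out["gene"][cls]
        multi = len(loci) > 1
        gb["multi_copy" if multi else "single_copy"] += 1
        gb["extra_copy"] += len(loci) - 1
        gb["total"] += len(loci)
        for locus in loci:
            is_extra = locus.attributes.get("extra_copy_number", "0") != "0"
            for txr in out_db.transcripts_of(locus.feature_id):
                tb = out["transcript"][_tx_class(txr, cls)]
                if is_extra:
                    tb["extra_copy"] += 1
                elif multi:
                    tb["multi_copy"] += 1
                else:
                    tb["single_copy"] += 1
                tb["total"] += 1
    return out


# -- file-level driver ---------------------------------------------------

def run(config: RunConfig) -> RunResult:
    """File-in, file-out pipeline run. Writes ``<prefix>.gff3``,
    ``<prefix>.mutations.tsv``, ``<prefix>.unmapped.tsv`` and
    ``<prefix>.census.json``."""
    ref_genome = annot_io.read_fasta(config.ref_fasta)
    target_genome = annot_io.read_fasta(config.target_fasta)
    ref_db = annot_io.read_annotation(config.ref_gff, config.ref_dialect)
    dna_db = annot_io.read_annotation(config.dna_gff)
    prot_db = annot_io.read_annotation(config.prot_gff)
    result = run_objects(ref_genome, ref_db, target_genome, dna_db, prot_db,
                         config)

    prefix = config.out_prefix
    annot_io.write_gff3(result.out_db, prefix + ".gff3")
    with open(prefix + ".mutations.tsv", "w") as fh:
        fh.write("transcript_id\tcategories\tdna_identity\tprotein_identity\n")
        for r in sorted(result.results, key=lambda r: r.transcript_id):
            if r.status == "unmapped":
                continue
            did = "" if r.dna_identity is None else _fmt(r.dna_identity)
            pid = "" if r.protein_identity is None else _fmt(r.protein_identity)
            fh.write(f"{r.transcript_id}\t{';'.join(sorted(r.categories))}"
                     f"\t{did}\t{pid}\n")
    with open(prefix + ".unmapped.tsv", "w") as fh:
        fh.write("level\tfeature_id\treason\n")
        for level, fid, reason in sorted(result.unmapped):
            fh.write(f"{level}\t{fid}\t{reason}\n")
    with open(prefix + ".census.json", "w") as fh:
        json.dump(result.census, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
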