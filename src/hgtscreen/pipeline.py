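"""End-to-end orchestration: screen, evidence, architectures, validation.

Each stage is a pure function of (bundle, configuration, seed) so reruns are
byte-identical.  The bacterial and fungal screens run independently: the
eukaryote background for the bacterial screen is every eukaryote partition
minus Arthropoda, and the fungal screen additionally removes Fungi from the
background.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .homology import ScoringScheme, SearchResult, TaxonDb, search_db
from .phylo import ValidateConfig, ValidationResult, validate_candidate
from .screen import (CoTransferPair, FusionCall, HgtCandidate,
                     ScreenThresholds, assign_to_genes, attach_evidence,
                     call_candidates, depth_evidence, detect_cotransfer,
                     detect_fusion, flag_intron_acquisition, matepair_evidence,
                     rna_evidence)
from .seqprep import SeqprepConfig, apply_mask, extract_ppps, six_frame_translate

__all__ = ["ScreenOutput", "run_screen", "run_validate", "run_famexpand",
           "candidates_frame", "validation_frame"]

EUK_BACKGROUND_TAXA = ("metazoa", "plants", "other_eukaryotes", "fungi")


@dataclass
class ScreenOutput:
    candidates: list[HgtCandidate]
    cotransfers: list[CoTransferPair]
    fusions: list[FusionCall]
    intron_counts: dict[str, int]
    n_ppps: int


def _build_dbs(proteomes, kingdom: str) -> tuple[TaxonDb, TaxonDb]:
    """Donor and eukaryote-background databases for one screen."""
    records = [r for recs in proteomes.values() for r in recs]
    donor = TaxonDb.build("donor", records, taxa=(kingdom,))
    if kingdom == "bacteria":
        background_taxa = EUK_BACKGROUND_TAXA
        excluded = ("Arthropoda",)
    elif kingdom == "fungi":
        background_taxa = tuple(t for t in EUK_BACKGROUND_TAXA if t != "fungi")
        excluded = ("Arthropoda", "fungi")
    else:
        raise ValueError(f"unknown donor kingdom {kingdom!r}")
    background = TaxonDb.build("eukaryote_background", records,
                               taxa=background_taxa, excluded_clades=excluded)
    return donor, background


def run_screen(bundle, scheme: ScoringScheme = ScoringScheme(),
               seqprep_cfg: SeqprepConfig = SeqprepConfig(),
               thresholds: ScreenThresholds = ScreenThresholds(),
               neighbor_k: int = 2, top_n: int = 5) -> ScreenOutput:
    """Mask -> translate -> PPP -> search -> h -> call -> merge -> annotate."""
    masked = apply_mask(bundle.genome, bundle.masks)
    ppps = extract_ppps(six_frame_translate(masked), seqprep_cfg)

    all_candidates: list[HgtCandidate] = []
    for kingdom in ("bacteria", "fungi"):
        donor_db, euk_db = _build_dbs(bundle.proteomes, kingdom)
        donor_res: dict[str, SearchResult] = {}
        euk_res: dict[str, SearchResult] = {}
        for q in ppps:
            donor_res[q.id] = search_db(q.id, q.pep, donor_db, scheme, top_n)
            euk_res[q.id] = search_db(q.id, q.pep, euk_db, scheme, 1)
        all_candidates.extend(
            call_candidates(ppps, donor_res, euk_res, kingdom, thresholds))

    merged = assign_to_genes(all_candidates, bundle.genes)

    # evidence annotation (never gates)
    ordered_genes = sorted(bundle.genes, key=lambda g: (g.seq_id, g.start))
    idx_of = {g.gene_id: i for i, g in enumerate(ordered_genes)}
    annotated = []
    for c in merged:
        if c.gene_id is not None and c.gene_id in idx_of:
            i = idx_of[c.gene_id]
            gene = ordered_genes[i]
            neighbors = [g for g in
                         ordered_genes[max(0, i - neighbor_k):i]
                         + ordered_genes[i + 1:i + 1 + neighbor_k]
                         if g.seq_id == gene.seq_id]
            left = next((g for g in reversed(ordered_genes[:i])
                         if g.seq_id == gene.seq_id), None)
            right = next((g for g in ordered_genes[i + 1:]
                          if g.seq_id == gene.seq_id), None)
            dep = depth_evidence(bundle.depth, gene.exons, neighbors)
            mp = matepair_evidence(bundle.matepairs,
                                   (gene.seq_id, gene.start, gene.end),
                                   left, right)
            strand = bundle.gene_strand.get(gene.gene_id, gene.strand)
            rna = rna_evidence(bundle.rna[strand], gene)
            annotated.append(attach_evidence(c, dep, mp, rna))
        else:
            annotated.append(c)

    cotransfers = detect_cotransfer(annotated, bundle.genus_of)
    fusions = []
    for c in annotated:
        if c.gene_id is None:
            continue
        # member hit intervals are in genome bp: 3 bp per residue
        call = detect_fusion(c.gene_id, c.member_hits, bundle.adjacency,
                             min_segment=180, max_overlap=30)
        if call is not None:
            fusions.append(call)
    gene_by_id = {g.gene_id: g for g in bundle.genes}
    introns = {c.gene_id: flag_intron_acquisition(gene_by_id[c.gene_id])
               for c in annotated if c.gene_id in gene_by_id}
    return ScreenOutput(annotated, cotransfers, fusions, introns, len(ppps))


def run_validate(bundle, candidates: list[HgtCandidate],
                 scheme: ScoringScheme = ScoringScheme(),
                 cfg: ValidateConfig = ValidateConfig(),
                 seed: int = 0) -> dict[str, ValidationResult]:
    """Validate each candidate's donor origin; seeded per candidate."""
    records = [r for recs in bundle.proteomes.values() for r in recs]
    dbs = {t: TaxonDb.build(t, records, taxa=(t,),
                            excluded_clades=("Arthropoda",))
           for t in bundle.proteomes}
    out = {}
    for i, c in enumerate(sorted(candidates, key=lambda c: c.locus_id)):
        sub_seed = (seed * 1009 + i) % (2 ** 31)
        pep = c.validation_pep or c.best_donor_hit.query_id
        out[c.locus_id] = validate_candidate(
            c.locus_id, pep, c.donor_kingdom, dbs, scheme, cfg, sub_seed)
    return out


def run_famexpand(bundle, alpha: float = 0.05) -> pd.DataFrame:
    from .famexpand import run_expansion_screen
    return run_expansion_screen(bundle.domain_matrix, alpha=alpha)


def candidates_frame(out: ScreenOutput) -> pd.DataFrame:
    fusion_genes = {f.gene_id for f in out.fusions}
    cot = {}
    for p in out.cotransfers:
        cot.setdefault(p.locus_a, p.locus_b)
        cot.setdefault(p.locus_b, p.locus_a)
    rows = []
    for c in out.candidates:
        ev = c.evidence
        rows.append({
            "locus_id": c.locus_id,
            "gene_id": c.gene_id or "",
            "seq_id": c.seq_id,
            "start": c.genome_start,
            "end": c.genome_end,
            "donor_kingdom": c.donor_kingdom,
            "h": round(c.h, 4),
            "donor_bits": round(c.best_donor_hit.bit_score, 4),
            "donor_subject": c.best_donor_hit.subject_id,
            "euk_bits": round(c.best_euk_hit.bit_score, 4)
            if c.best_euk_hit else 0.0,
            "euk_subject": c.best_euk_hit.subject_id if c.best_euk_hit else "",
            "depth_ratio": "" if ev is None or ev.depth_ratio is None
            else round(ev.depth_ratio, 4),
            "depth_pass": "" if ev is None or ev.depth_pass is None
            else ev.depth_pass,
            "matepair_pass": "" if ev is None or ev.matepair_pass is None
            else ev.matepair_pass,
            "rna_fraction": "" if ev is None or ev.rna_covered_fraction is None
            else round(ev.rna_covered_fraction, 4),
            "rna_pass": "" if ev is None or ev.rna_pass is None else ev.rna_pass,
            "introns": out.intron_counts.get(c.gene_id, ""),
            "is_fusion": c.gene_id in fusion_genes,
            "cotransfer_partner": cot.get(c.locus_id, ""),
            "validation_pep": c.validation_pep,
            "validation": c.validation,
        })
    return pd.DataFrame(rows)


def validation_frame(results: dict[str, ValidationResult]) -> pd.DataFrame:
    rows = []
    for locus_id in sorted(results):
        r = results[locus_id]
        rows.append({
            "locus_id": locus_id,
            "donor_taxon": r.donor_taxon,
            "monophyletic": "" if r.monophyletic is None else r.monophyletic,
            "support": "" if r.support is None else r.support,
            "bootstrap_reps": r.bootstrap_reps,
            "verdict": r.verdict,
            "reason": r.reason,
        })
    return pd.DataFrame(rows)
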