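"""Candidate HGT calling and annotation.

The screening statistic is the bit-score difference

    h = bits(best donor-kingdom hit) - bits(best eukaryote hit)

computed per query (PPP or transcript peptide) against two databases: the
donor partition (bacteria, or fungi) and a eukaryote background that always
excludes Arthropoda and additionally excludes Fungi when screening for fungal
transfers.  A query is a candidate when h >= h_min (default 30) and the donor
bit score is at least donor_bits_min (default 100); both boundaries inclusive.

Candidates are merged onto annotated gene models; read-based evidence
(depth similarity, mate-pair junction spans, sense-strand RNA coverage)
annotates but never gates candidates.  Detectors for co-transferred adjacent
gene pairs, donor-gene fusions, and intron acquisition report the
post-transfer architectures of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .homology import Hit, SearchResult
from .seqprep import Ppp

__all__ = [
    "ScreenThresholds",
    "GeneModel",
    "EvidenceReport",
    "HgtCandidate",
    "CoTransferPair",
    "FusionCall",
    "compute_h",
    "call_candidates",
    "assign_to_genes",
    "depth_evidence",
    "matepair_evidence",
    "rna_evidence",
    "detect_cotransfer",
    "detect_fusion",
    "flag_intron_acquisition",
]


@dataclass(frozen=True)
class ScreenThresholds:
    h_min: float = 30.0
    donor_bits_min: float = 100.0

    def __post_init__(self) -> None:
        if self.h_min <= 0 or self.donor_bits_min <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    seq_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if not a < b <= c < d:
                raise ValueError(f"exons of {self.gene_id} unsorted/overlapping")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.exons)


@dataclass(frozen=True)
class EvidenceReport:
    depth_ratio: float | None = None
    depth_pass: bool | None = None
    matepair_spans_left: int | None = None
    matepair_spans_right: int | None = None
    matepair_pass: bool | None = None
    rna_covered_fraction: float | None = None
    rna_pass: bool | None = None


@dataclass(frozen=True)
class HgtCandidate:
    locus_id: str
    seq_id: str
    genome_start: int
    genome_end: int
    donor_kingdom: str  # "bacteria" | "fungi"
    h: float
    best_donor_hit: Hit
    best_euk_hit: Hit | None
    query_source: str = "ppp"
    gene_id: str | None = None
    # donor hits of merged member queries, query intervals remapped to
    # genome bp so fusion segments are comparable across PPPs
    member_hits: tuple[Hit, ...] = ()
    validation_pep: str = ""  # best donor hit's query region, for tree building
    evidence: EvidenceReport | None = None
    validation: str = "pending"


@dataclass(frozen=True)
class CoTransferPair:
    locus_a: str
    locus_b: str
    donor_genus: str
    gap_bp: int


@dataclass(frozen=True)
class FusionCall:
    gene_id: str
    segment_a: tuple[int, int]
    segment_b: tuple[int, int]
    donor_a: str
    donor_b: str
    donors_adjacent: bool | None = None


def remap_hit_to_genome(h: Hit, q: Ppp) -> Hit:
    """Express a PPP-local hit's query interval in forward-strand genome bp."""
    if q.frame > 0:
        qs = q.genome_start + 3 * h.query_start
        qe = q.genome_start + 3 * h.query_end
    else:
        qs = q.genome_end - 3 * h.query_end
        qe = q.genome_end - 3 * h.query_start
    return replace(h, query_start=qs, query_end=qe)


def compute_h(best_donor: Hit, best_euk: Hit | None) -> float:
    """Donor bits minus eukaryote bits; no eukaryote hit counts as 0 bits."""
    euk_bits = best_euk.bit_score if best_euk is not None else 0.0
    return best_donor.bit_score - euk_bits


def call_candidates(
    queries: Sequence[Ppp],
    donor_results: Mapping[str, SearchResult],
    euk_results: Mapping[str, SearchResult],
    donor_kingdom: str,
    t: ScreenThresholds = ScreenThresholds(),
    query_source: str = "ppp",
) -> list[HgtCandidate]:
    """Apply the h >= h_min and donor-bits >= donor_bits_min rule (inclusive).

    ``donor_results``/``euk_results`` map query id to its SearchResult against
    the donor and eukaryote-background databases of one screen.  Output is
    ordered by genome position.
    """
    out = []
    for q in sorted(queries, key=lambda p: (p.seq_id, p.genome_start, p.frame)):
        dres = donor_results.get(q.id)
        if dres is None or dres.best is None:
            continue
        eres = euk_results.get(q.id)
        best_euk = eres.best if eres is not None else None
        h = compute_h(dres.best, best_euk)
        if h >= t.h_min and dres.best.bit_score >= t.donor_bits_min:
            out.append(HgtCandidate(
                locus_id=q.id, seq_id=q.seq_id,
                genome_start=q.genome_start, genome_end=q.genome_end,
                donor_kingdom=donor_kingdom, h=h,
                best_donor_hit=dres.best, best_euk_hit=best_euk,
                query_source=query_source,
                member_hits=tuple(remap_hit_to_genome(hh, q)
                                  for hh in dres.hits),
                validation_pep=q.pep[dres.best.query_start:dres.best.query_end]
                or q.pep,
            ))
    return out


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def assign_to_genes(candidates: Sequence[HgtCandidate],
                    genes: Sequence[GeneModel]) -> list[HgtCandidate]:
    """Merge query-level candidates into gene-anchored loci.

    A candidate overlapping any CDS exon of a gene is attached to that gene;
    all candidates of one (gene, donor kingdom) merge into a single locus that
    keeps the maximum-h hit pair and remembers every member's donor hit for
    downstream fusion detection.  Candidates overlapping no gene are kept as
    intergenic loci.  Output ordered by genome position.
    """
    by_gene: dict[tuple[str, str], list[HgtCandidate]] = {}
    intergenic: list[HgtCandidate] = []
    genes_by_seq: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_seq.setdefault(g.seq_id, []).append(g)
    for c in candidates:
        hit_gene = None
        for g in genes_by_seq.get(c.seq_id, []):
            if any(_overlaps(c.genome_start, c.genome_end, a, b)
                   for a, b in g.exons):
                hit_gene = g
                break
        if hit_gene is None:
            intergenic.append(c)
        else:
            by_gene.setdefault((hit_gene.gene_id, c.donor_kingdom), []).append(
                replace(c, gene_id=hit_gene.gene_id))
    merged = []
    for (gene_id, _kingdom), members in by_gene.items():
        best = max(members, key=lambda c: c.h)
        merged.append(replace(
            best,
            locus_id=gene_id,
            genome_start=min(c.genome_start for c in members),
            genome_end=max(c.genome_end for c in members),
            member_hits=tuple(h for c in members for h in c.member_hits),
        ))
    merged.extend(intergenic)
    merged.sort(key=lambda c: (c.seq_id, c.genome_start, c.donor_kingdom))
    return merged


def _median_depth(depth: np.ndarray, intervals: Iterable[tuple[int, int]]) -> float:
    chunks = [depth[a:b] for a, b in intervals]
    pooled = np.concatenate(chunks) if chunks else np.array([])
    return float(np.median(pooled)) if pooled.size else float("nan")


def depth_evidence(depth: np.ndarray, locus_exons: Sequence[tuple[int, int]],
                   neighbor_genes: Sequence[GeneModel],
                   band: tuple[float, float] = (0.5, 2.0)) -> EvidenceReport:
    """Compare median read depth over the locus CDS to pooled neighbor CDS.

    Pass iff the ratio lies in ``band`` (inclusive).  A zero/undefined neighbor
    depth leaves the check not-assessable (all fields None except the ratio).
    """
    locus_med = _median_depth(depth, locus_exons)
    nb_med = _median_depth(depth, [iv for g in neighbor_genes for iv in g.exons])
    if not nb_med or np.isnan(nb_med) or np.isnan(locus_med):
        return EvidenceReport(depth_ratio=None, depth_pass=None)
    ratio = locus_med / nb_med
    return EvidenceReport(depth_ratio=ratio,
                          depth_pass=band[0] <= ratio <= band[1])


def matepair_evidence(spans: Sequence[tuple[str, int, int]],
                      locus: tuple[str, int, int],
                      left_gene: GeneModel | None,
                      right_gene: GeneModel | None,
                      min_spans: int = 3) -> EvidenceReport:
    """Count mate-pair spans bridging the locus to each flanking gene.

    A span (left_bp, right_bp) bridges the left junction when its left end
    falls inside the left neighbor and its right end inside (or beyond the
    start of) the locus, and symmetrically on the right.  Loci at sequence
    ends are assessed on the one existing junction.
    """
    seq_id, lstart, lend = locus
    nleft = nright = None
    if left_gene is not None:
        nleft = sum(1 for (sid, a, b) in spans
                    if sid == seq_id and left_gene.start <= a < left_gene.end
                    and b >= lstart)
    if right_gene is not None:
        nright = sum(1 for (sid, a, b) in spans
                     if sid == seq_id and right_gene.start <= b < right_gene.end
                     and a < lend)
    checks = [n >= min_spans for n in (nleft, nright) if n is not None]
    ok = all(checks) if checks else None
    return EvidenceReport(matepair_spans_left=nleft, matepair_spans_right=nright,
                          matepair_pass=ok)


def rna_evidence(coverage: np.ndarray, gene: GeneModel,
                 min_fraction: float = 0.5) -> EvidenceReport:
    """Fraction of CDS bp with sense-strand RNA depth >= 1; pass iff >= min."""
    covered = sum(int(np.count_nonzero(coverage[a:b] >= 1))
                  for a, b in gene.exons)
    frac = covered / gene.cds_length
    return EvidenceReport(rna_covered_fraction=frac,
                          rna_pass=frac >= min_fraction)


def attach_evidence(c: HgtCandidate, *parts: EvidenceReport) -> HgtCandidate:
    """Merge field-wise partial reports into the candidate (annotation only)."""
    merged = {}
    for p in parts:
        for k, v in vars(p).items():
            if v is not None:
                merged[k] = v
    return replace(c, evidence=EvidenceReport(**merged))


def detect_cotransfer(candidates: Sequence[HgtCandidate],
                      genus_of_subject: Mapping[str, str],
                      window_bp: int = 10_000) -> list[CoTransferPair]:
    """Pair consecutive candidate loci whose best donor hits share a genus.

    Only neighboring loci (gap <= window on the same sequence) are compared, so
    three consecutive same-genus loci yield two pairs.  Loci whose donor
    subject has no genus annotation are skipped.
    """
    by_seq: dict[str, list[HgtCandidate]] = {}
    for c in candidates:
        by_seq.setdefault(c.seq_id, []).append(c)
    pairs = []
    for seq_id in sorted(by_seq):
        loci = sorted(by_seq[seq_id], key=lambda c: c.genome_start)
        loci = [c for c in loci
                if genus_of_subject.get(c.best_donor_hit.subject_id)]
        for a, b in zip(loci, loci[1:]):
            gap = max(0, b.genome_start - a.genome_end)
            ga = genus_of_subject[a.best_donor_hit.subject_id]
            gb = genus_of_subject[b.best_donor_hit.subject_id]
            if gap <= window_bp and ga == gb:
                pairs.append(CoTransferPair(a.locus_id, b.locus_id, ga, gap))
    return pairs


def detect_fusion(gene_id: str, donor_hits: Sequence[Hit],
                  adjacency: Mapping[frozenset, bool] | None = None,
                  min_segment: int = 60, max_overlap: int = 10) -> FusionCall | None:
    """Call a donor-gene fusion from localized donor hits on one gene.

    ``donor_hits`` carry query intervals in residues on a shared coordinate
    system for the gene.  A fusion requires two hits to *different* donor
    subjects whose query segments are each >= ``min_segment`` residues and
    overlap by at most ``max_overlap``.  Pairs whose subjects are mutual
    homologs — each subject also hits the *other* subject's segment with
    comparable score — are not fusions (they are one donor family seen
    through two query segments, e.g. the exons of an intron-split gene).
    The highest-scoring qualifying pair is returned; donor adjacency is
    looked up in ``adjacency`` when provided.
    """
    hits = sorted(donor_hits, key=lambda h: (-h.bit_score, h.subject_id))

    def _covers(h: Hit, seg: tuple[int, int], ref_bits: float) -> bool:
        ov = min(h.query_end, seg[1]) - max(h.query_start, seg[0])
        return ov > max_overlap and h.bit_score >= 0.5 * ref_bits

    best_pair = None
    for i, h1 in enumerate(hits):
        for h2 in hits[i + 1:]:
            if h1.subject_id == h2.subject_id:
                continue
            a, b = sorted((h1, h2), key=lambda h: h.query_start)
            if a.query_end - a.query_start < min_segment:
                continue
            if b.query_end - b.query_start < min_segment:
                continue
            if a.query_end - b.query_start > max_overlap:
                continue
            seg_a = (a.query_start, a.query_end)
            seg_b = (b.query_start, b.query_end)
            cross = any(
                (h.subject_id == b.subject_id and _covers(h, seg_a, a.bit_score))
                or (h.subject_id == a.subject_id and _covers(h, seg_b, b.bit_score))
                for h in hits)
            if cross:
                continue
            best_pair = (a, b)
            break
        if best_pair:
            break
    if not best_pair:
        return None
    a, b = best_pair
    adj = None
    if adjacency is not None:
        adj = bool(adjacency.get(frozenset((a.subject_id, b.subject_id)), False))
    return FusionCall(gene_id, (a.query_start, a.query_end),
                      (b.query_start, b.query_end), a.subject_id, b.subject_id,
                      adj)


def flag_intron_acquisition(gene: GeneModel) -> int:
    """Number of introns = exon count - 1 (0 for single-exon genes)."""
    return max(0, len(gene.exons) - 1)
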