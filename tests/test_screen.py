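"""The h statistic, candidate calling, merging, evidence, and architectures."""

import numpy as np
import pytest

from hgtscreen.homology import Hit
from hgtscreen.screen import (GeneModel, HgtCandidate,
                              ScreenThresholds, assign_to_genes,
                              call_candidates, compute_h, depth_evidence,
                              detect_cotransfer, detect_fusion,
                              flag_intron_acquisition, matepair_evidence,
                              rna_evidence)
from hgtscreen.seqprep import Ppp


def _hit(bits, subject="s", qs=0, qe=100):
    return Hit("q", subject, 0.0, bits, qs, qe)


@pytest.mark.parametrize("donor,euk,expected", [
    (150.0, 100.0, 50.0),
    (120.0, None, 120.0),
    (100.0, 100.0, 0.0),
])
def test_compute_h_definition(donor, euk, expected):
    best_euk = _hit(euk) if euk is not None else None
    assert compute_h(_hit(donor), best_euk) == expected


class _Res:
    def __init__(self, best, hits=None):
        self.best = best
        self.hits = hits if hits is not None else ([best] if best else [])


def _query(qid="p1", start=0, end=300):
    return Ppp(qid, "s", 1, "A" * ((end - start) // 3), start, end)


@pytest.mark.parametrize("h,donor_bits,called", [
    (30.0, 100.0, True),    # inclusive boundaries
    (29.9, 500.0, False),
    (80.0, 99.0, False),
    (30.1, 100.1, True),
])
def test_candidate_thresholds_inclusive(h, donor_bits, called):
    q = _query()
    donor = {q.id: _Res(_hit(donor_bits, "don"))}
    euk = {q.id: _Res(_hit(donor_bits - h, "euk"))}
    out = call_candidates([q], donor, euk, "bacteria")
    assert (len(out) == 1) is called
    for c in out:
        assert c.h >= 30.0 and c.best_donor_hit.bit_score >= 100.0


def test_candidate_with_no_eukaryote_hit_uses_zero_bits():
    q = _query()
    out = call_candidates([q], {q.id: _Res(_hit(120.0, "don"))}, {}, "fungi")
    assert len(out) == 1 and out[0].h == 120.0


def test_h_invariant_under_adding_worse_hits():
    q = _query()
    base = call_candidates([q], {q.id: _Res(_hit(200.0, "don"))},
                           {q.id: _Res(_hit(50.0, "euk"))}, "bacteria")[0]
    # the best hits define h regardless of how many worse hits exist
    assert base.h == 150.0


def test_raising_thresholds_never_adds_candidates():
    qs = [_query(f"p{i}", i * 300, (i + 1) * 300) for i in range(5)]
    donor = {q.id: _Res(_hit(100 + 10 * i, "don"))
             for i, q in enumerate(qs)}
    euk = {q.id: _Res(_hit(60.0, "euk")) for q in qs}
    loose = call_candidates(qs, donor, euk, "bacteria",
                            ScreenThresholds(30, 100))
    tight = call_candidates(qs, donor, euk, "bacteria",
                            ScreenThresholds(60, 120))
    assert {c.locus_id for c in tight} <= {c.locus_id for c in loose}


def _gene(gid, start, end, strand="+", introns=()):
    if not introns:
        return GeneModel(gid, "s", strand, ((start, end),))
    exons, prev = [], start
    for a, b in introns:
        exons.append((prev, a))
        prev = b
    exons.append((prev, end))
    return GeneModel(gid, "s", strand, tuple(exons))


def test_assign_merges_ppps_on_one_gene_keeping_max_h():
    g = _gene("G1", 100, 1000)
    c1 = HgtCandidate("p1", "s", 120, 420, "bacteria", 50.0,
                      _hit(150, "d1"), None, member_hits=(_hit(150, "d1"),))
    c2 = HgtCandidate("p2", "s", 500, 900, "bacteria", 80.0,
                      _hit(180, "d2"), None, member_hits=(_hit(180, "d2"),))
    merged = assign_to_genes([c1, c2], [g])
    assert len(merged) == 1
    assert merged[0].locus_id == "G1" and merged[0].h == 80.0
    assert len(merged[0].member_hits) == 2


def test_assign_keeps_intergenic_candidates():
    g = _gene("G1", 100, 400)
    c = HgtCandidate("p1", "s", 5000, 5300, "fungi", 40.0, _hit(120), None)
    merged = assign_to_genes([c], [g])
    assert merged[0].gene_id is None and merged[0].locus_id == "p1"


def test_depth_evidence_band():
    depth = np.full(1000, 30.0)
    rep = depth_evidence(depth, [(0, 100)], [_gene("N1", 200, 300)])
    assert rep.depth_ratio == pytest.approx(1.0) and rep.depth_pass
    depth[:100] = 10.0
    depth[200:300] = 40.0
    rep = depth_evidence(depth, [(0, 100)], [_gene("N1", 200, 300)])
    assert rep.depth_ratio == pytest.approx(0.25) and not rep.depth_pass


def test_depth_evidence_zero_neighbors_not_assessable():
    depth = np.zeros(400)
    depth[:100] = 30.0
    rep = depth_evidence(depth, [(0, 100)], [_gene("N1", 200, 300)])
    assert rep.depth_ratio is None and rep.depth_pass is None


def test_depth_evidence_poisson_pass_rate():
    """Planted loci under Poisson(30) coverage pass the similarity band."""
    rng = np.random.default_rng(11)
    passed = 0
    for _ in range(100):
        depth = rng.poisson(30, size=3000).astype(float)
        rep = depth_evidence(depth, [(1000, 1600)],
                             [_gene("L", 0, 600), _gene("R", 2200, 2900)])
        passed += bool(rep.depth_pass)
    assert passed >= 95


def test_matepair_evidence_counts_junction_spans():
    left, right = _gene("L", 0, 500), _gene("R", 1500, 2000)
    locus = ("s", 600, 1400)
    spans = [("s", 100, 700)] * 5 + [("s", 1300, 1800)] * 5
    rep = matepair_evidence(spans, locus, left, right)
    assert rep.matepair_spans_left == 5 and rep.matepair_spans_right == 5
    assert rep.matepair_pass
    rep2 = matepair_evidence(spans[:5], locus, left, right)
    assert rep2.matepair_spans_right == 0 and not rep2.matepair_pass
    # locus at a sequence end: only the existing junction is assessed
    rep3 = matepair_evidence(spans, locus, None, right)
    assert rep3.matepair_spans_left is None and rep3.matepair_pass


@pytest.mark.parametrize("covered,passes", [(1.0, True), (0.0, False),
                                            (0.5, True)])
def test_rna_evidence_covered_fraction(covered, passes):
    g = _gene("G", 0, 100)
    track = np.zeros(200)
    track[:int(100 * covered)] = 3.0
    rep = rna_evidence(track, g)
    assert rep.rna_covered_fraction == pytest.approx(covered)
    assert rep.rna_pass is passes


def _cand(lid, start, end, subject):
    return HgtCandidate(lid, "s", start, end, "bacteria", 50.0,
                        _hit(150.0, subject), None)


def test_cotransfer_pairs_same_genus_neighbors():
    genus = {"d1": "Cardinium", "d2": "Cardinium", "d3": "Rickettsia"}
    a, b = _cand("A", 0, 1000, "d1"), _cand("B", 3000, 4000, "d2")
    assert len(detect_cotransfer([a, b], genus)) == 1
    c = _cand("C", 3000, 4000, "d3")
    assert detect_cotransfer([a, c], genus) == []
    # beyond the window: no pair
    far = _cand("F", 20000, 21000, "d2")
    assert detect_cotransfer([a, far], genus) == []


def test_cotransfer_three_consecutive_gives_two_pairs():
    genus = {f"d{i}": "Pseudomonas" for i in range(3)}
    loci = [_cand(f"L{i}", i * 2000, i * 2000 + 1000, f"d{i}")
            for i in range(3)]
    pairs = detect_cotransfer(loci, genus)
    assert [(p.locus_a, p.locus_b) for p in pairs] == [("L0", "L1"),
                                                       ("L1", "L2")]


def test_cotransfer_skips_missing_genus():
    a, b = _cand("A", 0, 1000, "d1"), _cand("B", 2000, 3000, "d2")
    assert detect_cotransfer([a, b], {"d1": "Cardinium"}) == []


def test_fusion_two_disjoint_segments_different_donors():
    hits = [_hit(200, "P1", 0, 250), _hit(190, "P2", 260, 500)]
    call = detect_fusion("G", hits, {frozenset(("P1", "P2")): True})
    assert call is not None and call.donors_adjacent
    assert call.donor_a == "P1" and call.donor_b == "P2"


def test_fusion_not_called_for_single_donor_or_overlap():
    assert detect_fusion("G", [_hit(200, "P1", 0, 250),
                               _hit(150, "P1", 260, 500)]) is None
    overlapping = [_hit(200, "P1", 0, 250), _hit(190, "P2", 200, 500)]
    assert detect_fusion("G", overlapping) is None


def test_fusion_rejects_mutual_homolog_pairs():
    """Two family members hit both segments: one family, not a fusion."""
    hits = [_hit(200, "P1", 0, 250), _hit(190, "P2", 260, 500),
            _hit(180, "P2", 0, 250), _hit(170, "P1", 260, 500)]
    assert detect_fusion("G", hits) is None


@pytest.mark.parametrize("introns,expected", [((), 0), (((200, 300),), 1),
                                              (((200, 260), (400, 500)), 2)])
def test_intron_count_from_exons(introns, expected):
    g = _gene("G", 0, 900, introns=introns)
    assert flag_intron_acquisition(g) == expected
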