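"""Alignment, trimming, distances, NJ, monophyly, and bootstrap."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from hgtscreen.homology import ProteinRecord
from hgtscreen.phylo import (Msa, TrimError, ValidateConfig,
                             bootstrap_support, monophyly_test, nj_tree,
                             pairwise_distance, progressive_align,
                             trim_gap_columns, validate_candidate)

from _oracles import monophyly_oracle, random_additive_tree, tree_splits


def _rec(name, seq, taxon="bacteria"):
    return ProteinRecord(name, taxon, seq)


class TestProgressiveAlign:
    def test_identical_sequences_align_gapless(self):
        m = progressive_align([_rec("a", "HEAGAWGHEE"), _rec("b", "HEAGAWGHEE")])
        assert m.rows == ("HEAGAWGHEE", "HEAGAWGHEE")

    def test_single_deletion_opens_one_gap_column(self):
        m = progressive_align([_rec("a", "ACDEFG"), _rec("b", "ACEFG")])
        assert m.width == 6
        assert m.rows[0] == "ACDEFG"
        assert m.rows[1] == "AC-EFG"

    def test_width_at_least_longest_input(self):
        recs = [_rec("a", "MKVLA" * 8), _rec("b", "MKVA" * 9),
                _rec("c", "MKVLA" * 7 + "WW")]
        m = progressive_align(recs)
        assert m.width >= max(len(r.sequence) for r in recs)

    def test_degapping_reproduces_inputs(self):
        recs = [_rec("a", "MKVLAWGH"), _rec("b", "MKVAWH"),
                _rec("c", "MKVLAWGHEE"), _rec("d", "KVLAGH")]
        m = progressive_align(recs)
        for i, r in enumerate(recs):
            assert m.degapped(i) == r.sequence

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            progressive_align([_rec("a", "MKVLA")])


class TestTrim:
    def _msa(self, rows):
        return Msa(tuple(f"r{i}" for i in range(len(rows))),
                   tuple("query" for _ in rows), tuple(rows))

    def test_gap_fraction_boundary_strict(self):
        # 10 rows: 2 gaps (0.2) kept, 3 gaps (0.3) removed
        col_keep = ["A"] * 8 + ["-"] * 2
        col_drop = ["A"] * 7 + ["-"] * 3
        rows = ["".join(p) for p in zip(col_keep, col_drop)]
        t = trim_gap_columns(self._msa(rows))
        assert t.width == 1
        assert [r for r in t.rows] == col_keep

    def test_gapless_alignment_unchanged_and_idempotent(self):
        m = self._msa(["ACDE", "ACDE", "ACDE"])
        t = trim_gap_columns(m)
        assert t.rows == m.rows
        m2 = self._msa(["A-CE", "AC-E", "-ACE"])
        once = trim_gap_columns(m2, ValidateConfig(gap_trim_fraction=0.4))
        twice = trim_gap_columns(once, ValidateConfig(gap_trim_fraction=0.4))
        assert once.rows == twice.rows

    def test_all_columns_removed_raises(self):
        m = self._msa(["A-", "-A"])
        with pytest.raises(TrimError):
            trim_gap_columns(m)


class TestDistance:
    def test_identical_rows_distance_zero(self):
        m = Msa(("a", "b"), ("x", "x"), ("ACDE", "ACDE"))
        assert pairwise_distance(m)["a", "b"] == 0.0

    def test_kimura_formula_value(self):
        # p = 0.1 -> -ln(1 - 0.1 - 0.002) = 0.10763...
        rows = ("A" * 9 + "C", "A" * 9 + "D")
        m = Msa(("a", "b"), ("x", "x"), rows)
        expected = -math.log(1 - 0.1 - 0.2 * 0.01)
        assert pairwise_distance(m)["a", "b"] == pytest.approx(expected,
                                                               abs=1e-12)

    def test_distance_increasing_in_p_and_clamped(self):
        prev = -1.0
        for k in range(0, 9):
            rows = ("A" * 10, "A" * (10 - k) + "C" * k)
            d = pairwise_distance(Msa(("a", "b"), ("x", "x"), rows))["a", "b"]
            assert d > prev
            prev = d
        saturated = ("A" * 10, "C" * 9 + "A")
        d = pairwise_distance(Msa(("a", "b"), ("x", "x"), saturated))["a", "b"]
        assert d == 5.0

    def test_no_comparable_columns(self):
        m = Msa(("a", "b"), ("x", "x"), ("A-", "-A"))
        with pytest.raises(ValueError):
            pairwise_distance(m)
        assert pairwise_distance(m, on_empty="max")["a", "b"] == 5.0


class TestNj:
    def test_three_taxa_single_topology(self):
        dm = DistanceMatrix(np.array([[0, .3, .4], [.3, 0, .5], [.4, .5, 0]]),
                            ["a", "b", "c"])
        t = nj_tree(dm)
        assert {x.name for x in t.tips()} == {"a", "b", "c"}

    def test_four_taxa_recovers_split(self):
        d = np.array([[0, .2, .6, .6], [.2, 0, .6, .6],
                      [.6, .6, 0, .2], [.6, .6, .2, 0]])
        t = nj_tree(DistanceMatrix(d, ["A", "B", "C", "D"]))
        from hgtscreen.phylo import _bipartition_sides
        splits = tree_splits(_bipartition_sides(t),
                             frozenset(["A", "B", "C", "D"]))
        assert frozenset(["A", "B"]) in splits

    def test_recovers_random_additive_topologies(self):
        """NJ on additive matrices reproduces the generating tree splits."""
        from hgtscreen.phylo import _bipartition_sides
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 9))
            labels, d, true_splits = random_additive_tree(rng, n)
            t = nj_tree(DistanceMatrix(d, labels))
            got = tree_splits(_bipartition_sides(t), frozenset(labels))
            want = tree_splits(list(true_splits), frozenset(labels))
            assert got == want, f"seed {seed}"

    def test_branch_lengths_non_negative(self):
        d = np.array([[0, .1, .9, .9], [.1, 0, .2, .3],
                      [.9, .2, 0, .1], [.9, .3, .1, 0]])
        t = nj_tree(DistanceMatrix(d, list("abcd")))
        for node in t.traverse(include_self=False):
            assert node.length is None or node.length >= 0


class TestMonophyly:
    def _tree(self, newick):
        from skbio import TreeNode
        import io as _io
        return TreeNode.read(_io.StringIO(newick))

    def test_query_nested_with_donor(self):
        t = self._tree("((q:1,b1:1):1,(e1:1,e2:1):1);")
        taxon = {"q": "query", "b1": "bacteria", "e1": "metazoa",
                 "e2": "metazoa"}
        assert monophyly_test(t, "q", "bacteria", taxon)

    def test_query_nested_with_eukaryote(self):
        t = self._tree("((q:1,e1:1):1,(b1:1,b2:1):1);")
        taxon = {"q": "query", "e1": "metazoa", "b1": "bacteria",
                 "b2": "bacteria"}
        assert not monophyly_test(t, "q", "bacteria", taxon)

    def test_query_absent_raises(self):
        t = self._tree("((a:1,b:1):1,c:1);")
        with pytest.raises(ValueError):
            monophyly_test(t, "q", "bacteria", {})

    def test_only_query_and_donor_leaves_passes(self):
        t = self._tree("((q:1,b1:1):1,b2:1);")
        taxon = {"q": "query", "b1": "bacteria", "b2": "bacteria"}
        assert monophyly_test(t, "q", "bacteria", taxon)

    def test_agrees_with_bipartition_enumeration_oracle(self):
        """100 random trees (<= 10 leaves): implementation equals the
        dendropy-based exhaustive enumeration."""
        taxa_pool = ["bacteria", "fungi", "metazoa", "plants"]
        from skbio import TreeNode
        import io as _io
        agree = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            n = int(rng.integers(4, 11))
            labels, d, _ = random_additive_tree(rng, n)
            t = nj_tree(DistanceMatrix(d, labels))
            taxon_of = {lab: taxa_pool[rng.integers(0, len(taxa_pool))]
                        for lab in labels}
            query = labels[int(rng.integers(0, n))]
            taxon_of[query] = "query"
            donor = taxa_pool[int(rng.integers(0, 2))]
            got = monophyly_test(t, query, donor, taxon_of)
            want = monophyly_oracle(str(t), query, donor, taxon_of)
            assert got == want, f"seed {seed}"
            agree += 1
        assert agree == 100


class TestBootstrap:
    def _msa_signal(self):
        rows = ("MKVLAWGHEEMKVLAWGHEE",
                "MKVLAWGHEEMKVLAWGHEE",
                "MKVLAWGHEEMKVLAWGHEE",
                "WCPNQRSTYIDFHKLMEAGV",
                "CWNPQSRYTIFDKHMLAEVG")
        return Msa(("q", "b1", "b2", "e1", "e2"),
                   ("query", "bacteria", "bacteria", "metazoa", "metazoa"),
                   rows)

    def test_perfect_signal_full_support(self):
        m = self._msa_signal()
        taxon = dict(zip(m.ids, m.taxa))
        s = bootstrap_support(m, "q", "bacteria", taxon,
                              ValidateConfig(bootstrap_reps=100), seed=3)
        assert s == 100

    def test_support_bounded_and_reproducible(self):
        m = self._msa_signal()
        taxon = dict(zip(m.ids, m.taxa))
        cfg = ValidateConfig(bootstrap_reps=25)
        s1 = bootstrap_support(m, "q", "bacteria", taxon, cfg, seed=9)
        s2 = bootstrap_support(m, "q", "bacteria", taxon, cfg, seed=9)
        assert s1 == s2 <= 25


class TestValidateCandidate:
    def test_planted_bacterial_candidate_validated(self, bundle42, screen42,
                                                   validate42):
        truth = bundle42.truth.set_index("gene_id")
        for locus_id, res in validate42.items():
            kingdom = truth.loc[locus_id, "donor_taxon"]
            assert res.donor_taxon == kingdom
            assert res.verdict == "validated", locus_id

    def test_intrinsic_decoy_rejected(self, bundle42):
        """An intrinsic gene forced through validation is not monophyletic
        with bacteria (its homologs are metazoan)."""
        from hgtscreen.pipeline import run_validate
        from hgtscreen.screen import HgtCandidate
        from hgtscreen.homology import Hit
        from hgtscreen.seqprep import reverse_complement, translate_nt
        intr = bundle42.truth[bundle42.truth.cls == "intrinsic"].iloc[0]
        g = next(g for g in bundle42.genes if g.gene_id == intr.gene_id)
        sp = "".join(bundle42.genome.residues[a:b] for a, b in g.exons)
        if bundle42.gene_strand[g.gene_id] == "-":
            sp = reverse_complement(sp)
        pep = translate_nt(sp).rstrip("*")
        decoy = HgtCandidate(g.gene_id, g.seq_id, g.start, g.end, "bacteria",
                             0.0, Hit("q", "s", 0.0, 0.0), None,
                             validation_pep=pep)
        res = run_validate(bundle42, [decoy], seed=7)
        assert res[g.gene_id].verdict == "rejected"

    def test_too_few_sequences_not_assessable(self):
        from hgtscreen.homology import TaxonDb
        dbs = {"bacteria": TaxonDb("donor", ())}
        res = validate_candidate("c", "MKVLAWGHEE" * 6, "bacteria", dbs)
        assert res.verdict == "not_assessable"
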