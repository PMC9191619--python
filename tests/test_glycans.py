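"""Glycan model: condensed-sequence parsing, compositions, motif matching.

The motif matcher is checked against an independent brute-force oracle that
enumerates *all* injective node mappings and tests the embedding constraints
directly (no shared code with the production matcher).
"""

from itertools import permutations

import numpy as np
import pytest

from glyarray import (Composition, GlycanProbe, GrammarError, MotifPattern,
                      ProbeQuery, VocabularyError, composition, filter_probes,
                      match_motif, monosaccharide_dictionary, motif_dictionary,
                      parse_iupac)
from glyarray.glycans import GlycanNode, GlycanTree


# ---------------------------------------------------------------------------
# brute-force embedding oracle

def brute_force_count(tree: GlycanTree, motif: MotifPattern) -> int:
    """Enumerate every injective pattern→tree node mapping and count those
    satisfying the rooted-embedding constraints."""
    p_ids = sorted(motif.pattern_tree.nodes)
    t_ids = sorted(tree.nodes)
    if len(t_ids) < len(p_ids):
        return 0
    pt = motif.pattern_tree
    t_leaves = set(tree.leaves())
    p_leaves = set(pt.leaves())
    count = 0
    for images in permutations(t_ids, len(p_ids)):
        mapping = dict(zip(p_ids, images))
        ok = True
        for pid in p_ids:
            p = pt.nodes[pid]
            t = tree.nodes[mapping[pid]]
            if p.symbol != t.symbol:
                ok = False
                break
            if p.anomer != "?" and p.anomer != t.anomer:
                ok = False
                break
            if pid == pt.root:
                if motif.anchor == "reducing_end" and mapping[pid] != tree.root:
                    ok = False
                    break
            else:
                # parent relation + linkage fields must hold on non-root nodes
                if t.parent != mapping[pt.nodes[pid].parent]:
                    ok = False
                    break
                if p.child_pos is not None and p.child_pos != t.child_pos:
                    ok = False
                    break
                if p.parent_pos is not None and p.parent_pos != t.parent_pos:
                    ok = False
                    break
            if (motif.anchor == "nonreducing_terminal" and pid in p_leaves
                    and mapping[pid] not in t_leaves):
                ok = False
                break
        if ok:
            count += 1
    return count


SYMBOLS = ["Gal", "Glc", "GlcNAc", "Fuc", "NeuAc", "Man"]


def random_tree(rng: np.random.Generator, max_nodes: int) -> GlycanTree:
    n = int(rng.integers(1, max_nodes + 1))
    nodes = {}
    for i in range(1, n + 1):
        parent = None if i == 1 else int(rng.integers(1, i))
        nodes[i] = GlycanNode(
            id=i, symbol=str(rng.choice(SYMBOLS)),
            anomer=str(rng.choice(["a", "b", "?"])),
            parent=parent,
            child_pos=None if parent is None else
            [None, 1, 2][int(rng.integers(0, 3))],
            parent_pos=None if parent is None else
            [None, 2, 3, 4, 6][int(rng.integers(0, 5))])
    return GlycanTree(nodes=nodes, root=1)


class TestParseIupac:
    def test_sialyllactosyl_sequence(self):
        """The glycan part of the canonical sialylated glycolipid probe."""
        tree = parse_iupac("NeuAcα-3Galß-4Glcß")
        assert len(tree) == 3
        root = tree.nodes[tree.root]
        assert root.symbol == "Glc" and root.anomer == "b"
        gal = next(n for n in tree.nodes.values() if n.symbol == "Gal")
        neu = next(n for n in tree.nodes.values() if n.symbol == "NeuAc")
        assert (gal.child_pos, gal.parent_pos, gal.anomer) == (1, 4, "b")
        assert gal.parent == tree.root
        assert (neu.child_pos, neu.parent_pos, neu.anomer) == (None, 3, "a")
        assert neu.parent == gal.id

    def test_single_residue(self):
        tree = parse_iupac("Gal")
        assert len(tree) == 1
        assert composition(tree).as_dict() == {"Gal": 1}

    def test_branched_lewis_core(self):
        tree = parse_iupac("Galß-4(Fucα-3)GlcNAc")
        root = tree.nodes[tree.root]
        assert root.symbol == "GlcNAc"
        kids = {tree.nodes[c].symbol: tree.nodes[c] for c in tree.children(tree.root)}
        assert set(kids) == {"Gal", "Fuc"}
        assert kids["Gal"].parent_pos == 4 and kids["Fuc"].parent_pos == 3

    @pytest.mark.parametrize("seq,err", [
        ("Galz-4Glc", VocabularyError),   # 'z' starts an unknown token
        ("Foo-3Gal", VocabularyError),
        ("Galß-4(Fucα-3GlcNAc", GrammarError),
        ("Galß-4)Fucα-3(GlcNAc", GrammarError),
        ("", GrammarError),
    ])
    def test_errors(self, seq, err):
        with pytest.raises(err):
            parse_iupac(seq)

    def test_unicode_and_ascii_anomer_spellings_agree(self):
        variants = ["NeuAcα-3Galß-4Glcß", "NeuAca-3Galb-4Glcb",
                    "NeuAcα-3Galβ-4Glcβ"]
        trees = [parse_iupac(v) for v in variants]
        ref = [(n.symbol, n.anomer, n.parent_pos) for n in trees[0].nodes.values()]
        for t in trees[1:]:
            assert [(n.symbol, n.anomer, n.parent_pos)
                    for n in t.nodes.values()] == ref

    def test_explicit_anomeric_position_spelling(self):
        tree = parse_iupac("Neu5Acα2-3Galβ1-4Glc")
        neu = next(n for n in tree.nodes.values() if n.symbol == "NeuAc")
        gal = next(n for n in tree.nodes.values() if n.symbol == "Gal")
        assert neu.child_pos == 2 and gal.child_pos == 1


class TestComposition:
    def test_counts_and_conservation(self):
        tree = parse_iupac("NeuAcα-3Galß-4Glcß")
        comp = composition(tree)
        assert comp.as_dict() == {"NeuAc": 1, "Gal": 1, "Glc": 1}
        assert comp.total() == len(tree)

    def test_conservation_on_random_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            tree = random_tree(rng, 8)
            assert composition(tree).total() == len(tree)


class TestMatchMotif:
    def test_lactose_in_sialyllactose(self):
        tree = parse_iupac("NeuAcα-3Galß-4Glcß")
        res = match_motif(tree, MotifPattern.from_sequence("Galb-4Glc"))
        assert res.matched and res.n_sites == 1

    def test_wrong_sialyl_linkage_rejected(self):
        tree = parse_iupac("NeuAcα-3Galß-4Glcß")
        res = match_motif(tree, MotifPattern.from_sequence("NeuAca-6Gal"))
        assert not res.matched and res.n_sites == 0

    def test_identity_embedding_at_reducing_end(self):
        tree = parse_iupac("NeuAcα-3Galß-4Glcß")
        pat = MotifPattern.from_sequence("NeuAca-3Galb-4Glcb",
                                         anchor="reducing_end")
        res = match_motif(tree, pat)
        assert res.matched and res.n_sites == 1
        assert res.sites == [frozenset(tree.nodes)]

    def test_repeated_motif_counted_per_site(self):
        tree = parse_iupac("Galb-4GlcNAcb-3Galb-4GlcNAc")  # two LacNAc units
        res = match_motif(tree, MotifPattern.from_sequence("Galb-4GlcNAc"))
        assert res.n_sites == 2

    def test_terminal_anchor_excludes_internal_site(self):
        tree = parse_iupac("NeuAca-3Galb-4GlcNAc")
        internal = MotifPattern.from_sequence("Galb-4GlcNAc",
                                              anchor="nonreducing_terminal")
        assert not match_motif(tree, internal).matched
        terminal = MotifPattern.from_sequence("NeuAca-3Gal",
                                              anchor="nonreducing_terminal")
        assert match_motif(tree, terminal).matched

    @pytest.mark.parametrize("anchor", ["anywhere", "reducing_end",
                                        "nonreducing_terminal"])
    def test_agrees_with_brute_force_oracle(self, anchor):
        """≥ 500 random (tree ≤ 8, pattern ≤ 4 node) cases per anchor."""
        rng = np.random.default_rng(2024)
        for _ in range(500):
            tree = random_tree(rng, 8)
            pattern = MotifPattern(pattern_tree=random_tree(rng, 4),
                                   anchor=anchor)
            expected = brute_force_count(tree, pattern)
            got = match_motif(tree, pattern)
            assert got.n_sites == expected
            assert got.matched == (expected > 0)


class TestDictionaries:
    def test_monosaccharide_dictionary_size_and_uniqueness(self):
        entries = monosaccharide_dictionary()
        assert len(entries) == 69
        assert all(e["name"] and e["snfg_class"] for e in entries.values())

    def test_motif_dictionary_size_and_parseability(self):
        motifs = motif_dictionary()
        assert len(motifs) == 60
        assert len({m.motif_name for m in motifs}) == 60
        for m in motifs:
            assert len(m.pattern_tree) >= 1  # parsed into a tree already

    def test_every_motif_embeds_in_itself(self):
        for m in motif_dictionary():
            if m.anchor == "anywhere":
                assert match_motif(m.pattern_tree, m).matched


class TestProbesAndFiltering:
    def gsc_pair(self):
        seq = "NeuAcα-3Galß-4Glcß"
        p16 = GlycanProbe(probe_key="GSC-16", sequences={"CFG-IUPAC": seq},
                          tag={"tag_name": "Cer32", "description": "C32 ceramide"})
        p18 = GlycanProbe(probe_key="GSC-18", sequences={"CFG-IUPAC": seq},
                          tag={"tag_name": "Cer42", "description": "C42 ceramide"})
        return p16, p18

    def test_tag_stored_separately_from_glycan(self):
        p16, p18 = self.gsc_pair()
        assert p16.same_glycan(p18)  # identical glycan moiety
        assert p16.tag != p18.tag    # different lipid tags
        assert p16.probe_key != p18.probe_key

    def test_monosaccharide_filter(self):
        p16, _ = self.gsc_pair()
        lac = GlycanProbe(probe_key="LAC", sequences={"CFG-IUPAC": "Galß-4Glc"})
        subset, explain = filter_probes([p16, lac],
                                        ProbeQuery(monosaccharide="NeuAc"))
        assert [p.probe_key for p in subset] == ["GSC-16"]
        assert "lacks NeuAc" in explain["LAC"]

    def test_empty_query_is_identity(self):
        p16, p18 = self.gsc_pair()
        subset, _ = filter_probes([p16, p18], ProbeQuery())
        assert subset == [p16, p18]

    def test_unparseable_sequence_excluded_with_reason(self):
        wurcs_only = GlycanProbe(
            probe_key="W1",
            sequences={"WURCS": "WURCS=2.0/1,1,0/[a2122h-1b_1-5]/1/"})
        subset, explain = filter_probes([wurcs_only],
                                        ProbeQuery(monosaccharide="Glc"))
        assert subset == [] and explain["W1"] == "unparsed"

    def test_motif_filter_on_probe_panel(self):
        probes = [
            GlycanProbe(probe_key="A", sequences={"CFG-IUPAC": "NeuAca-3Galb-4Glcb"}),
            GlycanProbe(probe_key="B", sequences={"CFG-IUPAC": "Galb-4GlcNAcb"}),
            GlycanProbe(probe_key="C", sequences={"CFG-IUPAC": "Gala-4Galb-4Glcb"}),
        ]
        subset, _ = filter_probes(probes, ProbeQuery(motif="Galb-4Glc"))
        assert [p.probe_key for p in subset] == ["A", "C"]
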