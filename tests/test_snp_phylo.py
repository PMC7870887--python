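"""Thinning, alignments, p-distances, neighbor joining and rooting."""

import itertools

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from germpanel import snp_phylo
from germpanel.panel import GenotypePanel, SiteRecord
from germpanel.snp_phylo import SNPAlignment, nj_tree, p_distance_matrix

from conftest import brute_p_distance, make_panel, random_panel


class TestThinning:
    def test_every_fifth_of_large_set(self):
        n = 25_496
        sites = [
            SiteRecord(chrom="Gm01", pos=i + 1, ref="A", alt="G") for i in range(n)
        ]
        panel = GenotypePanel(
            samples=["s"], sites=sites, geno=np.zeros((1, n), dtype=np.int8)
        )
        assert snp_phylo.thin_sites(panel, step=5).n_sites == 5_100

    def test_step_one_is_identity(self, rng):
        panel = random_panel(rng, 2, 17)
        thinned = snp_phylo.thin_sites(panel, step=1)
        assert [s.key for s in thinned.sites] == [s.key for s in panel.sites]

    def test_offset_selects_shifted_indices(self):
        panel = make_panel([[0] * 10], positions=list(range(100, 1100, 100)))
        thinned = snp_phylo.thin_sites(panel, step=5, offset=4)
        assert [s.pos for s in thinned.sites] == [500, 1000]


class TestAlignment:
    def test_column_coding_iupac(self):
        panel = make_panel([[0], [2], [1], [-1]], ref="A", alt="G")
        aln = snp_phylo.panel_to_alignment(panel, het_policy="iupac")
        assert [s[0] for s in aln.seqs] == ["A", "G", "R", "N"]

    def test_het_policy_missing(self):
        panel = make_panel([[1]], ref="C", alt="T")
        aln = snp_phylo.panel_to_alignment(panel, het_policy="missing")
        assert aln.seqs[0] == "N"

    def test_all_missing_sample_is_all_N(self):
        panel = make_panel([[-1, -1, -1]])
        aln = snp_phylo.panel_to_alignment(panel)
        assert aln.seqs[0] == "NNN"

    def test_length_equals_site_count(self, rng):
        panel = random_panel(rng, 3, 23)
        assert snp_phylo.panel_to_alignment(panel).length == 23

    def test_fasta_roundtrip(self, tmp_path, rng):
        panel = random_panel(rng, 4, 90)
        aln = snp_phylo.panel_to_alignment(panel)
        aln.to_fasta(tmp_path / "a.fna")
        back = SNPAlignment.from_fasta(tmp_path / "a.fna")
        assert back.labels == aln.labels and back.seqs == aln.seqs


class TestPDistance:
    def test_matches_column_loop_oracle(self, rng):
        for _ in range(3):
            panel = random_panel(rng, rng.integers(3, 11), rng.integers(10, 101))
            aln = snp_phylo.panel_to_alignment(panel)
            D, comp = p_distance_matrix(aln)
            for i in range(len(aln.seqs)):
                for j in range(len(aln.seqs)):
                    want, want_comp = brute_p_distance(aln.seqs[i], aln.seqs[j])
                    if i != j:
                        assert comp[i, j] == want_comp
                        if want is None:
                            assert np.isnan(D[i, j])
                        else:
                            assert D[i, j] == pytest.approx(want, abs=1e-15)

    def test_hand_examples(self):
        aln = SNPAlignment(labels=["a", "b", "c"], seqs=["ACGT", "ACGA", "ANGT"])
        D, comp = p_distance_matrix(aln)
        assert D[0, 0] == 0
        assert D[0, 1] == pytest.approx(0.25)
        assert D[0, 2] == 0 and comp[0, 2] == 3  # N column excluded
        # ambiguity codes excluded like N
        aln2 = SNPAlignment(labels=["a", "b", "c"], seqs=["ARGT", "ACGT", "ACGT"])
        D2, comp2 = p_distance_matrix(aln2)
        assert comp2[0, 1] == 3 and D2[0, 1] == 0


def _enumerate_five_taxon_trees():
    """All 15 labeled unrooted 5-taxon topologies, grown by leaf insertion."""
    # tree as dict: edges list of (u, v); leaves 0..4, internal nodes >= 5
    base = {"edges": [(0, 5), (1, 5), (2, 5)], "next": 6}
    trees = [base]
    for leaf in (3, 4):
        grown = []
        for t in trees:
            for k in range(len(t["edges"])):
                u, v = t["edges"][k]
                new_internal = t["next"]
                edges = [e for i, e in enumerate(t["edges"]) if i != k]
                edges += [(u, new_internal), (new_internal, v), (leaf, new_internal)]
                grown.append({"edges": edges, "next": new_internal + 1})
        trees = grown
    return trees


def _additive_matrix(edges, lengths, n_leaves):
    import networkx as nx

    g = nx.Graph()
    for (u, v), w in zip(edges, lengths):
        g.add_edge(u, v, weight=w)
    D = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        sp = nx.single_source_dijkstra_path_length(g, i)
        for j in range(n_leaves):
            D[i, j] = sp[j]
    return (D + D.T) / 2.0  # remove float asymmetry from path summation


def _splits(tree):
    """Nontrivial leaf bipartitions, each normalized to the side holding the
    lexicographically smallest taxon."""
    taxa = {l.taxon.label for l in tree.leaf_node_iter()}
    anchor = min(taxa)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = {l.taxon.label for l in node.leaf_iter()}
        if 1 < len(side) < len(taxa) - 1:
            out.add(frozenset(side) if anchor in side else frozenset(taxa - side))
    return out


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        # generating tree ((A:1,B:2):1,(C:3,D:4))
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(D, list("ABCD"))
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for (a, b), want in {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
                             ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7}.items():
            assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(want, abs=1e-9)
        assert tree.negative_branches_clamped == 0

    def test_all_fifteen_five_taxon_topologies_recovered(self):
        rng = np.random.default_rng(42)
        labels = [f"T{i}" for i in range(5)]
        topologies = _enumerate_five_taxon_trees()
        assert len(topologies) == 15
        seen = set()
        for top in topologies:
            lengths = rng.uniform(0.5, 2.0, size=len(top["edges"]))
            D = _additive_matrix(top["edges"], lengths, 5)
            tree = nj_tree(D, labels)
            # recovered pairwise distances reproduce the generating metric
            pdm = tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.taxon_namespace}
            for i, j in itertools.combinations(range(5), 2):
                assert pdm.distance(taxa[f"T{i}"], taxa[f"T{j}"]) == pytest.approx(
                    D[i, j], abs=1e-9
                )
            seen.add(frozenset(_splits(tree)))
        assert len(seen) == 15  # every labeled topology distinguished

    def test_three_taxon_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        tree = nj_tree(D, ["a", "b", "c"])
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx(0.5)   # (2 + 3 - 4) / 2
        assert lengths["b"] == pytest.approx(1.5)
        assert lengths["c"] == pytest.approx(2.5)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(7)
        top = _enumerate_five_taxon_trees()[4]
        D = _additive_matrix(top["edges"], rng.uniform(0.5, 2, len(top["edges"])), 5)
        labels = [f"T{i}" for i in range(5)]
        t1 = nj_tree(D, labels)
        perm = [3, 1, 4, 0, 2]
        t2 = nj_tree(D[np.ix_(perm, perm)], [labels[i] for i in perm])
        assert _splits(t1) == _splits(t2)

    def test_agrees_with_library_nj_on_additive_input(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(3)
        top = _enumerate_five_taxon_trees()[9]
        D = _additive_matrix(top["edges"], rng.uniform(0.5, 2, len(top["edges"])), 5)
        labels = [f"T{i}" for i in range(5)]
        ours = _splits(nj_tree(D, labels))
        sk = skbio_nj(DistanceMatrix(D, ids=labels))
        tns = dendropy.TaxonNamespace(labels)
        theirs = _splits(
            dendropy.Tree.get(data=str(sk), schema="newick", taxon_namespace=tns)
        )
        assert ours == theirs

    def test_input_validation(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"])  # asymmetric
        with pytest.raises(ValueError):
            nj_tree(np.array([[0.0, np.nan], [np.nan, 0.0]]), ["a", "b"])


class TestRooting:
    def _tree(self):
        D = np.array(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 2], [8, 8, 2, 0]], float
        )
        return nj_tree(D, ["m1", "m2", "w1", "w2"])

    def test_clean_bipartition_mixing_zero(self):
        groups = {"m1": "max", "m2": "max", "w1": "soja", "w2": "soja"}
        res = snp_phylo.root_between_groups(self._tree(), groups)
        assert res.mixing_count == 0
        assert res.tree.is_rooted
        kids = res.tree.seed_node.child_nodes()
        sides = [
            {lf.taxon.label for lf in k.leaf_iter()} for k in kids
        ]
        assert {frozenset(s) for s in sides} == {
            frozenset({"m1", "m2"}), frozenset({"w1", "w2"})
        }

    def test_one_stray_leaf_counts_as_mixing(self):
        # two clean 3-leaf clusters, but m2 (inside the first cluster) is
        # labeled with the other group: no single branch separates the
        # groups, and the best branch leaves exactly one leaf stranded
        labels = ["m1", "m2", "m3", "w1", "w2", "w3"]
        D = np.full((6, 6), 8.0)
        D[:3, :3] = 2.0
        D[3:, 3:] = 2.0
        np.fill_diagonal(D, 0.0)
        tree = nj_tree(D, labels)
        groups = {"m1": "max", "m2": "soja", "m3": "max",
                  "w1": "soja", "w2": "soja", "w3": "soja"}
        res = snp_phylo.root_between_groups(tree, groups)
        assert res.mixing_count == 1

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            snp_phylo.root_between_groups(self._tree(), {"m1": "max", "m2": "max"})

    def test_newick_roundtrip(self):
        res = snp_phylo.root_between_groups(
            self._tree(), {"m1": "max", "m2": "max", "w1": "soja", "w2": "soja"}
        )
        text = res.tree.as_string(schema="newick")
        back = dendropy.Tree.get(data=text, schema="newick")
        assert {l.taxon.label for l in back.leaf_node_iter()} == {"m1", "m2", "w1", "w2"}

    def test_synthetic_populations_separate_cleanly(self):
        from germpanel.synthetic import SimConfig, simulate_panel

        cfg = SimConfig(
            seed=5, n_pops=2, n_per_pop=8, n_chrom=1, chrom_len_bp=500_000,
            n_sites_per_chrom=300, divergence=0.5, n_mislabels=0, n_duplicates=0,
            missing_rate=0.0,
        )
        panel, truth = simulate_panel(cfg)
        aln = snp_phylo.panel_to_alignment(panel)
        D, _ = p_distance_matrix(aln)
        tree = nj_tree(D, aln.labels)
        res = snp_phylo.root_between_groups(tree, truth.species_map())
        assert res.mixing_count == 0


class TestOriginTags:
    def test_tag_and_roundtrip(self):
        aln = SNPAlignment(labels=["PI483463", "PI999999"], seqs=["AC", "GT"])
        tagged, mapping = snp_phylo.label_with_origin(
            aln, {"PI483463": "China"}
        )
        assert tagged.labels == ["PI483463|China", "PI999999|NA"]
        assert snp_phylo.unlabel(tagged, mapping).labels == aln.labels

    def test_tree_tagging_does_not_mutate_original(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        tree = nj_tree(D, ["a", "b", "c"])
        tagged, mapping = snp_phylo.label_with_origin(tree, {"a": "Japan"})
        assert {t.label for t in tagged.taxon_namespace} == {"a|Japan", "b|NA", "c|NA"}
        assert {t.label for t in tree.taxon_namespace} == {"a", "b", "c"}
        back = snp_phylo.unlabel(tagged, mapping)
        assert {t.label for t in back.taxon_namespace} == {"a", "b", "c"}
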