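import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from pcevol.core_io import as_alignment
from pcevol.phylogeny import (
    PhylogenyError,
    bootstrap_support,
    concatenate_alignments,
    neighbor_joining,
    root_with_outgroup,
    tree_from_newick,
    tree_to_newick,
)
from pcevol.synthetic import SynthConfig, simulate_polycistron_alignment


def _tree_distances(newick):
    """Leaf-to-leaf path-length matrix of a newick tree, as a DataFrame."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(t.label for t in tree.taxon_namespace)
    tns = tree.taxon_namespace
    mat = [
        [0.0 if a == b else pdm.distance(tns.get_taxon(a), tns.get_taxon(b)) for b in taxa]
        for a in taxa
    ]
    return pd.DataFrame(mat, index=taxa, columns=taxa)


def _path_matrix(tree, taxa):
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    return np.array(
        [
            [0.0 if a == b else pdm.distance(tns.get_taxon(a), tns.get_taxon(b)) for b in taxa]
            for a in taxa
        ]
    )


def _bipartition_set(tree):
    tree.encode_bipartitions()
    return {
        e.bipartition.split_bitmask
        for e in tree.preorder_edge_iter()
        if e.head_node is not tree.seed_node and not e.head_node.is_leaf()
    }


class TestNeighborJoining:
    def test_additive_five_taxon_matrix_recovered_exactly(self):
        dm = _tree_distances("((A:1,B:2):1.5,(C:0.5,D:1):2,E:3);")
        tree = neighbor_joining(dm)
        recovered = _path_matrix(tree, list(dm.index))
        assert np.allclose(recovered, dm.to_numpy(), atol=1e-9)

    def test_three_taxa_closed_form(self):
        dm = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=list("ABC"), columns=list("ABC")
        )
        tree = neighbor_joining(dm)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_four_taxon_topology_matches_minimum_evolution_oracle(self):
        """NJ picks the same quartet topology as exhaustive least-squares
        fitting over all three resolved quartets."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            # random additive quartet with an internal edge
            a, b, c, d, m = rng.uniform(0.2, 2.0, size=5)
            dm = pd.DataFrame(
                [
                    [0, a + b, a + m + c, a + m + d],
                    [a + b, 0, b + m + c, b + m + d],
                    [a + m + c, b + m + c, 0, c + d],
                    [a + m + d, b + m + d, c + d, 0],
                ],
                index=list("ABCD"),
                columns=list("ABCD"),
            )
            tree = neighbor_joining(dm)
            # oracle: the true split is AB|CD by construction, so the
            # four-point condition identifies it; check NJ found it
            bip = _bipartition_set(tree)
            expected_tree = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
            expected_tree.migrate_taxon_namespace(tree.taxon_namespace)
            assert bip == _bipartition_set(expected_tree)

    def test_random_additive_trees_recovered(self):
        rng = np.random.default_rng(1)
        for n_taxa in (4, 5, 6):
            labels = [chr(65 + i) for i in range(n_taxa)]
            # random caterpillar tree with random positive lengths
            parts = [f"{labels[0]}:{rng.uniform(0.1, 1):.4f}"]
            nested = f"({labels[1]}:{rng.uniform(0.1, 1):.4f},{labels[2]}:{rng.uniform(0.1, 1):.4f})"
            for lab in labels[3:]:
                nested = f"({nested}:{rng.uniform(0.1, 1):.4f},{lab}:{rng.uniform(0.1, 1):.4f})"
            newick = f"({parts[0]},{nested}:0.0);"
            dm = _tree_distances(newick)
            tree = neighbor_joining(dm)
            assert np.allclose(
                _path_matrix(tree, list(dm.index)), dm.to_numpy(), atol=1e-9
            )

    def test_matches_independent_nj_implementation(self):
        """Cross-check against scikit-bio's neighbor joining."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(2)
        n = 6
        base = rng.uniform(0.1, 1.0, size=(n, n))
        mat = (base + base.T) / 2
        np.fill_diagonal(mat, 0)
        ids = [f"t{i}" for i in range(n)]
        ours = neighbor_joining(pd.DataFrame(mat, index=ids, columns=ids))
        theirs_nwk = skbio.tree.nj(
            skbio.DistanceMatrix(mat, ids)
        ).write([])  # newick string list-free form
        theirs = tree_from_newick("".join(theirs_nwk))
        theirs.migrate_taxon_namespace(ours.taxon_namespace)
        theirs.encode_bipartitions()
        assert _bipartition_set(ours) == _bipartition_set(theirs)

    def test_invariant_under_taxon_permutation(self):
        dm = _tree_distances("((A:1,B:2):1.5,(C:0.5,D:1):2,E:3);")
        perm = ["C", "E", "A", "D", "B"]
        t1 = neighbor_joining(dm)
        t2 = neighbor_joining(dm.loc[perm, perm])
        t2.migrate_taxon_namespace(t1.taxon_namespace)
        assert _bipartition_set(t1) == _bipartition_set(t2)

    def test_asymmetric_matrix_rejected(self):
        dm = pd.DataFrame(
            [[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], index=list("ABC"), columns=list("ABC")
        )
        with pytest.raises(PhylogenyError, match="symmetric"):
            neighbor_joining(dm)


@pytest.fixture(scope="module")
def variable_alignment():
    sim = simulate_polycistron_alignment(
        SynthConfig(
            tree="star:6",
            region_lengths=(0, 107, 0, 85, 0),
            region_rates=(0, 0.1, 0, 0.1, 0),
            seed=11,
        )
    )
    return sim.alignment


class TestBootstrap:
    def test_same_seed_reproduces_supports(self, variable_alignment):
        b1 = bootstrap_support(variable_alignment, n_replicates=25, seed=9)
        b2 = bootstrap_support(variable_alignment, n_replicates=25, seed=9)
        labels = lambda t: [n.label for n in t.preorder_node_iter() if n.label]
        assert labels(b1.tree) == labels(b2.tree)

    def test_identical_sequences_flagged_degenerate(self):
        aln = as_alignment(["ACGUACGUAC"] * 4)
        with pytest.warns(UserWarning, match="no variation"):
            res = bootstrap_support(aln, n_replicates=10, seed=0)
        assert res.degenerate
        labels = [n.label for n in res.tree.preorder_node_iter() if n.label]
        assert all(l == "0" for l in labels)

    def test_clear_structure_gets_high_support(self):
        """Two deeply separated clades should be supported in nearly every
        replicate."""
        rng = np.random.default_rng(3)
        core = "".join(rng.choice(list("ACGU"), size=200))
        other = "".join(
            {"A": "C", "C": "A", "G": "U", "U": "G"}[c] if rng.random() < 0.4 else c
            for c in core
        )
        def tweak(s, k):
            out = list(s)
            idx = rng.choice(len(s), size=k, replace=False)
            for i in idx:
                out[i] = str(rng.choice([b for b in "ACGU" if b != out[i]]))
            return "".join(out)
        aln = as_alignment(
            [core, tweak(core, 4), tweak(core, 4), other, tweak(other, 4), tweak(other, 4)],
            ids=[f"s{i}" for i in range(6)],
        )
        res = bootstrap_support(aln, n_replicates=100, seed=5)
        supports = [
            float(n.label) for n in res.tree.preorder_node_iter() if n.label
        ]
        assert max(supports) >= 90


class TestRooting:
    def test_single_taxon_outgroup_roots_on_pendant_edge(self):
        tree = neighbor_joining(_tree_distances("((A:1,B:2):1.5,(C:0.5,D:1):2,E:3);"))
        rooted = root_with_outgroup(tree, ["E"])
        children = rooted.seed_node.child_nodes()
        sides = [
            {lf.taxon.label for lf in c.leaf_iter()} for c in children
        ]
        assert {"E"} in sides

    def test_outgroup_cherry_roots_on_stem(self):
        tree = neighbor_joining(_tree_distances("((A:1,B:2):1.5,(C:0.5,D:1):2,E:3);"))
        rooted = root_with_outgroup(tree, ["C", "D"])
        sides = [
            {lf.taxon.label for lf in c.leaf_iter()}
            for c in rooted.seed_node.child_nodes()
        ]
        assert {"C", "D"} in sides

    def test_non_monophyletic_outgroup_rejected(self):
        tree = neighbor_joining(_tree_distances("((A:1,B:2):1.5,(C:0.5,D:1):2,E:3);"))
        with pytest.raises(PhylogenyError, match="monophyletic"):
            root_with_outgroup(tree, ["A", "C"])


class TestConcatenate:
    def test_widths_add_up(self):
        a = as_alignment(["ACGUA", "ACGUC"], ids=["x", "y"])
        b = as_alignment(["GGGUACC", "GGGUACG"], ids=["x", "y"])
        cat = concatenate_alignments([a, b])
        assert cat.n_columns == 12

    def test_fill_policy_pads_missing_taxa_with_gaps(self):
        a = as_alignment(["ACGUA", "ACGUC"], ids=["x", "y"])
        b = as_alignment(["GGG", "CCC"], ids=["x", "z"])
        cat = concatenate_alignments([a, b], policy="fill")
        assert cat["y"].residues == "ACGUC---"
        assert cat["z"].residues == "-----CCC"

    def test_intersect_policy_with_disjoint_taxa_errors(self):
        a = as_alignment(["ACGU", "ACGA"], ids=["x", "y"])
        b = as_alignment(["GGGG", "CCCC"], ids=["p", "q"])
        with pytest.raises(PhylogenyError):
            concatenate_alignments([a, b], policy="intersect")


def test_newick_roundtrip_preserves_topology_lengths_and_supports():
    sim = simulate_polycistron_alignment(
        SynthConfig(
            tree="star:5",
            region_lengths=(0, 107, 0, 0, 0),
            region_rates=(0, 0.1, 0, 0, 0),
            seed=8,
        )
    )
    res = bootstrap_support(sim.alignment, n_replicates=20, seed=1)
    nwk = tree_to_newick(res.tree)
    back = tree_from_newick(nwk)
    back.migrate_taxon_namespace(res.tree.taxon_namespace)
    assert _bipartition_set(back) == _bipartition_set(res.tree)
    assert sorted(n.label for n in back.preorder_node_iter() if n.label) == sorted(
        n.label for n in res.tree.preorder_node_iter() if n.label
    )
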