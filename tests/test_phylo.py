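"""Distances, neighbor-joining, bootstrap, clade purity."""

import math

import numpy as np
import pytest

from rdnarip import phylo
from rdnarip import synthetic as syn


# --- independent oracle: random additive trees ------------------------------

def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random unrooted binary tree; returns (distance matrix, bipartitions)."""
    ids = [f"t{i}" for i in range(n_leaves)]
    # grow by random edge attachment on a path metric held in a graph
    import itertools

    import networkx as nx

    g = nx.Graph()
    g.add_edge(ids[0], ids[1], weight=float(rng.uniform(0.05, 1.0)))
    inner = 0
    for leaf in ids[2:]:
        u, v = list(g.edges())[rng.integers(g.number_of_edges())]
        w = g[u][v]["weight"]
        mid = f"x{inner}"
        inner += 1
        g.remove_edge(u, v)
        a = float(rng.uniform(0.05, 1.0)) * w / max(w, 1e-9)
        g.add_edge(u, mid, weight=max(0.05, w * 0.5))
        g.add_edge(mid, v, weight=max(0.05, w * 0.5))
        g.add_edge(mid, leaf, weight=float(rng.uniform(0.05, 1.0)))
    d = np.zeros((n_leaves, n_leaves))
    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    for i, j in itertools.combinations(range(n_leaves), 2):
        d[i, j] = d[j, i] = paths[ids[i]][ids[j]]
    # true bipartitions: removing each internal edge splits the leaves
    anchor = min(ids)
    bips = set()
    for u, v in g.edges():
        h = g.copy()
        h.remove_edge(u, v)
        import networkx as nxx

        comp = nxx.node_connected_component(h, u)
        side = frozenset(x for x in comp if x in ids)
        if len(side) < 2 or len(side) > n_leaves - 2:
            continue
        if anchor in side:
            side = frozenset(ids) - side
        bips.add(side)
    return phylo.DistanceMatrix(ids, d, "p", "pairwise"), bips


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected,sites",
        [
            ("ACGT", "ACGA", 0.25, 4),
            ("ACGT", "ACGT", 0.0, 4),
            ("AC-T", "ACGT", 0.0, 3),
        ],
    )
    def test_values(self, a, b, expected, sites):
        d, n = phylo.p_distance(a, b)
        assert d == expected and n == sites

    def test_complete_deletion_uses_alignment_mask(self):
        aln = {"a": "ACGT", "b": "ACGA", "c": "AC-T"}
        mask = phylo.complete_deletion_mask(aln)
        d, n = phylo.p_distance(aln["a"], aln["b"], "complete", mask)
        assert n == 3 and d == pytest.approx(1 / 3)

    def test_undefined_when_no_overlap(self):
        d, n = phylo.p_distance("A--", "-CC")
        assert math.isnan(d) and n == 0


class TestK2P:
    def test_zero_distance(self):
        assert phylo.k2p_distance("ACGT", "ACGT") == 0.0

    def test_closed_form_p01_q005(self):
        # 20 sites: 2 transitions (A->G), 1 transversion (A->C)
        ref = "A" * 20
        qry = "GG" + "C" + "A" * 17
        d = phylo.k2p_distance(qry, ref)
        assert d == pytest.approx(0.170182, abs=1e-6)

    def test_closed_form_single_transition(self):
        # one transition over 4 sites: P=0.25 -> d = -0.5 ln(0.5)
        d = phylo.k2p_distance("GCGT", "ACGT")
        assert d == pytest.approx(0.346574, abs=1e-6)

    def test_saturation_flagged_as_nan(self):
        # all transitions: P=1 -> log argument <= 0
        assert math.isnan(phylo.k2p_distance("GGGG", "AAAA"))

    def test_k2p_at_least_p_distance(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), 200))
            b = "".join(rng.choice(list("ACGT"), 200))
            dk = phylo.k2p_distance(a, b)
            dp, _ = phylo.p_distance(a, b)
            if not math.isnan(dk):
                assert dk >= dp - 1e-12


class TestAveragePDistance:
    def test_identical_pair(self):
        assert phylo.average_p_distance({"a": "ACGT", "b": "ACGT"}) == 0.0

    def test_mean_over_pairs(self):
        # three sequences engineered to give pairwise distances 0.1/0.2/0.3
        base = "A" * 10
        aln = {"a": base, "b": "G" + base[1:], "c": "CCC" + base[3:]}
        # a-b: 1 diff, a-c: 3 diffs, b-c: 3 diffs -> mean (0.1+0.3+0.3)/3
        assert phylo.average_p_distance(aln) == pytest.approx((0.1 + 0.3 + 0.3) / 3)

    def test_needs_two(self):
        with pytest.raises(ValueError):
            phylo.average_p_distance({"a": "ACGT"})


class TestNJ:
    def test_four_taxon_additive_exact(self):
        ids = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 0, 0],
            ],
            dtype=float,
        )
        d[3, 2] = d[2, 3] = 7
        dm = phylo.DistanceMatrix(ids, d, "p", "pairwise")
        tree = phylo.nj_tree(dm)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        lengths = {n.name: n.length for n in tree.root.leaves()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)
        assert lengths["D"] == pytest.approx(4.0)

    def test_three_taxon_star_exact(self):
        ids = ["A", "B", "C"]
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = phylo.nj_tree(phylo.DistanceMatrix(ids, d, "p", "pairwise"))
        lengths = {n.name: n.length for n in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 0.0, "B": 2.0, "C": 3.0})

    def test_recovers_random_additive_topologies(self):
        """NJ on additive matrices returns the generating topology."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            dm, true_bips = random_additive_tree(n, rng)
            tree = phylo.nj_tree(dm)
            assert tree.bipartitions() == true_bips

    def test_matches_skbio_on_noisy_matrix(self):
        """Cross-check against an independent NJ implementation."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(11)
        dm, _ = random_additive_tree(7, rng)
        noisy = dm.d + rng.uniform(0, 0.01, dm.d.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        ours = phylo.nj_tree(phylo.DistanceMatrix(dm.ids, noisy, "p", "pairwise"))
        sk_tree = skbio_nj(SkbioDM(noisy, dm.ids))
        anchor = min(dm.ids)
        sk_bips = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(dm.ids) - 2:
                if anchor in side:
                    side = frozenset(dm.ids) - side
                sk_bips.add(side)
        assert ours.bipartitions() == sk_bips

    def test_saturated_entries_named_in_error(self):
        aln = {"a": "AAAA", "b": "GGGG", "c": "AAAC"}
        dm = phylo.distance_matrix(aln, "k2p")
        with pytest.raises(ValueError, match="a.*b"):
            phylo.nj_tree(dm)

    def test_newick_roundtrip(self):
        rng = np.random.default_rng(13)
        dm, _ = random_additive_tree(6, rng)
        tree = phylo.nj_tree(dm)
        again = phylo.parse_newick(tree.newick())
        assert again.leaf_names() == tree.leaf_names()
        assert again.bipartitions() == tree.bipartitions()


def _two_clade_alignment(n_each=5, rip=0.28, seed=2):
    """Functional copies (identical) vs independently RIPped pseudogenes."""
    t = syn.generate_reference_unit({"18S": 1800}, {"18S": 0.48}, rng_seed=seed)
    params = syn.RipParams(
        context_rates=dict.fromkeys(syn.RIP_CONTEXTS, rip), background_rate=0.0
    )
    aln = {}
    labels = {}
    rng = np.random.default_rng(seed)
    for i in range(n_each):
        aln[f"f{i}"] = t.sequence
        labels[f"f{i}"] = "functional"
        out, _ = syn.apply_rip(t.sequence, params, rng_seed=int(rng.integers(2**31)))
        aln[f"p{i}"] = out
        labels[f"p{i}"] = "pseudogene"
    return aln, labels


class TestBootstrap:
    def test_deterministic_for_fixed_seed(self):
        aln, _ = _two_clade_alignment(n_each=3)
        t1 = phylo.bootstrap_support(aln, n_replicates=20, rng_seed=5)
        t2 = phylo.bootstrap_support(aln, n_replicates=20, rng_seed=5)
        assert t1.newick() == t2.newick()

    def test_functional_pseudogene_split_strongly_supported(self):
        """Two well-separated synthetic clades: the separating bipartition
        is present with support >= 95 at 100 replicates."""
        aln, labels = _two_clade_alignment(n_each=5)
        tree = phylo.bootstrap_support(aln, n_replicates=100, rng_seed=3)
        func = frozenset(k for k, v in labels.items() if v == "functional")
        pseudo = frozenset(k for k, v in labels.items() if v == "pseudogene")
        bips = tree.bipartitions()
        assert func in bips or pseudo in bips
        supports = {}
        all_leaves = frozenset(aln)
        for node, clade in tree._edge_clades():
            side = clade if min(all_leaves) not in clade else all_leaves - clade
            if node.support is not None:
                supports[side] = node.support
        split = func if func in supports else pseudo
        assert supports[split] >= 95

    def test_supports_invariant_to_leaf_order(self):
        aln, _ = _two_clade_alignment(n_each=3)
        tree1 = phylo.bootstrap_support(aln, n_replicates=20, rng_seed=9)
        rev = dict(reversed(list(aln.items())))
        tree2 = phylo.bootstrap_support(rev, n_replicates=20, rng_seed=9)
        assert tree1.newick() == tree2.newick()


class TestCladePurity:
    def test_separating_tree(self):
        tree = phylo.parse_newick("((p1:1,p2:1):1,(f1:1,f2:1):1);")
        labels = {"p1": "pseudogene", "p2": "pseudogene",
                  "f1": "functional", "f2": "functional"}
        res = phylo.clade_purity(tree, labels)
        assert res == {"is_bipartition_separating": True, "best_split_impurity": 0}

    def test_intermixed_tree_impurity_one(self):
        tree = phylo.parse_newick("((p1:1,f1:1):1,(p2:1,f2:1):1);")
        labels = {"p1": "pseudogene", "p2": "pseudogene",
                  "f1": "functional", "f2": "functional"}
        res = phylo.clade_purity(tree, labels)
        assert not res["is_bipartition_separating"]
        assert res["best_split_impurity"] == 1

    def test_unlabeled_leaf_rejected(self):
        tree = phylo.parse_newick("((p1:1,p2:1):1,f1:1);")
        with pytest.raises(ValueError, match="unlabeled"):
            phylo.clade_purity(tree, {"p1": "pseudogene", "p2": "pseudogene"})

    def test_interspecies_clustering_of_pseudogenes(self):
        """Pseudogenes of two closely related simulated species intermix
        while the functional/pseudogene split holds."""
        anc = syn.generate_reference_unit({"18S": 1500}, {"18S": 0.48}, rng_seed=4)
        spA = anc.sequence
        spB = syn.diverge(anc.sequence, 0.005, rng_seed=5)  # closely related
        params = syn.RipParams(
            context_rates=dict.fromkeys(syn.RIP_CONTEXTS, 0.35), background_rate=0.0
        )
        aln, labels = {}, {}
        rng = np.random.default_rng(6)
        for sp, seq in (("A", spA), ("B", spB)):
            aln[f"f_{sp}"] = seq
            labels[f"f_{sp}"] = "functional"
            for i in range(3):
                out, _ = syn.apply_rip(seq, params, rng_seed=int(rng.integers(2**31)))
                aln[f"p_{sp}{i}"] = out
                labels[f"p_{sp}{i}"] = "pseudogene"
        tree = phylo.nj_tree(phylo.distance_matrix(aln, "k2p"))
        res = phylo.clade_purity(tree, labels)
        assert res["is_bipartition_separating"]
        # within the pseudogene clade, species do not both form pure clades
        all_leaves = frozenset(aln)
        pa = frozenset(k for k in aln if k.startswith("p_A"))
        pb = frozenset(k for k in aln if k.startswith("p_B"))
        clades = {c for _, c in tree._edge_clades()}
        clades |= {all_leaves - c for c in clades}
        assert pa not in clades or pb not in clades
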