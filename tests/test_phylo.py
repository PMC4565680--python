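"""NJ vs additive matrices and an independent library implementation,
midpoint rooting vs brute-force path enumeration, pruning likelihood vs
exhaustive ancestral-state summation, clade extraction."""

import itertools
import math

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from te_evoscan.evometrics import DistanceMatrix
from te_evoscan.phylo import (
    CladeGroup,
    Phylogeny,
    SubstitutionModel,
    bootstrap_support,
    canonical_bipartition,
    extract_supported_clades,
    gtr_gamma_loglik,
    midpoint_root,
    nj_tree,
)
from te_evoscan.records import CodonAlignment

# --- helpers ---------------------------------------------------------------


def random_tree_and_distances(n_leaves, rng):
    """A random binary tree with branch lengths and its additive matrix."""
    labels = [f"t{i}" for i in range(n_leaves)]
    nodes = {lab: {"children": [], "label": lab} for lab in labels}
    active = list(labels)
    counter = [0]
    lengths = {}
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[j], active[i]
        name = f"n{counter[0]}"
        counter[0] += 1
        nodes[name] = {"children": [a, b], "label": name}
        lengths[a] = rng.uniform(0.1, 1.0)
        lengths[b] = rng.uniform(0.1, 1.0)
        active = [x for x in active if x not in (a, b)] + [name]
    root = active[0]

    # leaf-to-leaf additive distances by path sums
    def leafset(x):
        ch = nodes[x]["children"]
        if not ch:
            return {x: 0.0}
        out = {}
        for c in ch:
            for leaf, d in leafset(c).items():
                out[leaf] = d + lengths[c]
        return out

    dists = {}

    def collect(x):
        ch = nodes[x]["children"]
        if not ch:
            return {x: 0.0}
        sub = [collect(c) for c in ch]
        for (c1, s1), (c2, s2) in itertools.combinations(zip(ch, sub), 2):
            for l1, d1 in s1.items():
                for l2, d2 in s2.items():
                    dists[tuple(sorted((l1, l2)))] = (
                        d1 + lengths[c1] + d2 + lengths[c2]
                    )
        merged = {}
        for c, s in zip(ch, sub):
            for leaf, d in s.items():
                merged[leaf] = d + lengths[c]
        return merged

    collect(root)
    D = np.zeros((n_leaves, n_leaves))
    for (l1, l2), d in dists.items():
        i, j = labels.index(l1), labels.index(l2)
        D[i, j] = D[j, i] = d

    def bipartitions(x, parent_set=None):
        out = set()

        def walk(y):
            ch = nodes[y]["children"]
            if not ch:
                return {y}
            s = set()
            for c in ch:
                sub = walk(c)
                if 1 < len(sub) < n_leaves - 1:
                    out.add(canonical_bipartition(sub, labels))
                s |= sub
            return s

        walk(x)
        return out

    return labels, D, bipartitions(root)


# --- NJ --------------------------------------------------------------------


def test_nj_three_taxa_closed_form():
    D = DistanceMatrix(ids=["a", "b", "c"], values=np.array(
        [[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]]
    ))
    phy = nj_tree(D)
    d = phy.leaf_distances()
    assert d[("a", "b")] == pytest.approx(0.4)
    assert d[("a", "c")] == pytest.approx(0.6)
    assert d[("b", "c")] == pytest.approx(0.8)


def test_nj_fewer_than_three_taxa_errors():
    with pytest.raises(ValueError, match="at least 3"):
        nj_tree(DistanceMatrix(ids=["a", "b"], values=np.array([[0, 1.0], [1.0, 0]])))


def test_nj_recovers_additive_trees_up_to_12_leaves():
    rng = np.random.default_rng(42)
    for rep in range(15):
        n = int(rng.integers(4, 13))
        labels, D, true_bips = random_tree_and_distances(n, rng)
        phy = nj_tree(DistanceMatrix(ids=labels, values=D))
        assert phy.bipartitions() == true_bips
        # branch lengths: recovered path lengths equal the additive input
        d = phy.leaf_distances()
        for i, l1 in enumerate(labels):
            for l2 in labels[i + 1 :]:
                assert d[tuple(sorted((l1, l2)))] == pytest.approx(
                    D[labels.index(l1), labels.index(l2)], abs=1e-9
                )


def test_nj_agrees_with_skbio_on_random_matrix():
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    rng = np.random.default_rng(3)
    labels, D, _ = random_tree_and_distances(8, rng)
    mine = nj_tree(DistanceMatrix(ids=labels, values=D))
    theirs = sk_nj(SkDM(D, ids=labels))
    their_bips = set()
    for node in theirs.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(labels) - 1:
            their_bips.add(canonical_bipartition(side, labels))
    assert mine.bipartitions() == their_bips


def test_nj_tie_break_reproducible():
    # perfectly symmetric 4-taxon matrix: every join is tied
    D = np.full((4, 4), 1.0)
    np.fill_diagonal(D, 0.0)
    ids = ["a", "b", "c", "d"]
    t1 = nj_tree(DistanceMatrix(ids=ids, values=D))
    t2 = nj_tree(DistanceMatrix(ids=ids, values=D))
    assert t1.as_newick() == t2.as_newick()
    assert t1.bipartitions() == {canonical_bipartition({"a", "b"}, ids)}


# --- midpoint rooting -------------------------------------------------------


def test_midpoint_two_leaves():
    phy = Phylogeny.from_newick("(A:0.5,B:1.5);")
    rooted = midpoint_root(phy)
    root = rooted.tree.seed_node
    kids = {c.taxon.label: c.edge.length for c in root.child_nodes()}
    assert kids["A"] == pytest.approx(1.0)
    assert kids["B"] == pytest.approx(1.0)


def test_midpoint_bisects_longest_path_brute_force():
    rng = np.random.default_rng(11)
    for rep in range(10):
        labels, D, _ = random_tree_and_distances(int(rng.integers(4, 10)), rng)
        phy = nj_tree(DistanceMatrix(ids=labels, values=D))
        before = phy.leaf_distances()
        longest = max(before.values())
        rooted = midpoint_root(phy)
        after = rooted.leaf_distances()
        for k, v in before.items():
            assert after[k] == pytest.approx(v, abs=1e-9)
        # root-to-leaf depth: max depth equals half the longest path
        depths = {}
        for leaf in rooted.tree.leaf_node_iter():
            depth, node = 0.0, leaf
            while node.parent_node is not None:
                depth += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = depth
        assert max(depths.values()) == pytest.approx(longest / 2, abs=1e-9)


def test_midpoint_balanced_tree_roots_at_center():
    phy = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    rooted = midpoint_root(phy)
    sides = [rooted.node_leafset(c) for c in rooted.tree.seed_node.child_nodes()]
    assert {frozenset({"A", "B"}), frozenset({"C", "D"})} == set(map(frozenset, sides))


# --- bootstrap --------------------------------------------------------------


def _two_cluster_alignment(rng, n_per=3, n_codons=40):
    from te_evoscan.simulate import simulate_codon_pair

    a, b = simulate_codon_pair(n_codons, divergence=1.0, omega=1.0, seed=9)
    recs = []
    for k in range(n_per):
        ga = list(a)
        gb = list(b)
        for s, g in ((ga, "x"), (gb, "y")):
            i = int(rng.integers(0, len(s)))
            s[i] = "ACGT"[int(rng.integers(0, 4))]
        recs.append((f"x{k}", "".join(ga)))
        recs.append((f"y{k}", "".join(gb)))
    return CodonAlignment(recs)


def test_bootstrap_deep_split_near_full_support():
    rng = np.random.default_rng(2)
    aln = _two_cluster_alignment(rng)
    phy = bootstrap_support(aln, n_reps=50, seed=7)
    split = canonical_bipartition({"x0", "x1", "x2"}, aln.ids)
    assert phy.support[split] >= 90.0


def test_bootstrap_single_rep_support_binary():
    rng = np.random.default_rng(4)
    aln = _two_cluster_alignment(rng)
    phy = bootstrap_support(aln, n_reps=1, seed=1)
    assert set(phy.support.values()) <= {0.0, 100.0}


def test_bootstrap_deterministic_given_seed():
    rng = np.random.default_rng(6)
    aln = _two_cluster_alignment(rng)
    s1 = bootstrap_support(aln, n_reps=20, seed=3).support
    s2 = bootstrap_support(aln, n_reps=20, seed=3).support
    assert s1 == s2


# --- likelihood -------------------------------------------------------------


def brute_force_loglik(aln, phy, model):
    """Sum over all ancestral state assignments, P(t) via scipy expm."""
    pi = np.array(model.base_freqs)
    q = model.rate_matrix()
    rates, weights = model.rate_categories()
    tree = phy.tree
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    seqs = dict(aln.records)
    total = 0.0
    for site in range(aln.n_sites):
        site_like = 0.0
        for rate, weight in zip(rates, weights):
            pmat = {
                n: expm(q * rate * (n.edge.length or 0.0))
                for n in tree.preorder_node_iter()
                if n.parent_node is not None
            }
            like = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                states = dict(zip(internals, assign))
                prob = pi[states[tree.seed_node]]
                for n in tree.preorder_node_iter():
                    if n.parent_node is None:
                        continue
                    parent_state = states[n.parent_node]
                    if n.is_leaf():
                        ch = seqs[n.taxon.label][site].upper()
                        if ch in idx:
                            prob *= pmat[n][parent_state, idx[ch]]
                    else:
                        prob *= pmat[n][parent_state, states[n]]
                like += prob
            site_like += weight * like
        total += math.log(site_like)
    return total


def test_loglik_identical_pair_zero_branch_closed_form():
    aln = CodonAlignment([("A", "AAA"), ("B", "AAA")])
    phy = Phylogeny.from_newick("(A:0.0,B:0.0);")
    assert gtr_gamma_loglik(aln, phy) == pytest.approx(3 * math.log(0.25))


def test_loglik_two_taxon_jc_closed_form():
    d = 0.3
    phy = Phylogeny.from_newick(f"(A:{d/2},B:{d/2});")
    p_same = 0.25 + 0.75 * math.exp(-4 * d / 3)
    p_diff = (1 - p_same) / 3
    aln = CodonAlignment([("A", "ACG"), ("B", "ACT")])
    expected = 2 * math.log(0.25 * p_same) + math.log(0.25 * p_diff)
    assert gtr_gamma_loglik(aln, phy) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "model",
    [
        SubstitutionModel(),
        SubstitutionModel(
            exchangeabilities=(1.2, 3.0, 0.8, 1.1, 3.5, 1.0),
            base_freqs=(0.3, 0.2, 0.2, 0.3),
            gamma_shape=0.7,
        ),
        SubstitutionModel(gamma_shape=1.2, p_invariant=0.2),
    ],
    ids=["jc", "gtr_gamma", "gtr_gamma_inv"],
)
def test_pruning_equals_brute_force_enumeration(model):
    rng = np.random.default_rng(13)
    labels, D, _ = random_tree_and_distances(5, rng)
    phy = nj_tree(DistanceMatrix(ids=labels, values=D * 0.2))
    chars = "ACGT-N"
    recs = [
        (lab, "".join(rng.choice(list(chars), p=[0.22, 0.22, 0.22, 0.22, 0.06, 0.06], size=9)))
        for lab in labels
    ]
    aln = CodonAlignment(recs)
    mine = gtr_gamma_loglik(aln, phy, model)
    brute = brute_force_loglik(aln, phy, model)
    assert mine == pytest.approx(brute, abs=1e-9)


def test_loglik_invariant_to_rerooting():
    rng = np.random.default_rng(17)
    labels, D, _ = random_tree_and_distances(6, rng)
    phy = nj_tree(DistanceMatrix(ids=labels, values=D * 0.1))
    recs = [(lab, "".join(rng.choice(list("ACGT"), size=12))) for lab in labels]
    aln = CodonAlignment(recs)
    model = SubstitutionModel(gamma_shape=0.9)
    base = gtr_gamma_loglik(aln, phy, model)
    rooted = midpoint_root(phy)
    assert gtr_gamma_loglik(aln, rooted, model) == pytest.approx(base, abs=1e-9)


def test_loglik_leaf_mismatch_errors():
    aln = CodonAlignment([("A", "AAA"), ("B", "AAA")])
    phy = Phylogeny.from_newick("(A:0.1,C:0.1);")
    with pytest.raises(ValueError, match="mismatch"):
        gtr_gamma_loglik(aln, phy)


# --- supported clades -------------------------------------------------------


def _phy_with_support(newick, support, rooted=False):
    phy = Phylogeny.from_newick(newick, rooted=rooted)
    labels = phy.leaf_labels
    phy.support = {
        canonical_bipartition(side, labels): val for side, val in support.items()
    }
    return phy


def test_extract_single_supported_cherry():
    phy = _phy_with_support(
        "((A:1,B:1):1,(C:1,D:1):1,E:2);",
        {frozenset({"A", "B"}): 100.0, frozenset({"C", "D"}): 60.0},
    )
    groups = extract_supported_clades(phy, threshold=80)
    assert len(groups) == 1
    assert groups[0].member_ids == frozenset({"A", "B"})
    assert groups[0].support == 100.0


def test_extract_no_clades_below_threshold():
    phy = _phy_with_support(
        "((A:1,B:1):1,(C:1,D:1):1,E:2);",
        {frozenset({"A", "B"}): 79.0, frozenset({"C", "D"}): 80.0},
    )
    assert extract_supported_clades(phy, threshold=80) == []  # strict >


def test_extract_nested_clades_reported_under_maximal():
    # explicitly rooted with a trifurcating root, so F stays outside both groups
    phy = _phy_with_support(
        "(((A:1,B:1):1,C:1):1,(D:1,E:1):1,F:3);",
        {
            frozenset({"A", "B"}): 95.0,
            frozenset({"A", "B", "C"}): 90.0,
            frozenset({"D", "E"}): 85.0,
        },
        rooted=True,
    )
    groups = extract_supported_clades(phy, threshold=80)
    by_members = {g.member_ids: g for g in groups}
    assert frozenset({"A", "B", "C"}) in by_members
    assert by_members[frozenset({"A", "B", "C"})].nested_supports == [95.0]
    assert frozenset({"D", "E"}) in by_members
    assert frozenset({"A", "B"}) not in by_members
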