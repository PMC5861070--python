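import numpy as np
import pytest
from scipy import stats as sps

from domainevol.phylo import (
    DistanceMatrix,
    PhyloError,
    bootstrap_supports,
    distance_matrix,
    jtt_distance,
    jtt_model,
    nj_tree,
    tree_loglik,
)
from domainevol.seqio import Alignment, SequenceRecord, parse_newick, node_support
from oracles import grid_search_distance

AA = "ARNDCQEGHILKMFPSTWYV"


def simulate_pair(model, t, n_sites, seed):
    """Ancestor from the stationary distribution, descendant via P(t)."""
    rng = np.random.default_rng(seed)
    pi = model.frequencies
    anc = rng.choice(20, size=n_sites, p=pi)
    p = model.transition_matrix(t)
    cdf = np.cumsum(p, axis=1)
    u = rng.random(n_sites)
    dec = (u[:, None] < cdf[anc]).argmax(axis=1)
    to_str = np.array(list(AA))
    return "".join(to_str[anc]), "".join(to_str[dec])


def test_transition_matrix_rows_sum_to_one(jtt):
    for t in (0.01, 0.1, 1.0, 5.0):
        p = jtt.transition_matrix(t)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
    assert np.allclose(jtt.transition_matrix(0.0), np.eye(20), atol=1e-12)


def test_detailed_balance(jtt):
    pi, q = jtt.frequencies, jtt.rate_matrix
    assert np.allclose(pi[:, None] * q, (pi[:, None] * q).T, atol=1e-12)


def test_identical_sequences_return_lower_bound(jtt):
    seq = "ARNDCQEGHILKMFPSTWYV" * 3
    est = jtt_distance(seq, seq, jtt)
    assert est.distance <= 1e-6 and not est.saturated


def test_ml_distance_matches_grid_search(jtt):
    a, b = simulate_pair(jtt, t=0.3, n_sites=100, seed=42)
    counts = np.zeros((20, 20))
    ia = jtt.encode(a)
    ib = jtt.encode(b)
    np.add.at(counts, (ia, ib), 1.0)
    t_grid = grid_search_distance(counts, jtt, step=1e-4)
    est = jtt_distance(a, b, jtt)
    assert est.distance == pytest.approx(t_grid, abs=1e-3)


def test_saturated_pair_flagged(jtt):
    a = "A" * 60
    b = "W" * 60
    assert jtt_distance(a, b, jtt).saturated


def test_alphabet_violation(jtt):
    with pytest.raises(PhyloError, match="alphabet"):
        jtt_distance("AX", "AA", jtt)


def test_nj_three_taxon_closed_form():
    d = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
    tree = nj_tree(d)
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths == {"A": 0.5, "B": 1.5, "C": 2.5}


def test_nj_recovers_additive_four_taxon_tree():
    # tree ((A:1,B:2):1,(C:3,D:4)): additive distances
    ids = ["A", "B", "C", "D"]
    mat = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
    )
    tree = nj_tree(DistanceMatrix(ids, mat))
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                mat[ids.index(a), ids.index(b)], abs=1e-9
            )
    # AB|CD split present
    splits = [
        frozenset(l.taxon.label for l in n.leaf_iter())
        for n in tree.preorder_internal_node_iter()
    ]
    assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits


def test_nj_star_tree_zero_internal_branches():
    ids = list("ABCD")
    mat = np.ones((4, 4)) - np.eye(4)
    tree = nj_tree(DistanceMatrix(ids, mat))
    for node in tree.preorder_internal_node_iter():
        if node is not tree.seed_node and node.edge.length is not None:
            assert node.edge.length == pytest.approx(0.0, abs=1e-12)


def test_nj_needs_three_taxa():
    with pytest.raises(PhyloError):
        nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))


def two_block_alignment():
    b1 = "ARNDCQEGHILKMFPSTWYV" * 2
    b2 = "VYWTSPFMKLIHGEQCDNRA" * 2
    return Alignment(
        [
            SequenceRecord("A1", b1),
            SequenceRecord("A2", b1),
            SequenceRecord("B1", b2),
            SequenceRecord("B2", b2),
        ]
    )


def test_bootstrap_perfect_split_support(jtt):
    tree = bootstrap_supports(two_block_alignment(), n_reps=100, seed=3, model=jtt)
    supports = [
        node_support(n)
        for n in tree.preorder_internal_node_iter()
        if n is not tree.seed_node
    ]
    assert supports == [100]


def test_bootstrap_single_rep_supports_binary(jtt):
    tree = bootstrap_supports(two_block_alignment(), n_reps=1, seed=5, model=jtt)
    for n in tree.preorder_internal_node_iter():
        if n is not tree.seed_node:
            assert node_support(n) in (0, 100)


def test_bootstrap_deterministic_under_seed(jtt, sim_family):
    from domainevol.filtering import complete_deletion
    from domainevol.seqio import tree_to_newick

    aln = complete_deletion(sim_family.protein_alignment).alignment
    sub = aln.subset(aln.ids[:6])
    t1 = bootstrap_supports(sub, n_reps=20, seed=9, model=jtt)
    t2 = bootstrap_supports(sub, n_reps=20, seed=9, model=jtt)
    assert tree_to_newick(t1) == tree_to_newick(t2)


def test_loglik_zero_branch_single_column(jtt):
    tree = parse_newick("(X:0,Y:0);")
    aln = Alignment([SequenceRecord("X", "A"), SequenceRecord("Y", "A")])
    ll = tree_loglik(tree, aln, jtt)
    assert ll == pytest.approx(np.log(jtt.frequencies[0]), abs=1e-10)


def test_loglik_two_taxon_equals_pairwise_formula(jtt):
    a, b = simulate_pair(jtt, t=0.4, n_sites=50, seed=1)
    tree = parse_newick("(X:0.25,Y:0.15);")
    ll = tree_loglik(
        tree, Alignment([SequenceRecord("X", a), SequenceRecord("Y", b)]), jtt
    )
    p = jtt.transition_matrix(0.4)  # total path length
    pi = jtt.frequencies
    expected = sum(
        np.log(pi[jtt.encode(x)[0]] * p[jtt.encode(x)[0], jtt.encode(y)[0]])
        for x, y in zip(a, b)
    )
    assert ll == pytest.approx(expected, abs=1e-8)


def test_loglik_root_invariance_and_leaf_order(jtt):
    rng = np.random.default_rng(0)
    tree = parse_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.1):0.07);")
    to_str = np.array(list(AA))
    records = [
        SequenceRecord(x, "".join(to_str[rng.integers(0, 20, 30)]))
        for x in "ABCD"
    ]
    aln = Alignment(records)
    ll = tree_loglik(tree, aln, jtt)
    # reroot on an internal edge
    tree2 = parse_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.1):0.07);")
    node_c = [l for l in tree2.leaf_node_iter() if l.taxon.label == "C"][0]
    tree2.reroot_at_edge(node_c.edge, length1=0.1, length2=0.2)
    assert tree_loglik(tree2, aln, jtt) == pytest.approx(ll, abs=1e-8)
    # permuting leaf order in the alignment changes nothing
    aln_perm = Alignment(records[::-1])
    assert tree_loglik(tree, aln_perm, jtt) == pytest.approx(ll, abs=1e-10)


def test_loglik_label_mismatch(jtt):
    tree = parse_newick("(A:0.1,B:0.1);")
    aln = Alignment([SequenceRecord("A", "AA"), SequenceRecord("Z", "AA")])
    with pytest.raises(PhyloError, match="labels"):
        tree_loglik(tree, aln, jtt)


def test_distance_increases_with_divergence(jtt):
    levels = np.linspace(0.05, 2.0, 20)
    estimates = []
    for i, t in enumerate(levels):
        a, b = simulate_pair(jtt, t=float(t), n_sites=300, seed=100 + i)
        estimates.append(jtt_distance(a, b, jtt).distance)
    rho = sps.spearmanr(levels, estimates).statistic
    assert rho > 0.8
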