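"""Pruning likelihood, branch-length optimization and tree comparison."""

import itertools

import dendropy
import numpy as np
import pytest

import ratemix as rm
from ratemix.matrices import transition_probability_values
from ratemix.trees import TreeNode

from conftest import random_model


def brute_force_loglik(aln, tree, Q):
    """Exhaustive summation over all internal-node state assignments."""
    n = Q.alphabet.size
    nodes = tree.postorder()
    internal = [x for x in nodes if not x.is_leaf]
    leaves = {x.name: x for x in nodes if x.is_leaf}
    parent = {}
    for node in nodes:
        for c in node.children:
            parent[id(c)] = node
    coded = aln.encode(Q.alphabet)
    total = 0.0
    pmats = {id(x): transition_probability_values(Q, x.length)
             for x in nodes if x is not tree.root}
    for site in range(aln.n_sites):
        site_lik = 0.0
        leaf_states = {name: coded[aln.names.index(name), site] for name in leaves}
        for assignment in itertools.product(range(n), repeat=len(internal)):
            state_of = {id(node): s for node, s in zip(internal, assignment)}
            for name, node in leaves.items():
                state_of[id(node)] = leaf_states[name]
            prob = Q.frequencies.values[state_of[id(tree.root)]]
            for node in nodes:
                if node is tree.root:
                    continue
                s_child = state_of[id(node)]
                s_parent = state_of[id(parent[id(node)])]
                if s_child >= 0:  # missing leaf: sum_s P[parent, s] = 1
                    prob *= pmats[id(node)][s_parent, s_child]
            site_lik += prob
        total += np.log(site_lik)
    return total


def test_single_leaf_likelihood_is_root_prior(alpha4):
    _, pi, Q = random_model(alpha4, np.random.default_rng(0))
    aln = rm.Alignment(("x",), ("A",))
    tree = rm.PhyloTree(TreeNode("x"))
    res = rm.log_likelihood(aln, tree, Q)
    assert res.log_likelihood == pytest.approx(np.log(pi.values[0]), abs=1e-12)


@pytest.mark.parametrize("n_leaves,size,seed", [(3, 2, 0), (4, 4, 1), (5, 3, 2)])
def test_pruning_equals_exhaustive_enumeration(n_leaves, size, seed):
    rng = np.random.default_rng(seed)
    alphabet = rm.toy_alphabet(size)
    _, _, Q = random_model(alphabet, rng)
    tree = rm.random_tree(n_leaves, rng)
    aln = rm.simulate_alignment(rm.SimulationConfig(tree, Q, 3, seed=seed + 10))
    res = rm.log_likelihood(aln, tree, Q)
    assert res.log_likelihood == pytest.approx(brute_force_loglik(aln, tree, Q),
                                               abs=1e-10)


def test_likelihood_invariant_to_rerooting(small_dataset):
    aln, tree, Q = small_dataset
    base = rm.log_likelihood(aln, tree, Q).log_likelihood
    for e in range(len(tree.edges())):
        rerooted = tree.rerooted_at_edge(e)
        assert rm.log_likelihood(aln, rerooted, Q).log_likelihood == \
            pytest.approx(base, abs=1e-8)


def test_likelihood_invariant_to_leaf_permutation(small_dataset):
    aln, tree, Q = small_dataset
    base = rm.log_likelihood(aln, tree, Q).log_likelihood
    order = np.random.default_rng(0).permutation(len(aln.names))
    permuted = rm.Alignment(tuple(aln.names[i] for i in order),
                            tuple(aln.rows[i] for i in order))
    assert rm.log_likelihood(permuted, tree, Q).log_likelihood == \
        pytest.approx(base, abs=1e-10)


def test_all_missing_sequence_leaves_likelihood_unchanged(small_dataset):
    aln, tree, Q = small_dataset
    base = rm.log_likelihood(aln, tree, Q).log_likelihood
    grown = rm.PhyloTree(TreeNode(None, 0.0, [tree.copy().root,
                                              TreeNode("ghost", 0.3)]))
    aug = rm.Alignment(aln.names + ("ghost",), aln.rows + ("-" * aln.n_sites,))
    assert rm.log_likelihood(aug, grown, Q).log_likelihood == \
        pytest.approx(base, abs=1e-8)


def test_gamma_with_unit_rates_equals_single_rate(small_dataset):
    aln, tree, Q = small_dataset
    single = rm.log_likelihood(aln, tree, Q).log_likelihood
    # alpha -> infinity: all categories at rate 1, exactly the single-rate model
    flat = rm.GammaRateModel(alpha=np.inf, n_categories=4)
    assert rm.log_likelihood(aln, tree, Q, flat).log_likelihood == \
        pytest.approx(single, abs=1e-8)
    # large finite alpha approaches the same limit
    nearly_flat = rm.GammaRateModel(alpha=1e6, n_categories=4)
    assert rm.log_likelihood(aln, tree, Q, nearly_flat).log_likelihood == \
        pytest.approx(single, abs=1e-4)


def test_gamma_model_mean_rate_one():
    for alpha in (0.2, 0.7, 2.0, 10.0):
        g = rm.GammaRateModel(alpha)
        assert float(g.category_probs @ g.category_rates) == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(g.category_rates) > 0)


def test_per_site_values_sum_to_total(small_dataset):
    aln, tree, Q = small_dataset
    res = rm.log_likelihood(aln, tree, Q, rm.GammaRateModel(0.5))
    assert res.log_likelihood == pytest.approx(res.per_site_log_likelihoods.sum(),
                                               abs=1e-8)


def test_likelihood_name_mismatch_raises(small_dataset):
    aln, tree, Q = small_dataset
    bad = rm.Alignment(tuple(n + "_x" for n in aln.names), aln.rows)
    with pytest.raises(ValueError, match="names differ"):
        rm.log_likelihood(bad, tree, Q)


def test_branch_length_recovery_two_taxa(alpha4):
    _, _, Q = random_model(alpha4, np.random.default_rng(3), uniform_pi=True)
    true_t = 0.5
    tree = rm.PhyloTree(TreeNode(None, 0.0, [TreeNode("a", true_t / 2),
                                             TreeNode("b", true_t / 2)]))
    aln = rm.simulate_alignment(rm.SimulationConfig(tree, Q, 50_000, seed=21))
    start = tree.copy()
    for e in start.edges():
        e.length = 0.1
    fitted, _ = rm.optimize_branch_lengths(aln, start, Q)
    assert fitted.total_length() == pytest.approx(true_t, abs=0.05)


def test_identical_sequences_drive_branches_to_lower_bound(alpha4):
    _, _, Q = random_model(alpha4, np.random.default_rng(4))
    tree = rm.random_tree(4, np.random.default_rng(5))
    aln = rm.Alignment(tuple(tree.leaf_names()), ("AAAA",) * 4)
    fitted, _ = rm.optimize_branch_lengths(aln, tree, Q)
    assert all(e.length < 1e-4 for e in fitted.edges())


def test_branch_optimization_monotone_and_fixed_point(small_dataset):
    aln, tree, Q = small_dataset
    before = rm.log_likelihood(aln, tree, Q).log_likelihood
    fitted, res = rm.optimize_branch_lengths(aln, tree, Q)
    assert res.log_likelihood >= before
    _, res2 = rm.optimize_branch_lengths(aln, fitted, Q, tol=1e-6)
    assert res2.log_likelihood == pytest.approx(res.log_likelihood, abs=1e-3)


# -- Robinson-Foulds -------------------------------------------------------

def test_rf_identical_topologies_zero():
    t1 = rm.PhyloTree.from_newick("((a:1,b:2):1,(c:3,d:4):2);")
    t2 = rm.PhyloTree.from_newick("((a:9,b:1):5,(c:1,d:1):1);")
    assert rm.robinson_foulds(t1, t2) == 0


def test_rf_distinct_quartets_is_two():
    t1 = rm.PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
    t2 = rm.PhyloTree.from_newick("((a:1,c:1):1,(b:1,d:1):1);")
    assert rm.robinson_foulds(t1, t2) == 2
    assert rm.robinson_foulds(t2, t1) == 2


def test_rf_matches_dendropy_on_random_trees():
    rng = np.random.default_rng(7)
    t1 = rm.random_tree(20, rng)
    t2 = rm.random_tree(20, rng)
    taxa = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                           taxon_namespace=taxa)
    d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                           taxon_namespace=taxa)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
    assert rm.robinson_foulds(t1, t2) == expected


def test_rf_leaf_set_mismatch():
    t1 = rm.PhyloTree.from_newick("((a:1,b:1):1,c:1);")
    t2 = rm.PhyloTree.from_newick("((a:1,b:1):1,d:1);")
    with pytest.raises(ValueError, match="leaf set"):
        rm.robinson_foulds(t1, t2)


def test_mean_per_site_gain():
    r1 = rm.LikelihoodResult(-900.0, np.full(100, -9.0))
    r2 = rm.LikelihoodResult(-1000.0, np.full(100, -10.0))
    assert rm.mean_per_site_loglik_gain(r1, r2) == pytest.approx(1.0)
    assert rm.mean_per_site_loglik_gain(r1, r1) == 0.0
    r3 = rm.LikelihoodResult(-10.0, np.full(2, -5.0))
    with pytest.raises(ValueError, match="length"):
        rm.mean_per_site_loglik_gain(r1, r3)


def test_newick_roundtrip(tmp_path):
    t = rm.PhyloTree.from_newick("((a:0.1,b:0.2):0.05,(c:0.3,'d x':0.4):0.07,e:0.5);")
    path = tmp_path / "t.nwk"
    t.write(path)
    t2 = rm.read_newick(path)
    assert sorted(t2.leaf_names()) == sorted(t.leaf_names())
    assert rm.robinson_foulds(t, t2) == 0
    assert t2.total_length() == pytest.approx(t.total_length(), rel=1e-9)
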