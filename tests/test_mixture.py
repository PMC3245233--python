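"""Mixture weights over basis sets, AICc rank selection and MOER."""

import numpy as np
import pytest

import ratemix as rm

from conftest import random_model


@pytest.fixture(scope="module")
def alpha4m():
    return rm.toy_alphabet(4)


@pytest.fixture(scope="module")
def basis2(alpha4m):
    return rm.random_basis(alpha4m, 2, np.random.default_rng(10))


def test_combine_unit_vector_recovers_basis_column(basis2):
    for i in range(2):
        w = rm.WeightVector(np.eye(2)[i])
        S = rm.combine(basis2, w)
        assert np.allclose(S.flatten(), basis2.matrix[:, i])


def test_combine_is_elementwise_average_at_half(basis2):
    S = rm.combine(basis2, rm.WeightVector(np.array([0.5, 0.5])))
    assert np.allclose(S.flatten(), basis2.matrix.mean(axis=1))


def test_combine_closure_symmetric_nonnegative(basis2):
    rng = np.random.default_rng(11)
    for _ in range(5):
        w = rm.WeightVector(rng.dirichlet(np.ones(2)))
        S = rm.combine(basis2, w)
        assert np.all(S.values >= 0)
        assert np.allclose(S.values, S.values.T)


def test_combine_validates_lengths(basis2):
    with pytest.raises(ValueError, match="length"):
        rm.combine(basis2, rm.WeightVector(np.array([1.0])))
    with pytest.raises(ValueError, match="non-negative"):
        rm.WeightVector(np.array([1.2, -0.2]))


def test_aicc_values():
    assert rm.aicc(-100.0, 0, 50) == pytest.approx(200.0, abs=1e-12)
    assert rm.aicc(-100.0, 5, 50) == pytest.approx(200 + 10 + 60 / 44, abs=1e-10)
    # the small-sample correction vanishes as n grows
    k = 5
    gap = [rm.aicc(-100.0, k, n) - (200 + 2 * k) for n in (50, 500, 50_000)]
    assert gap[0] == pytest.approx(2 * k * (k + 1) / (50 - k - 1), abs=1e-12)
    assert gap[-1] < 1e-2
    with pytest.raises(ValueError, match="undefined"):
        rm.aicc(-100.0, 49, 50)


def test_candidate_set_penalty_forty_models():
    assert rm.candidate_set_penalty(40) == pytest.approx(2 * np.log(40), abs=1e-12)
    assert rm.candidate_set_penalty(40) == pytest.approx(7.4, abs=0.03)


def test_weight_recovery_small(alpha4m, basis2):
    """Weights (0.7, 0.3) recovered from a 4-state simulation."""
    rng = np.random.default_rng(12)
    w_true = np.array([0.7, 0.3])
    pi = rm.FrequencyVector.uniform(alpha4m)
    S = rm.unflatten_exchangeabilities(basis2.matrix @ w_true, alpha4m)
    Q = rm.build_rate_matrix(S.normalized(pi), pi)
    tree = rm.random_tree(12, rng)
    aln = rm.simulate_alignment(rm.SimulationConfig(tree, Q, 2000, seed=13))
    fit = rm.fit_weights(aln, tree, basis2, seed=0)
    assert np.max(np.abs(fit.weights.weights - w_true)) < 0.1
    assert fit.k == 2
    assert fit.aicc == pytest.approx(rm.aicc(fit.log_likelihood, 2, 2000), abs=1e-10)


def test_single_basis_equals_fixed_matrix_fit(alpha4m, basis2):
    rng = np.random.default_rng(14)
    _, pi, Q = random_model(alpha4m, rng)
    tree = rm.random_tree(6, rng)
    aln = rm.simulate_alignment(rm.SimulationConfig(tree, Q, 300, seed=15))
    single = rm.BasisSet(alpha4m, basis2.matrix[:, :1],
                         basis2.reference_frequencies, np.ones(1))
    fit = rm.fit_weights(aln, tree, single, seed=0)
    assert np.array_equal(fit.weights.weights, [1.0])
    pi_emp = rm.empirical_frequencies(aln, alpha4m)
    Q_fixed = rm.build_rate_matrix(
        rm.unflatten_exchangeabilities(basis2.matrix[:, 0], alpha4m), pi_emp)
    _, fixed = rm.optimize_branch_lengths(aln, tree, Q_fixed)
    assert fit.log_likelihood == pytest.approx(fixed.log_likelihood, abs=1e-2)


def test_mixture_at_least_best_single_component(alpha4m, basis2):
    rng = np.random.default_rng(16)
    _, pi, Q = random_model(alpha4m, rng)
    tree = rm.random_tree(6, rng)
    aln = rm.simulate_alignment(rm.SimulationConfig(tree, Q, 300, seed=17))
    mix = rm.fit_weights(aln, tree, basis2, seed=0)
    singles = []
    for i in range(2):
        sub = rm.BasisSet(alpha4m, basis2.matrix[:, i:i + 1],
                          basis2.reference_frequencies, np.ones(1))
        singles.append(rm.fit_weights(aln, tree, sub, seed=0).log_likelihood)
    assert mix.log_likelihood >= max(singles) - 1e-2


def test_select_rank_prefers_small_rank_under_rank2_truth(alpha4m):
    rng = np.random.default_rng(18)
    truth = rm.random_basis(alpha4m, 2, rng)
    w_true = np.array([0.6, 0.4])
    pi = rm.FrequencyVector.uniform(alpha4m)
    S = rm.unflatten_exchangeabilities(truth.matrix @ w_true, alpha4m)
    Q = rm.build_rate_matrix(S.normalized(pi), pi)
    tree = rm.random_tree(10, rng)
    aln = rm.simulate_alignment(rm.SimulationConfig(tree, Q, 1500, seed=19))
    sweep = [rm.BasisSet(alpha4m, truth.matrix[:, :1],
                         truth.reference_frequencies, np.ones(1)),
             truth,
             rm.random_basis(alpha4m, 3, rng),
             rm.random_basis(alpha4m, 4, rng)]
    sel = rm.select_rank(aln, tree, sweep, seed=0)
    assert sel.best.rank <= 3
    deltas = np.array(list(sel.delta_table.values()))
    assert np.sum(deltas == 0) == 1
    assert np.all(deltas >= 0)


def test_select_rank_single_candidate(alpha4m, basis2, small_dataset):
    aln, tree, _ = small_dataset
    sel = rm.select_rank(aln, tree, [basis2], seed=0)
    assert sel.best.rank == 2
    assert list(sel.delta_table.values()) == [0.0]


def test_select_rank_skips_undefined_aicc(alpha4m, basis2):
    rng = np.random.default_rng(20)
    _, _, Q = random_model(alpha4m, rng)
    tree = rm.random_tree(4, rng)
    aln = rm.simulate_alignment(rm.SimulationConfig(tree, Q, 5, seed=21))
    big = rm.random_basis(alpha4m, 4, rng)
    with pytest.warns(UserWarning, match="skipping"):
        sel = rm.select_rank(aln, tree, [basis2, big], seed=0)
    assert sel.best.rank == 2  # the rank-4 model has n_obs - k - 1 <= 0 at 5 sites


def test_nesting_with_warm_start_monotone_lnl(alpha4m, small_dataset):
    """lnL never decreases in rank when warm-started from the padded optimum."""
    aln, tree, _ = small_dataset
    rng = np.random.default_rng(22)
    bases = [rm.random_basis(alpha4m, 1, np.random.default_rng(40))]
    for r in (2, 3):
        bigger = np.column_stack([bases[-1].matrix,
                                  rm.random_basis(alpha4m, 1, rng).matrix])
        bases.append(rm.BasisSet(alpha4m, bigger, bases[-1].reference_frequencies,
                                 np.ones(r)))
    lnls = []
    prev_fit = None
    for basis in bases:
        init = None
        if prev_fit is not None:
            padded = np.concatenate([prev_fit.weights.weights, [0.0]])
            padded = np.maximum(padded, 1e-9)
            init = rm.WeightVector(padded / padded.sum())
        prev_fit = rm.fit_weights(aln, tree, basis, init=init, seed=0)
        lnls.append(prev_fit.log_likelihood)
    assert all(b >= a - 1e-3 for a, b in zip(lnls, lnls[1:]))


def test_full_rank_coordinate_basis_matches_rev_fit():
    """With all n(n-1)/2 coordinate directions as bases, the mixture family
    is exactly the REV family (the protein statement at rank 190, exercised
    on the 3-state alphabet where the full fit is cheap)."""
    a3 = rm.toy_alphabet(3)
    rng = np.random.default_rng(23)
    _, pi, Q = random_model(a3, rng)
    tree = rm.random_tree(6, rng)
    aln = rm.simulate_alignment(rm.SimulationConfig(tree, Q, 400, seed=24))
    ref = rm.FrequencyVector.uniform(a3)
    cols = [rm.unflatten_exchangeabilities(np.eye(3)[i], a3).normalized(ref).flatten()
            for i in range(3)]
    coord_basis = rm.BasisSet(a3, np.column_stack(cols), ref, np.ones(3))
    mix = rm.fit_weights(aln, tree, coord_basis, seed=0, n_starts=4)
    rev = rm.fit_rev(aln, tree, alphabet=a3)
    assert mix.log_likelihood == pytest.approx(rev.log_likelihood, abs=0.1)


def test_moer_single_bundle_matrix_equals_fixed_fit(protein):
    rng = np.random.default_rng(25)
    wag = rm.load_bundled_matrix("WAG")
    pi = rm.FrequencyVector.uniform(protein)
    Q = rm.build_rate_matrix(wag.normalized(pi), pi)
    tree = rm.random_tree(5, rng)
    aln = rm.simulate_alignment(rm.SimulationConfig(tree, Q, 200, seed=26))
    fit = rm.moer_fit(aln, tree, {"WAG": wag}, seed=0)
    pi_emp = rm.empirical_frequencies(aln, protein)
    _, fixed = rm.optimize_branch_lengths(
        aln, tree, rm.build_rate_matrix(wag.normalized(pi_emp), pi_emp))
    assert fit.log_likelihood == pytest.approx(fixed.log_likelihood, abs=1e-2)
    assert fit.weights.weights.tolist() == [1.0]


def test_joint_factorization_loglik_additive(alpha4m, basis2):
    rng = np.random.default_rng(27)
    pairs = []
    pi = rm.FrequencyVector.uniform(alpha4m)
    weights = np.array([[0.8, 0.2], [0.3, 0.7]]).T
    for j in range(2):
        S = rm.unflatten_exchangeabilities(basis2.matrix @ weights[:, j], alpha4m)
        Q = rm.build_rate_matrix(S.normalized(pi), pi)
        tree = rm.random_tree(5, rng)
        aln = rm.simulate_alignment(rm.SimulationConfig(tree, Q, 150, seed=28 + j))
        pairs.append((aln, tree))
    coeffs = rm.CoefficientMatrix(weights, ("a", "b"))
    total = rm.joint_factorization_loglik(pairs, basis2, coeffs)
    parts = []
    for j, (aln, tree) in enumerate(pairs):
        single = rm.CoefficientMatrix(weights[:, j:j + 1], ("x",))
        parts.append(rm.joint_factorization_loglik([(aln, tree)], basis2, single))
    assert total == pytest.approx(sum(parts), abs=1e-8)


def test_joint_loglik_prefers_fitted_basis_over_random(alpha4m, basis2):
    rng = np.random.default_rng(29)
    pi = rm.FrequencyVector.uniform(alpha4m)
    pairs, weights = [], []
    for j in range(3):
        w = rng.dirichlet(np.ones(2))
        weights.append(w)
        S = rm.unflatten_exchangeabilities(basis2.matrix @ w, alpha4m)
        Q = rm.build_rate_matrix(S.normalized(pi), pi)
        tree = rm.random_tree(6, rng)
        aln = rm.simulate_alignment(rm.SimulationConfig(tree, Q, 300, seed=30 + j))
        pairs.append((aln, tree))
    coeffs = rm.CoefficientMatrix(np.array(weights).T, ("a", "b", "c"))
    truth_lnl = rm.joint_factorization_loglik(pairs, basis2, coeffs)
    random_b = rm.random_basis(alpha4m, 2, np.random.default_rng(99))
    random_lnl = rm.joint_factorization_loglik(pairs, random_b, coeffs)
    assert truth_lnl >= random_lnl
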