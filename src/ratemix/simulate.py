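"""Synthetic alignments, trees and model libraries.

The simulator is the generative counterpart of the likelihood: root
states are drawn from the equilibrium frequencies and evolved edge-wise
with the exact transition probabilities, optionally with per-site
discrete-gamma rate multipliers (a category drawn per site, matching the
discretised likelihood model exactly).  ``simulate_library`` builds a
complete train/test benchmark around a known low-rank basis so the whole
estimate-factorize-select pipeline can be exercised, and its recovery
quantified, without any external corpus.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import Alignment
from .alphabet import Alphabet, protein_alphabet
from .factorization import BasisSet, CoefficientMatrix
from .likelihood import GammaRateModel
from .matrices import (FrequencyVector, RateMatrix, build_rate_matrix,
                       free_parameter_count, transition_probability_values,
                       unflatten_exchangeabilities)
from .trees import PhyloTree, random_tree

__all__ = ["SimulationConfig", "FixtureSet", "simulate_alignment",
           "random_basis", "simulate_library"]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to draw one alignment reproducibly."""

    tree: PhyloTree
    model: RateMatrix
    n_sites: int
    seed: int
    gamma_alpha: float | None = None
    gamma_categories: int = 4

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("need at least one site")


def simulate_alignment(config: SimulationConfig) -> Alignment:
    """Evolve states down the tree with exact transition probabilities."""
    rng = np.random.default_rng(config.seed)
    Q = config.model
    alphabet = Q.alphabet
    n_sites = config.n_sites
    if config.gamma_alpha is not None:
        gamma = GammaRateModel(config.gamma_alpha, config.gamma_categories)
        site_rates = rng.choice(gamma.category_rates, size=n_sites)
    else:
        site_rates = np.ones(n_sites)

    root_states = rng.choice(alphabet.size, size=n_sites, p=Q.frequencies.values)
    states: dict[int, np.ndarray] = {id(config.tree.root): root_states}
    # preorder: parents before children
    for node in reversed(config.tree.postorder()):
        for child in node.children:
            parent_states = states[id(node)]
            child_states = np.empty(n_sites, dtype=np.int64)
            for rate in np.unique(site_rates):
                mask = site_rates == rate
                p = transition_probability_values(Q, child.length * float(rate))
                cum = np.cumsum(p, axis=1)
                u = rng.random(int(mask.sum()))
                rows = cum[parent_states[mask]]
                child_states[mask] = (u[:, None] > rows).sum(axis=1)
            states[id(child)] = child_states

    symbols = np.array(list(alphabet.symbols))
    names, rows = [], []
    for leaf in config.tree.leaves():
        names.append(leaf.name)
        rows.append("".join(symbols[states[id(leaf)]]))
    return Alignment(tuple(names), tuple(rows))


@dataclass(frozen=True)
class FixtureSet:
    """A synthetic train/test benchmark with recorded ground truth."""

    training: tuple          # (alignment, tree) pairs
    test: tuple              # held-out (alignment, tree) pairs
    truth_basis: BasisSet
    truth_coefficients: CoefficientMatrix
    truth_test_weights: np.ndarray
    master_seed: int

    def write_manifest(self, path: str | Path) -> None:
        lines = [f"master_seed: {self.master_seed}",
                 f"n_training: {len(self.training)}",
                 f"n_test: {len(self.test)}",
                 f"true_rank: {self.truth_basis.rank}"]
        Path(path).write_text("\n".join(lines) + "\n")


def random_basis(alphabet: Alphabet, rank: int, rng: np.random.Generator,
                 reference: FrequencyVector | None = None,
                 sparsity: float = 0.5) -> BasisSet:
    """Random non-negative basis, columns normalised to unit mean rate.

    Columns are sparse lognormal draws so the bases are well separated
    (nearly disjoint supports at high sparsity), which makes rank
    recovery a meaningful target rather than a lottery.  Every column is
    additionally forced to connect all states (a random spanning tree of
    small positive entries) so each basis on its own defines an
    irreducible substitution process.
    """
    if rank < 1:
        raise ValueError("rank must be at least 1")
    reference = reference or FrequencyVector.uniform(alphabet)
    n_states = alphabet.size
    n = free_parameter_count(alphabet)
    i_idx, j_idx = np.triu_indices(n_states, k=1)
    cols = []
    for _ in range(rank):
        col = rng.lognormal(mean=0.0, sigma=1.0, size=n)
        keep = rng.random(n) >= sparsity
        col = np.where(keep, col, 0.0)
        # spanning tree over a random state order keeps the chain irreducible
        order = rng.permutation(n_states)
        floor_value = 0.05 * max(col.mean(), 0.1)
        for a, b in zip(order[:-1], order[1:]):
            lo, hi = min(a, b), max(a, b)
            k = np.flatnonzero((i_idx == lo) & (j_idx == hi))[0]
            col[k] = max(col[k], floor_value)
        S = unflatten_exchangeabilities(col, alphabet).normalized(reference)
        cols.append(S.flatten())
    return BasisSet(alphabet, np.column_stack(cols), reference, np.ones(rank))


def simulate_library(n_alignments: int, true_rank: int,
                     taxa_range: tuple[int, int] = (8, 12),
                     sites_range: tuple[int, int] = (300, 500),
                     noise: float = 0.0,
                     master_seed: int = 0,
                     alphabet: Alphabet | None = None,
                     n_test: int = 2,
                     test_sites_range: tuple[int, int] | None = None,
                     gamma_alpha: float | None = None) -> FixtureSet:
    """Draw a ground-truth basis and a train/test set generated under it.

    Per alignment: simplex weights over the true basis (Dirichlet),
    optional multiplicative noise on the combined exchangeabilities, a
    random coalescent-style tree, and a simulated alignment.  Training
    and test draws are disjoint and all seeds derive from ``master_seed``.
    Held-out alignments default to the training size range; pass
    ``test_sites_range`` to emulate the realistic case of new alignments
    smaller than the training ones.
    """
    if true_rank < 1:
        raise ValueError("true_rank must be at least 1")
    if taxa_range[0] < 2 or sites_range[0] < 1 or taxa_range[0] > taxa_range[1] \
            or sites_range[0] > sites_range[1]:
        raise ValueError("infeasible taxa/sites ranges")
    alphabet = alphabet or protein_alphabet()
    rng = np.random.default_rng(master_seed)
    reference = FrequencyVector.uniform(alphabet)
    basis = random_basis(alphabet, true_rank, rng, reference)

    def draw_pair(weights: np.ndarray, seed: int, sites=None):
        sites = sites or sites_range
        n_taxa = int(rng.integers(taxa_range[0], taxa_range[1] + 1))
        n_sites = int(rng.integers(sites[0], sites[1] + 1))
        tree = random_tree(n_taxa, rng)
        vec = basis.matrix @ weights
        if noise > 0:
            vec = vec * rng.lognormal(mean=0.0, sigma=noise, size=len(vec))
        S = unflatten_exchangeabilities(vec, alphabet).normalized(reference)
        Q = build_rate_matrix(S, reference, normalize=True)
        config = SimulationConfig(tree, Q, n_sites, seed, gamma_alpha=gamma_alpha)
        return simulate_alignment(config), tree

    train_weights = rng.dirichlet(np.ones(true_rank), size=n_alignments)
    training = tuple(draw_pair(train_weights[i], int(rng.integers(2 ** 31)))
                     for i in range(n_alignments))
    test_weights = rng.dirichlet(np.ones(true_rank), size=n_test)
    test = tuple(draw_pair(test_weights[i], int(rng.integers(2 ** 31)),
                           sites=test_sites_range)
                 for i in range(n_test))
    coeffs = CoefficientMatrix(train_weights.T,
                               tuple(f"train_{i}" for i in range(n_alignments)))
    return FixtureSet(training, test, basis, coeffs, test_weights, master_seed)
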