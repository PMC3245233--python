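"""Mixture models over basis exchangeability matrices, with AICc selection.

A new alignment's exchangeability matrix is modelled as the non-negative
weighted sum S = sum_i w_i B_i over a fixed set of basis matrices.
Because rate and time are confounded with free branch lengths, the
weights are constrained to the probability simplex (sum to one) and
every basis matrix is pre-normalised to unit mean rate, so the weights
carry no overall-rate information.  Weights and branch lengths are
optimised jointly (alternating) by maximum likelihood; the number of
basis matrices (the factorization rank) is selected by AICc with the
number of alignment sites as the observation count and branch lengths
excluded from the parameter count.

The same machinery over a bundle of published matrices (Dayhoff, JTT,
WAG, rtREV, mtMAM, mtREV24, HIVwithin, HIVbetween) is the "Mixture of
Existing Rates" (MOER) model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .alignment import Alignment, empirical_frequencies
from .alphabet import check_same_alphabet, protein_alphabet
from .factorization import BasisSet, CoefficientMatrix
from .likelihood import GammaRateModel, log_likelihood, optimize_branch_lengths
from .matrices import (ExchangeabilityMatrix, FrequencyVector, build_rate_matrix,
                       unflatten_exchangeabilities)
from .paml import read_paml_matrix
from .trees import PhyloTree

__all__ = [
    "WeightVector", "RankFit", "ModelSelection",
    "combine", "fit_weights", "aicc", "select_rank", "moer_fit",
    "candidate_set_penalty", "joint_factorization_loglik",
    "BUNDLED_MATRIX_NAMES", "load_bundled_matrix", "load_bundle",
]

BUNDLED_MATRIX_NAMES = ("Dayhoff", "JTT", "WAG", "rtREV", "mtMAM", "mtREV24",
                        "HIVwithin", "HIVbetween")


@dataclass(frozen=True)
class WeightVector:
    """Non-negative mixture weights on the simplex."""

    weights: np.ndarray
    basis_ref: str = ""

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float).copy()
        if w.ndim != 1 or len(w) < 1:
            raise ValueError("weights must be a non-empty vector")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-10:
            raise ValueError("weights must sum to 1")
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class RankFit:
    rank: int
    weights: WeightVector
    log_likelihood: float
    k: int
    n_obs: int
    aicc: float
    tree: PhyloTree
    converged: bool = True

    def __post_init__(self):
        expected = aicc(self.log_likelihood, self.k, self.n_obs)
        if abs(expected - self.aicc) > 1e-10:
            raise ValueError("stored AICc does not reproduce from (lnL, k, n_obs)")


@dataclass(frozen=True)
class ModelSelection:
    fits: tuple
    best: RankFit
    delta_table: dict

    def __post_init__(self):
        deltas = np.array(list(self.delta_table.values()))
        if np.any(deltas < 0):
            raise ValueError("delta AICc values must be non-negative")
        if int(np.sum(deltas == 0)) != 1:
            raise ValueError("exactly one model must have delta AICc == 0")


def combine(basis: BasisSet, w: WeightVector) -> ExchangeabilityMatrix:
    """S = sum_i w_i B_i, element-wise over the flattened representation."""
    if len(w) != basis.rank:
        raise ValueError("weight length does not match basis rank")
    vec = basis.matrix @ w.weights
    return unflatten_exchangeabilities(vec, basis.alphabet)


def aicc(log_likelihood: float, k: int, n_obs: int) -> float:
    """Small-sample Akaike criterion: -2 lnL + 2k + 2k(k+1)/(n_obs - k - 1).

    ``n_obs`` is the number of alignment sites and ``k`` counts mixture
    weights only; the correction term is undefined when n_obs <= k + 1.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if n_obs - k - 1 <= 0:
        raise ValueError("AICc undefined: n_obs - k - 1 must be positive")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n_obs - k - 1)


def candidate_set_penalty(n_candidates: int) -> float:
    """Flat 2 ln(#candidates) diagnostic penalty for selecting across a sweep
    (about 7.4 for 40 candidate ranks)."""
    if n_candidates < 1:
        raise ValueError("need at least one candidate")
    return 2.0 * float(np.log(n_candidates))


def _simplex_to_theta(w: np.ndarray) -> np.ndarray:
    """Log-ratio coordinates against the last weight (reference)."""
    w = np.maximum(w, 1e-12)
    return np.log(w[:-1] / w[-1])


def _theta_to_simplex(theta: np.ndarray) -> np.ndarray:
    z = np.concatenate([theta, [0.0]])
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def fit_weights(alignment: Alignment, tree: PhyloTree, basis: BasisSet,
                rates: GammaRateModel | None = None,
                init: WeightVector | None = None,
                k_convention: str = "r",
                n_starts: int = 3, seed: int = 0,
                tol: float = 1e-4, max_rounds: int = 30) -> RankFit:
    """ML mixture weights (simplex) and branch lengths for one basis set.

    Multi-start over the simplex (uniform, best single component, random)
    to dodge local optima; alternates quasi-Newton steps in log-ratio
    coordinates with coordinate-wise branch-length updates.  ``k``
    defaults to the rank r (``k_convention="r"``); set
    ``k_convention="r-1"`` to count simplex degrees of freedom instead.
    """
    alphabet = check_same_alphabet(basis)
    r = basis.rank
    pi = empirical_frequencies(alignment, alphabet)
    n_obs = alignment.n_sites

    def lnl_for(w: np.ndarray, current_tree: PhyloTree) -> float:
        S = combine(basis, WeightVector(w))
        Q = build_rate_matrix(S, pi, normalize=True)
        try:
            return log_likelihood(alignment, current_tree, Q, rates).log_likelihood
        except ValueError:
            # structurally impossible point (e.g. a reducible combined matrix
            # on the simplex boundary): steer the optimizer away
            return -1e12

    if r == 1:
        S = combine(basis, WeightVector(np.array([1.0])))
        Q = build_rate_matrix(S, pi, normalize=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted_tree, result = optimize_branch_lengths(alignment, tree, Q, rates)
        k = 1 if k_convention == "r" else 0
        return RankFit(1, WeightVector(np.array([1.0])), result.log_likelihood,
                       k, n_obs, aicc(result.log_likelihood, k, n_obs), fitted_tree)

    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(init.weights)
    starts.append(np.full(r, 1.0 / r))
    # best single component on the starting tree
    singles = [lnl_for(np.eye(r)[i] * (1 - 1e-6) + 1e-6 / r, tree) for i in range(r)]
    best_single = int(np.argmax(singles))
    e = np.full(r, 1e-3 / (r - 1))
    e[best_single] = 1.0 - 1e-3
    starts.append(e)
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_starts - 2)):
        starts.append(rng.dirichlet(np.ones(r)))

    best_fit = None
    for w0 in starts:
        current_tree = tree.copy()
        w = np.asarray(w0, dtype=float)
        w = np.maximum(w, 1e-9)
        w /= w.sum()
        lnl = lnl_for(w, current_tree)
        converged = False
        for _ in range(max_rounds):
            previous = lnl
            theta0 = _simplex_to_theta(w)

            def objective(theta):
                return -lnl_for(_theta_to_simplex(theta), current_tree)

            res = minimize(objective, theta0, method="L-BFGS-B",
                           options={"maxiter": 40, "ftol": 1e-10})
            if -res.fun > lnl:
                w = _theta_to_simplex(res.x)
                lnl = -res.fun
            S = combine(basis, WeightVector(w))
            Q = build_rate_matrix(S, pi, normalize=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                current_tree, result = optimize_branch_lengths(
                    alignment, current_tree, Q, rates, tol=tol / 2, max_cycles=3)
            lnl = result.log_likelihood
            if lnl - previous < tol:
                converged = True
                break
        if not converged:
            warnings.warn("weight optimization reached the round limit")
        if best_fit is None or lnl > best_fit[0]:
            best_fit = (lnl, w, current_tree, converged)

    lnl, w, fitted_tree, converged = best_fit
    # zero-out numerical dust so reported weights are clean simplex points
    w = np.where(w < 1e-9, 0.0, w)
    w /= w.sum()
    k = r if k_convention == "r" else r - 1
    return RankFit(r, WeightVector(w), lnl, k, n_obs,
                   aicc(lnl, k, n_obs), fitted_tree, converged)


def select_rank(alignment: Alignment, tree: PhyloTree, sweep,
                rates: GammaRateModel | None = None,
                k_convention: str = "r", seed: int = 0,
                labels=None) -> ModelSelection:
    """Fit every basis set in the sweep and pick the minimum-AICc model.

    Ranks whose AICc correction is undefined (n_sites <= k + 1) are
    skipped with a warning; ties break toward the smaller rank.
    """
    sweep = list(sweep)
    if not sweep:
        raise ValueError("empty basis sweep")
    labels = list(labels) if labels is not None else [f"rank_{b.rank}" for b in sweep]
    fits, kept_labels = [], []
    for label, basis in zip(labels, sweep):
        k = basis.rank if k_convention == "r" else basis.rank - 1
        if alignment.n_sites - k - 1 <= 0:
            warnings.warn(f"skipping {label}: AICc undefined at k={k} "
                          f"with {alignment.n_sites} sites")
            continue
        try:
            fit = fit_weights(alignment, tree, basis, rates=rates,
                              k_convention=k_convention, seed=seed)
        except ValueError as exc:
            warnings.warn(f"skipping {label}: {exc}")
            continue
        if fit.log_likelihood <= -1e11:
            warnings.warn(f"skipping {label}: model incompatible with the data")
            continue
        fits.append(fit)
        kept_labels.append(label)
    if not fits:
        raise ValueError("no rank admits a defined AICc for this alignment")
    scores = np.array([f.aicc for f in fits])
    order = np.lexsort((np.array([f.rank for f in fits]), scores))
    best = fits[int(order[0])]
    minimum = best.aicc
    delta_table = {}
    for label, f in zip(kept_labels, fits):
        delta = float(f.aicc - minimum)
        if f is not best and delta == 0.0:
            # exact float tie: the smaller rank won the tie-break, so mark
            # the other entry as (infinitesimally) non-optimal
            delta = float(np.nextafter(0.0, 1.0))
        delta_table[label] = delta
    return ModelSelection(tuple(fits), best, delta_table)


def load_bundled_matrix(name: str) -> ExchangeabilityMatrix:
    """One of the eight published matrices shipped with the package."""
    if name not in BUNDLED_MATRIX_NAMES:
        raise KeyError(f"unknown bundled matrix {name!r}; "
                       f"choose from {BUNDLED_MATRIX_NAMES}")
    ref = resources.files("ratemix.data.matrices") / f"{name}.dat"
    with resources.as_file(ref) as path:
        S, _ = read_paml_matrix(path)
    return S


def load_bundle(names=BUNDLED_MATRIX_NAMES) -> dict[str, ExchangeabilityMatrix]:
    return {name: load_bundled_matrix(name) for name in names}


def moer_fit(alignment: Alignment, tree: PhyloTree,
             bundle: dict[str, ExchangeabilityMatrix] | None = None,
             rates: GammaRateModel | None = None,
             k_convention: str = "r", seed: int = 0) -> RankFit:
    """Mixture of Existing Rates: mixture weights over published matrices.

    Each bundle matrix is renormalised to unit mean rate under the
    alignment's empirical frequencies before mixing (the bundles' own
    equilibrium frequencies are never used); then the machinery is
    exactly :func:`fit_weights` with k = bundle size.
    """
    bundle = bundle or load_bundle()
    alphabet = next(iter(bundle.values())).alphabet
    pi = empirical_frequencies(alignment, alphabet)
    cols = [S.normalized(pi).flatten() for S in bundle.values()]
    basis = BasisSet(alphabet, np.column_stack(cols), pi, np.ones(len(cols)))
    fit = fit_weights(alignment, tree, basis, rates=rates,
                      k_convention=k_convention, seed=seed)
    return RankFit(fit.rank,
                   WeightVector(fit.weights.weights, basis_ref="MOER:" +
                                ",".join(bundle.keys())),
                   fit.log_likelihood, fit.k, fit.n_obs, fit.aicc,
                   fit.tree, fit.converged)


def joint_factorization_loglik(training, basis: BasisSet,
                               coefficients: CoefficientMatrix,
                               rates: GammaRateModel | None = None) -> float:
    """Diagnostic joint log-likelihood of the training set under the
    factorization: sum over alignments of the pruning lnL under the model
    combined from the basis and that alignment's coefficient column
    (renormalised to the simplex).  Never optimised — the factorization
    itself is fit by least squares.
    """
    training = list(training)
    if coefficients.matrix.shape[1] != len(training):
        raise ValueError("coefficient columns do not match the training list")
    total = 0.0
    for j, (alignment, tree) in enumerate(training):
        col = coefficients.matrix[:, j]
        if col.sum() <= 0:
            raise ValueError(f"coefficient column {j} has no mass")
        w = WeightVector(col / col.sum())
        S = combine(basis, w)
        pi = empirical_frequencies(alignment, basis.alphabet)
        Q = build_rate_matrix(S, pi, normalize=True)
        total += log_likelihood(alignment, tree, Q, rates).log_likelihood
    return total
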