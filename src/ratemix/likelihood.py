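"""Felsenstein pruning likelihood with optional discrete-gamma rate variation.

Site patterns are compressed before the post-order sweep, partial
likelihoods are rescaled per node and per pattern to avoid underflow on
deep trees, and the transition matrix on each branch comes from the
eigendecomposition cached on the rate matrix.  Missing data (gaps,
ambiguity codes) enter as all-ones partial vectors, so an all-missing
sequence leaves the likelihood unchanged.

Among-site rate variation is the standard discretised gamma: equal
probability categories represented by their conditional means, shape
``alpha``, mean rate constrained to 1 so branch lengths keep their
substitutions-per-site meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .alignment import Alignment
from .matrices import RateMatrix, transition_probability_values
from .trees import MIN_BRANCH_LENGTH, PhyloTree

__all__ = [
    "GammaRateModel",
    "LikelihoodResult",
    "log_likelihood",
    "optimize_branch_lengths",
    "mean_per_site_loglik_gain",
]

#: Partial-likelihood rescale trigger.
_SCALE_THRESHOLD = 1e-100

MAX_BRANCH_LENGTH = 20.0


@dataclass(frozen=True)
class GammaRateModel:
    """Discretised gamma rates: equal-probability categories, category means."""

    alpha: float
    n_categories: int = 4
    category_rates: np.ndarray = field(init=False)
    category_probs: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("gamma shape must be positive")
        if self.n_categories < 1:
            raise ValueError("need at least one rate category")
        k = self.n_categories
        a = self.alpha
        if np.isinf(a):  # the no-variation limit: every category at rate 1
            object.__setattr__(self, "category_rates", np.ones(k))
            object.__setattr__(self, "category_probs", np.full(k, 1.0 / k))
            return
        # category boundaries at quantiles i/k of Gamma(a, scale=1/a);
        # category rate = conditional mean within the slice, times k
        bounds = gamma_dist.ppf(np.arange(1, k) / k, a, scale=1.0 / a)
        upper = np.concatenate([bounds, [np.inf]])
        lower = np.concatenate([[0.0], bounds])
        mass_mean = gammainc(a + 1, np.where(np.isinf(upper), np.inf, upper * a)) - \
            gammainc(a + 1, lower * a)
        rates = mass_mean * k
        rates = rates / (rates.mean())  # exact mean-1 despite quadrature error
        object.__setattr__(self, "category_rates", rates)
        object.__setattr__(self, "category_probs", np.full(k, 1.0 / k))
        if np.any(np.diff(rates) <= 0) and k > 1:
            raise ValueError("category rates must be strictly increasing")


@dataclass(frozen=True)
class LikelihoodResult:
    log_likelihood: float
    per_site_log_likelihoods: np.ndarray
    scaling_events: int = 0

    def __post_init__(self):
        if not np.isfinite(self.log_likelihood):
            raise ValueError("non-finite log-likelihood")


@lru_cache(maxsize=64)
def _compress_patterns(alignment: Alignment, alphabet):
    """Unique site columns, their weights, and the site->pattern map.

    Cached per (alignment, alphabet), like the encoding: optimisers hit
    this with identical arguments thousands of times.
    """
    coded = alignment.encode(alphabet)
    cols, inverse, counts = np.unique(coded.T, axis=0, return_inverse=True,
                                      return_counts=True)
    patterns = np.ascontiguousarray(cols.T)
    patterns.flags.writeable = False
    return patterns, counts.astype(float), inverse


def _site_likelihoods_one_rate(tree: PhyloTree, Q: RateMatrix, patterns: np.ndarray,
                               leaf_row: dict[str, int], rate: float):
    """Per-pattern likelihood and log-scalers for a single rate multiplier."""
    n_states = Q.alphabet.size
    n_patterns = patterns.shape[1]
    eye = np.eye(n_states)
    partials: dict[int, np.ndarray] = {}
    log_scale = np.zeros(n_patterns)
    scaling_events = 0
    for node in tree.postorder():
        if node.is_leaf:
            codes = patterns[leaf_row[node.name]]
            part = np.ones((n_patterns, n_states))
            observed = codes >= 0
            part[observed] = eye[codes[observed]]
        else:
            part = np.ones((n_patterns, n_states))
            for child in node.children:
                p = transition_probability_values(Q, child.length * rate)
                part *= partials.pop(id(child)) @ p.T
            small = part.max(axis=1) < _SCALE_THRESHOLD
            if small.any():
                scaler = np.where(small, part.max(axis=1), 1.0)
                scaler[scaler == 0] = 1.0
                part /= scaler[:, None]
                log_scale += np.log(scaler)
                scaling_events += int(small.sum())
        partials[id(node)] = part
    root_part = partials[id(tree.root)]
    site_lik = root_part @ Q.frequencies.values
    return site_lik, log_scale, scaling_events


def log_likelihood(alignment: Alignment, tree: PhyloTree, Q: RateMatrix,
                   rates: GammaRateModel | None = None) -> LikelihoodResult:
    """Pruning log-likelihood of an alignment on a tree under generator Q.

    With a :class:`GammaRateModel`, each site's likelihood is the
    equal-weight average of category likelihoods computed with branch
    lengths multiplied by the category rate.
    """
    if set(tree.leaf_names()) != set(alignment.names):
        raise ValueError("tree leaves and alignment sequence names differ")
    patterns, weights, inverse = _compress_patterns(alignment, Q.alphabet)
    leaf_row = {name: i for i, name in enumerate(alignment.names)}

    rate_values = rates.category_rates if rates is not None else np.array([1.0])
    per_cat = np.zeros((len(rate_values), patterns.shape[1]))
    scaling_events = 0
    log_scales = np.zeros((len(rate_values), patterns.shape[1]))
    for c, r in enumerate(rate_values):
        lik, log_scale, events = _site_likelihoods_one_rate(tree, Q, patterns, leaf_row, r)
        per_cat[c] = lik
        log_scales[c] = log_scale
        scaling_events += events
    # average across categories in a scale-safe way
    shifted = log_scales - log_scales.max(axis=0, keepdims=True)
    mixed = (per_cat * np.exp(shifted)).mean(axis=0)
    with np.errstate(divide="ignore"):
        pattern_loglik = np.log(mixed) + log_scales.max(axis=0)
    if np.any(~np.isfinite(pattern_loglik)):
        raise ValueError("zero-likelihood site pattern (incompatible data/model)")
    per_site = pattern_loglik[inverse]
    return LikelihoodResult(float(pattern_loglik @ weights), per_site, scaling_events)


def optimize_branch_lengths(alignment: Alignment, tree: PhyloTree, Q: RateMatrix,
                            rates: GammaRateModel | None = None,
                            tol: float = 1e-6, max_cycles: int = 50,
                            t_max: float = MAX_BRANCH_LENGTH):
    """Coordinate-wise ML branch lengths on [MIN_BRANCH_LENGTH, t_max].

    Cycles Brent searches over every branch until the cycle improves the
    log-likelihood by less than ``tol``; returns the optimised tree copy
    and its likelihood.  Warns (and returns the best found) if the cycle
    limit is reached without convergence.
    """
    tree = tree.copy()
    current = log_likelihood(alignment, tree, Q, rates).log_likelihood
    converged = False
    for _ in range(max_cycles):
        previous = current
        for edge in tree.edges():
            original = edge.length

            def negloglik(t: float, edge=edge) -> float:
                edge.length = t
                return -log_likelihood(alignment, tree, Q, rates).log_likelihood

            res = minimize_scalar(negloglik, bounds=(MIN_BRANCH_LENGTH, t_max),
                                  method="bounded", options={"xatol": 1e-7})
            if -res.fun >= current - 1e-12:
                edge.length = float(res.x)
                current = -float(res.fun)
            else:  # guard against rare bounded-search misses
                edge.length = original
        if current - previous < tol:
            converged = True
            break
    if not converged:
        warnings.warn("branch-length optimization did not converge; returning best found")
    return tree, log_likelihood(alignment, tree, Q, rates)


def mean_per_site_loglik_gain(result_a: LikelihoodResult,
                              result_b: LikelihoodResult) -> float:
    """(lnL_a - lnL_b) / n_sites, the per-site improvement of model a over b."""
    n_a = len(result_a.per_site_log_likelihoods)
    n_b = len(result_b.per_site_log_likelihoods)
    if n_a != n_b:
        raise ValueError("results come from alignments of different lengths")
    return (result_a.log_likelihood - result_b.log_likelihood) / n_a
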