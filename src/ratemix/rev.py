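"""Maximum-likelihood estimation of general reversible (REV) exchangeabilities.

The full REV model frees all n(n-1)/2 exchangeabilities (190 for
proteins) — the amino-acid analogue of GTR.  Because overall rate and
time are confounded with free branch lengths, one reference entry is
pinned during optimisation and the returned matrix is renormalised to
unit mean rate under the alignment's empirical frequencies.

The "1-step" restriction fixes to zero every exchangeability between
residues whose codons (standard nuclear code, sense codons only) cannot
interconvert through a single nucleotide change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.optimize import minimize

from .alignment import Alignment, empirical_frequencies
from .alphabet import Alphabet, protein_alphabet
from .likelihood import GammaRateModel, log_likelihood, optimize_branch_lengths
from .matrices import (ExchangeabilityMatrix, FrequencyVector, build_rate_matrix,
                       free_parameter_count)
from .trees import PhyloTree

__all__ = ["REVFit", "OneStepMask", "one_step_mask", "fit_rev"]


@dataclass(frozen=True)
class REVFit:
    S_hat: ExchangeabilityMatrix
    log_likelihood: float
    n_free: int
    converged: bool
    iterations: int
    tree: PhyloTree
    frequencies: FrequencyVector
    trace: list  # (round, lnL, max parameter delta) per outer round


@dataclass(frozen=True)
class OneStepMask:
    """Symmetric boolean matrix: which residue pairs are one nucleotide apart."""

    alphabet: Alphabet
    allowed: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.allowed, dtype=bool).copy()
        n = self.alphabet.size
        if a.shape != (n, n):
            raise ValueError("mask shape mismatch")
        if not np.array_equal(a, a.T):
            raise ValueError("mask must be symmetric")
        a.flags.writeable = False
        object.__setattr__(self, "allowed", a)

    @property
    def n_allowed_pairs(self) -> int:
        return int(np.triu(self.allowed, k=1).sum())


_STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def one_step_mask(alphabet: Alphabet | None = None) -> OneStepMask:
    """Pairs of residues reachable by one nucleotide change in the standard code.

    Computed over the 61 sense codons; a pair (i, j) is allowed iff some
    codon of i and some codon of j differ at exactly one position.
    """
    alphabet = alphabet or protein_alphabet()
    if set(alphabet.symbols) != set(protein_alphabet().symbols):
        raise ValueError("the one-step mask is defined for the protein alphabet")
    codons_of = {aa: [c for c, a in _STANDARD_CODE.items() if a == aa]
                 for aa in alphabet.symbols}
    n = alphabet.size
    allowed = np.zeros((n, n), dtype=bool)
    for i, j in product(range(n), range(n)):
        if i >= j:
            continue
        for ci in codons_of[alphabet.symbols[i]]:
            for cj in codons_of[alphabet.symbols[j]]:
                if sum(a != b for a, b in zip(ci, cj)) == 1:
                    allowed[i, j] = allowed[j, i] = True
                    break
            if allowed[i, j]:
                break
    return OneStepMask(alphabet, allowed)


def _mask_vector(mask: OneStepMask | None, alphabet: Alphabet) -> np.ndarray:
    n = alphabet.size
    i, j = np.triu_indices(n, k=1)
    if mask is None:
        return np.ones(len(i), dtype=bool)
    return mask.allowed[i, j]


def fit_rev(alignment: Alignment, tree: PhyloTree,
            mask: OneStepMask | None = None,
            rates: GammaRateModel | None = None,
            alphabet: Alphabet | None = None,
            init: ExchangeabilityMatrix | None = None,
            tol: float = 1e-4, max_rounds: int = 200,
            branch_cycles_per_round: int = 2) -> REVFit:
    """Joint ML fit of exchangeabilities and branch lengths.

    Free exchangeabilities are optimised as logs of positive reals with
    the first free entry pinned (removing the rate/time confound);
    optimisation alternates quasi-Newton rounds on the exchangeabilities
    with coordinate-wise branch-length updates until the round improves
    the log-likelihood by less than ``tol``.  The returned matrix is
    scaled to unit mean rate under the alignment's empirical frequencies.
    """
    alphabet = alphabet or protein_alphabet()
    pi = empirical_frequencies(alignment, alphabet)
    free = _mask_vector(mask, alphabet)
    n_free = int(free.sum())
    if n_free == 0:
        raise ValueError("mask leaves no free exchangeabilities")
    i_idx, j_idx = np.triu_indices(alphabet.size, k=1)

    if init is not None:
        vec0 = init.flatten()[free]
        vec0 = np.maximum(vec0, 1e-8)
    else:
        vec0 = np.ones(n_free)

    def build_S(free_values: np.ndarray) -> ExchangeabilityMatrix:
        full = np.zeros(len(i_idx))
        full[free] = free_values
        m = np.zeros((alphabet.size,) * 2)
        m[i_idx, j_idx] = full
        m[j_idx, i_idx] = full
        return ExchangeabilityMatrix(alphabet, m)

    # pin the first free entry: optimise the remaining n_free-1 in log space
    pinned = vec0[0]

    def unpack(theta: np.ndarray) -> np.ndarray:
        return np.concatenate([[pinned], np.exp(theta)])

    tree = tree.copy()
    current_vec = vec0.copy()

    def loglik_for(free_values: np.ndarray) -> float:
        S = build_S(free_values)
        Q = build_rate_matrix(S, pi, normalize=True)
        return log_likelihood(alignment, tree, Q, rates).log_likelihood

    lnl = loglik_for(current_vec)
    trace = [(0, lnl, np.nan)]
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        previous_lnl = lnl
        previous_vec = current_vec.copy()
        if n_free > 1:
            theta0 = np.log(np.maximum(current_vec[1:], 1e-10))

            def objective(theta: np.ndarray) -> float:
                return -loglik_for(unpack(theta))

            res = minimize(objective, theta0, method="L-BFGS-B",
                           options={"maxiter": 60, "ftol": 1e-10})
            if -res.fun > lnl:
                current_vec = unpack(res.x)
                lnl = -res.fun
        S = build_S(current_vec)
        Q = build_rate_matrix(S, pi, normalize=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree, result = optimize_branch_lengths(
                alignment, tree, Q, rates, tol=tol / 2,
                max_cycles=branch_cycles_per_round)
        lnl = result.log_likelihood
        delta = float(np.max(np.abs(current_vec - previous_vec)))
        trace.append((rounds, lnl, delta))
        if lnl - previous_lnl < tol:
            converged = True
            break
    if not converged:
        warnings.warn("REV fit did not converge within the round limit")

    S_hat = build_S(current_vec).normalized(pi)
    return REVFit(S_hat=S_hat, log_likelihood=lnl,
                  n_free=n_free if mask is not None else free_parameter_count(alphabet),
                  converged=converged, iterations=rounds,
                  tree=tree, frequencies=pi, trace=trace)


def write_fit_trace(fit: REVFit, path) -> None:
    """Optimisation trace as CSV (round, lnL, max parameter delta)."""
    import pandas as pd
    pd.DataFrame(fit.trace, columns=["round", "lnL", "max_param_delta"]).to_csv(
        path, index=False)
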