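"""Exchangeability matrices, equilibrium frequencies and the CTMC machinery.

A reversible substitution process is parameterised as ``Q = S @ diag(pi)``
(off-diagonals ``q_ij = s_ij * pi_j``) where ``S`` is a symmetric
non-negative exchangeability matrix and ``pi`` the equilibrium residue
frequencies.  The diagonal of ``Q`` is set so rows sum to zero, and ``Q``
is conventionally scaled to one expected substitution per unit time so
branch lengths are in substitutions per site.  Transition probabilities
are ``P(t) = expm(Q t)``, computed here through the eigendecomposition of
the symmetrised generator ``diag(sqrt(pi)) Q diag(1/sqrt(pi))`` (exact for
reversible ``Q``), with scipy's scaling-and-squaring as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .alphabet import Alphabet, check_same_alphabet

__all__ = [
    "ExchangeabilityMatrix",
    "FrequencyVector",
    "RateMatrix",
    "TransitionMatrix",
    "build_rate_matrix",
    "transition_probabilities",
    "flatten_exchangeabilities",
    "unflatten_exchangeabilities",
    "free_parameter_count",
    "FREQ_FLOOR",
]

#: Floor applied to empirical frequencies so absent residues never produce
#: absorbing states or break the reversible symmetrisation.
FREQ_FLOOR = 1e-6


def free_parameter_count(alphabet: Alphabet) -> int:
    """Number of free exchangeabilities for a symmetric matrix: n(n-1)/2.

    190 for the 20-state protein alphabet.
    """
    n = alphabet.size
    return n * (n - 1) // 2


@dataclass(frozen=True)
class ExchangeabilityMatrix:
    """Symmetric non-negative relative-rate matrix S (diagonal unused, zero)."""

    alphabet: Alphabet
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).copy()
        n = self.alphabet.size
        if v.shape != (n, n):
            raise ValueError(f"expected {n}x{n} matrix, got {v.shape}")
        if not np.allclose(v, v.T, rtol=0, atol=1e-10):
            raise ValueError("exchangeability matrix must be symmetric")
        if np.any(v < 0):
            raise ValueError("exchangeability matrix must be non-negative")
        np.fill_diagonal(v, 0.0)
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    def flatten(self) -> np.ndarray:
        return flatten_exchangeabilities(self)

    def mean_rate(self, pi: "FrequencyVector") -> float:
        """Expected substitutions per unit time of the implied (unnormalised) Q."""
        check_same_alphabet(self, pi)
        q_off = self.values * pi.values[None, :]
        return float(pi.values @ q_off.sum(axis=1))

    def normalized(self, pi: "FrequencyVector") -> "ExchangeabilityMatrix":
        """Rescale so the implied Q under ``pi`` has mean rate 1."""
        mu = self.mean_rate(pi)
        if mu <= 0:
            raise ValueError("cannot normalize an all-zero exchangeability matrix")
        return ExchangeabilityMatrix(self.alphabet, self.values / mu)


@dataclass(frozen=True)
class FrequencyVector:
    """Equilibrium residue frequencies (strictly positive, summing to 1)."""

    alphabet: Alphabet
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).copy()
        if v.shape != (self.alphabet.size,):
            raise ValueError("frequency vector length mismatch")
        if np.any(v <= 0):
            raise ValueError("frequencies must be strictly positive (apply flooring upstream)")
        if abs(v.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    @classmethod
    def from_counts(cls, alphabet: Alphabet, counts: np.ndarray,
                    floor: float = FREQ_FLOOR) -> "FrequencyVector":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("no countable residues")
        freqs = np.maximum(counts / total, floor)
        return cls(alphabet, freqs / freqs.sum())

    @classmethod
    def uniform(cls, alphabet: Alphabet) -> "FrequencyVector":
        n = alphabet.size
        return cls(alphabet, np.full(n, 1.0 / n))


@dataclass(frozen=True)
class RateMatrix:
    """Instantaneous-rate generator Q with zero row sums and detailed balance."""

    alphabet: Alphabet
    values: np.ndarray
    frequencies: FrequencyVector
    # cached eigendecomposition of the symmetrised generator, built lazily
    _eig: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).copy()
        n = self.alphabet.size
        if v.shape != (n, n):
            raise ValueError("rate matrix shape mismatch")
        off = v.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal rates must be non-negative")
        if np.max(np.abs(v.sum(axis=1))) > 1e-10:
            raise ValueError("rate matrix rows must sum to 0")
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    @property
    def mean_rate(self) -> float:
        return float(-(self.frequencies.values @ np.diag(self.values)))

    def _eigendecomposition(self):
        """Eigendecomposition via the symmetrised generator (reversible Q)."""
        if "w" not in self._eig:
            pi = self.frequencies.values
            d = np.sqrt(pi)
            sym = (d[:, None] * self.values) / d[None, :]
            sym = 0.5 * (sym + sym.T)
            w, u = np.linalg.eigh(sym)
            self._eig["w"] = w
            self._eig["left"] = u.T * d[None, :]      # U^T D
            self._eig["right"] = u / d[:, None]        # D^-1 U
        return self._eig["w"], self._eig["right"], self._eig["left"]

    def is_reversible(self, atol: float = 1e-8) -> bool:
        if "reversible" not in self._eig:
            pi = self.frequencies.values
            flux = pi[:, None] * self.values
            self._eig["reversible"] = bool(np.allclose(flux, flux.T, rtol=0, atol=atol))
        return self._eig["reversible"]


@dataclass(frozen=True)
class TransitionMatrix:
    """P(t) = expm(Q t): substitution probabilities over a branch."""

    alphabet: Alphabet
    values: np.ndarray
    time: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).copy()
        rs = v.sum(axis=1)
        if np.max(np.abs(rs - 1.0)) > 1e-8:
            raise ValueError("transition matrix rows must sum to 1")
        v = np.clip(v, 0.0, 1.0)
        v /= v.sum(axis=1, keepdims=True)
        v.flags.writeable = False
        object.__setattr__(self, "values", v)


def build_rate_matrix(S: ExchangeabilityMatrix, pi: FrequencyVector,
                      normalize: bool = True) -> RateMatrix:
    """Assemble Q from exchangeabilities and frequencies.

    Off-diagonals are ``q_ij = s_ij * pi_j``; the diagonal makes rows sum
    to zero; with ``normalize`` the matrix is scaled to mean rate 1 so
    branch lengths measure expected substitutions per site.
    """
    alphabet = check_same_alphabet(S, pi)
    q = S.values * pi.values[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if normalize:
        mu = -(pi.values @ np.diag(q))
        if mu <= 0:
            raise ValueError("cannot normalize: exchangeability matrix is all zero")
        q = q / mu
    return RateMatrix(alphabet, q, pi)


def transition_probability_values(Q: RateMatrix, t: float) -> np.ndarray:
    """Raw ndarray P(t); used in likelihood inner loops to skip wrapping."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if not np.all(np.isfinite(Q.values)):
        raise ValueError("non-finite entries in rate matrix")
    if Q.is_reversible():
        w, right, left = Q._eigendecomposition()
        p = (right * np.exp(w * t)[None, :]) @ left
    else:  # pragma: no cover - non-reversible generators are not produced here
        p = scipy.linalg.expm(Q.values * t)
    rs = p.sum(axis=1)
    if np.max(np.abs(rs - 1.0)) > 1e-8:
        raise ValueError("matrix exponential produced invalid row sums")
    p = np.clip(p, 0.0, 1.0)
    p /= p.sum(axis=1, keepdims=True)
    return p


def transition_probabilities(Q: RateMatrix, t: float) -> TransitionMatrix:
    """P(t) = expm(Q t) as a validated :class:`TransitionMatrix`."""
    return TransitionMatrix(Q.alphabet, transition_probability_values(Q, t), t)


def _upper_triangle_indices(n: int):
    return np.triu_indices(n, k=1)


def flatten_exchangeabilities(S: ExchangeabilityMatrix) -> np.ndarray:
    """Canonical flattening: row-major upper triangle over the alphabet order.

    Length n(n-1)/2 (190 for proteins).  ``unflatten_exchangeabilities``
    inverts it exactly.
    """
    i, j = _upper_triangle_indices(S.alphabet.size)
    return S.values[i, j].copy()


def unflatten_exchangeabilities(vector: np.ndarray, alphabet: Alphabet) -> ExchangeabilityMatrix:
    vector = np.asarray(vector, dtype=float)
    n = alphabet.size
    expected = n * (n - 1) // 2
    if vector.shape != (expected,):
        raise ValueError(f"expected vector of length {expected}, got {vector.shape}")
    m = np.zeros((n, n))
    i, j = _upper_triangle_indices(n)
    m[i, j] = vector
    m[j, i] = vector
    return ExchangeabilityMatrix(alphabet, m)
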