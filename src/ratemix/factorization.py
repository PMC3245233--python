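"""Non-negative matrix factorization of a library of REV models.

Each fitted specialist model is flattened to its 190-vector (n(n-1)/2
generally) and stacked as a column of the library matrix V.  NNMF finds
non-negative W (basis matrices, one per column) and H (per-alignment
weights) minimising ||V - WH||^2 by Lee-Seung multiplicative updates:
several random initialisations are burned in, the best is refined
further.  Basis columns are finally rescaled to unit mean rate under a
set of reference frequencies (with the compensating rescale of H rows,
leaving WH unchanged) so each column is directly usable as an
exchangeability matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import Alphabet, protein_alphabet
from .matrices import (ExchangeabilityMatrix, FrequencyVector,
                       free_parameter_count, unflatten_exchangeabilities)
from .paml import read_paml_matrix, write_paml_matrix

__all__ = [
    "ModelLibrary", "BasisSet", "CoefficientMatrix", "FactorizationResult",
    "assemble_library", "nnmf", "rank_sweep",
]

_EPS = 1e-12          # denominator floor and absorbing-zero guard
_ORDER_VERSION = "upper-triangle-row-major/ARNDCQEGHILKMFPSTWYV/v1"


@dataclass(frozen=True)
class ModelLibrary:
    """n x m non-negative matrix; columns are flattened specialist REV models."""

    alphabet: Alphabet
    matrix: np.ndarray
    column_ids: tuple[str, ...]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float).copy()
        if m.ndim != 2 or m.shape[0] != free_parameter_count(self.alphabet):
            raise ValueError("library rows must equal the free-parameter count")
        if m.shape[1] != len(self.column_ids):
            raise ValueError("column ids do not match matrix width")
        if np.any(m < 0):
            raise ValueError("library entries must be non-negative")
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    def column_matrix(self, j: int) -> ExchangeabilityMatrix:
        return unflatten_exchangeabilities(self.matrix[:, j], self.alphabet)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=pd.Index(self.alphabet.pair_labels(), name="pair"),
                     columns=list(self.column_ids)).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, alphabet: Alphabet | None = None) -> "ModelLibrary":
        df = pd.read_csv(path, index_col=0)
        if alphabet is None:
            # reconstruct the alphabet from the pair labels: the first n-1
            # rows are pairs of the first symbol with every later symbol
            first = str(df.index[0]).split("-")[0]
            tail = []
            for label in df.index:
                a, _, b = str(label).partition("-")
                if a != first:
                    break
                tail.append(b)
            alphabet = Alphabet(tuple([first] + tail))
        if list(df.index) != alphabet.pair_labels():
            raise ValueError("library CSV pair labels do not match the canonical order")
        return cls(alphabet, df.to_numpy(dtype=float), tuple(df.columns))


@dataclass(frozen=True)
class BasisSet:
    """n x r non-negative basis, columns normalised to unit mean rate."""

    alphabet: Alphabet
    matrix: np.ndarray
    reference_frequencies: FrequencyVector
    normalization: np.ndarray  # per-column scale divided out at normalisation

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float).copy()
        if m.ndim != 2 or m.shape[0] != free_parameter_count(self.alphabet):
            raise ValueError("basis rows must equal the free-parameter count")
        if m.shape[1] < 1:
            raise ValueError("rank must be at least 1")
        if np.any(m < 0):
            raise ValueError("basis entries must be non-negative")
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    @property
    def rank(self) -> int:
        return self.matrix.shape[1]

    def column(self, i: int) -> ExchangeabilityMatrix:
        return unflatten_exchangeabilities(self.matrix[:, i], self.alphabet)

    def save(self, directory: str | Path, seed: int | None = None,
             sse: float | None = None) -> None:
        """Serialize as a directory: per-column PAML files, a combined CSV
        and a flat key-value manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i in range(self.rank):
            write_paml_matrix(self.column(i), directory / f"basis_{i + 1:03d}.dat",
                              freqs=self.reference_frequencies,
                              header=f"basis matrix {i + 1} of {self.rank}")
        pd.DataFrame(self.matrix,
                     index=pd.Index(self.alphabet.pair_labels(), name="pair"),
                     columns=[f"basis_{i + 1}" for i in range(self.rank)]
                     ).to_csv(directory / "basis.csv")
        lines = [f"rank: {self.rank}",
                 f"alphabet: {''.join(self.alphabet.symbols)}",
                 f"ordering: {_ORDER_VERSION}",
                 "normalization: unit mean rate under reference frequencies",
                 "reference_frequencies: " + " ".join(
                     f"{x:.12g}" for x in self.reference_frequencies.values),
                 "column_scales: " + " ".join(f"{x:.12g}" for x in self.normalization)]
        if seed is not None:
            lines.append(f"seed: {seed}")
        if sse is not None:
            lines.append(f"sse: {sse:.12g}")
        (directory / "manifest.txt").write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, directory: str | Path, alphabet: Alphabet | None = None) -> "BasisSet":
        directory = Path(directory)
        manifest = {}
        for line in (directory / "manifest.txt").read_text().splitlines():
            key, _, value = line.partition(":")
            manifest[key.strip()] = value.strip()
        if alphabet is None:
            alphabet = (Alphabet(tuple(manifest["alphabet"]))
                        if "alphabet" in manifest else protein_alphabet())
        rank = int(manifest["rank"])
        ref = FrequencyVector(alphabet, np.array(
            [float(x) for x in manifest["reference_frequencies"].split()]))
        cols = []
        for i in range(rank):
            S, _ = read_paml_matrix(directory / f"basis_{i + 1:03d}.dat", alphabet)
            cols.append(S.flatten())
        scales = np.array([float(x) for x in manifest["column_scales"].split()])
        return cls(alphabet, np.column_stack(cols), ref, scales)


@dataclass(frozen=True)
class CoefficientMatrix:
    """r x m non-negative weights reconstructing the library columns."""

    matrix: np.ndarray
    column_ids: tuple[str, ...]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float).copy()
        if np.any(m < 0):
            raise ValueError("coefficients must be non-negative")
        if m.shape[1] != len(self.column_ids):
            raise ValueError("column ids do not match matrix width")
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix,
                     index=pd.Index([f"basis_{i + 1}" for i in range(self.matrix.shape[0])],
                                    name="basis"),
                     columns=list(self.column_ids)).to_csv(path)


@dataclass(frozen=True)
class FactorizationResult:
    basis: BasisSet
    coefficients: CoefficientMatrix
    sse: float
    sse_trace: np.ndarray
    restarts: int
    seed: int

    @property
    def rank(self) -> int:
        return self.basis.rank


def assemble_library(fits, ids=None) -> ModelLibrary:
    """Stack normalised specialist fits into the library matrix V."""
    fits = list(fits)
    if not fits:
        raise ValueError("empty fit list")
    alphabet = fits[0].S_hat.alphabet
    if any(f.S_hat.alphabet != alphabet for f in fits):
        raise ValueError("mixed alphabets")
    ids = tuple(ids) if ids is not None else tuple(f"aln_{i}" for i in range(len(fits)))
    cols = [f.S_hat.flatten() for f in fits]
    return ModelLibrary(alphabet, np.column_stack(cols), ids)


def _multiplicative_updates(V, W, H, n_iters, record_trace=False,
                            short_circuit_window=10, short_circuit_tol=1e-10):
    """Lee-Seung updates for the Frobenius objective; returns final W, H, trace."""
    trace = []
    previous = None
    stalled = 0
    for _ in range(n_iters):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        np.maximum(H, _EPS, out=H)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        np.maximum(W, _EPS, out=W)
        if record_trace or short_circuit_window:
            sse = float(np.sum((V - W @ H) ** 2))
            if record_trace:
                trace.append(sse)
            if previous is not None:
                rel = abs(previous - sse) / max(previous, _EPS)
                stalled = stalled + 1 if rel < short_circuit_tol else 0
                if stalled >= short_circuit_window:
                    break
            previous = sse
    return W, H, np.array(trace)


def _normalize_basis(alphabet, W, H, reference: FrequencyVector):
    """Scale basis columns to unit mean rate, compensating in H (WH unchanged)."""
    scales = np.empty(W.shape[1])
    for i in range(W.shape[1]):
        S = unflatten_exchangeabilities(W[:, i], alphabet)
        mu = S.mean_rate(reference)
        scales[i] = mu if mu > 0 else 1.0
    W = W / scales[None, :]
    H = H * scales[:, None]
    return W, H, scales


def nnmf(V: ModelLibrary, rank: int, restarts: int = 20, burn_iters: int = 2000,
         refine_iters: int = 5000, seed: int = 0,
         reference_frequencies: FrequencyVector | None = None,
         warm_start: tuple[np.ndarray, np.ndarray] | None = None) -> FactorizationResult:
    """Multiplicative-update NNMF of the model library at a given rank.

    ``restarts`` random initialisations are run for ``burn_iters`` each;
    the lowest-objective candidate is refined for ``refine_iters`` more.
    ``warm_start`` optionally adds one extra candidate (W0, H0)
    initialisation (used by :func:`rank_sweep` to guarantee a monotone
    SSE-vs-rank curve).
    """
    if rank < 1:
        raise ValueError("rank must be at least 1")
    n, m = V.matrix.shape
    if rank > min(n, m):
        warnings.warn(f"rank {rank} exceeds min(n, m) = {min(n, m)}")
    reference = reference_frequencies or FrequencyVector.uniform(V.alphabet)
    rng_master = np.random.default_rng(seed)
    scale = V.matrix.mean() / rank

    candidates = []
    for _ in range(restarts):
        rng = np.random.default_rng(rng_master.integers(2 ** 31))
        W0 = scale * (1.0 - rng.random((n, rank)))   # i.i.d. uniform on (0, 1]
        H0 = 1.0 - rng.random((rank, m))
        candidates.append((W0, H0))
    if warm_start is not None:
        W0 = np.maximum(np.asarray(warm_start[0], dtype=float), _EPS)
        H0 = np.maximum(np.asarray(warm_start[1], dtype=float), _EPS)
        if W0.shape != (n, rank) or H0.shape != (rank, m):
            raise ValueError("warm start shape mismatch")
        candidates.append((W0, H0))

    best = None
    for W0, H0 in candidates:
        W, H, _ = _multiplicative_updates(V.matrix, W0.copy(), H0.copy(), burn_iters)
        sse = float(np.sum((V.matrix - W @ H) ** 2))
        if best is None or sse < best[0]:
            best = (sse, W, H)

    _, W, H = best
    W, H, trace = _multiplicative_updates(V.matrix, W, H, refine_iters,
                                          record_trace=True)
    sse = float(np.sum((V.matrix - W @ H) ** 2))
    W, H, scales = _normalize_basis(V.alphabet, W, H, reference)
    basis = BasisSet(V.alphabet, W, reference, scales)
    coeffs = CoefficientMatrix(H, V.column_ids)
    return FactorizationResult(basis, coeffs, sse, trace, len(candidates), seed)


def rank_sweep(V: ModelLibrary, ranks, restarts: int = 20, burn_iters: int = 2000,
               refine_iters: int = 5000, seed: int = 0,
               reference_frequencies: FrequencyVector | None = None
               ) -> list[FactorizationResult]:
    """One factorization per rank, in increasing rank order.

    Each rank beyond the first adds a warm-start candidate built from the
    previous rank's (denormalised) basis plus one small random column, so
    the best SSE can never increase with rank.
    """
    ranks = sorted(set(int(r) for r in ranks))
    if not ranks or ranks[0] < 1:
        raise ValueError("ranks must be positive")
    rng = np.random.default_rng(seed)
    results = []
    previous: FactorizationResult | None = None
    for r in ranks:
        warm = None
        if previous is not None:
            # normalized basis times compensated coefficients reproduces WH,
            # so this start resumes at (essentially) the previous rank's SSE
            prev_W = previous.basis.matrix
            prev_H = previous.coefficients.matrix
            extra = r - prev_W.shape[1]
            if extra > 0:
                pad_w = 1e-3 * V.matrix.mean() * (1.0 - rng.random((prev_W.shape[0], extra)))
                warm = (np.column_stack([prev_W, pad_w]),
                        np.vstack([prev_H, np.full((extra, prev_H.shape[1]), _EPS)]))
            elif extra == 0:
                warm = (prev_W, prev_H)
            else:
                warm = (prev_W[:, :r], prev_H[:r, :])
        result = nnmf(V, r, restarts=restarts, burn_iters=burn_iters,
                      refine_iters=refine_iters, seed=seed + r,
                      reference_frequencies=reference_frequencies,
                      warm_start=warm)
        results.append(result)
        previous = result
    return results
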