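"""Reading and writing exchangeability matrices in the PAML text dialect.

The dialect is the one consumed by PAML, PhyML and HyPhy for custom
amino-acid models: for an n-state alphabet, n-1 lines of lower-triangular
exchangeabilities (line i holds s_{i,0..i-1}), then one line of n
equilibrium frequencies.  Comment lines starting with ``#`` are ignored
on read and used for provenance on write.  Flattened 190-vectors
round-trip through a single-column CSV keyed by residue pair ("A-R").
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import Alphabet, protein_alphabet
from .matrices import ExchangeabilityMatrix, FrequencyVector

__all__ = ["read_paml_matrix", "write_paml_matrix", "read_vector_csv", "write_vector_csv"]

_PRECISION = 12  # significant digits on write; round-trip tested


def _fmt(x: float) -> str:
    return f"{x:.{_PRECISION}g}"


def read_paml_matrix(path: str | Path, alphabet: Alphabet | None = None
                     ) -> tuple[ExchangeabilityMatrix, FrequencyVector | None]:
    """Parse a PAML-dialect file; the frequency line is optional."""
    alphabet = alphabet or protein_alphabet()
    n = alphabet.size
    tokens: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            tokens.extend(float(tok) for tok in line.split())
    n_tri = n * (n - 1) // 2
    if len(tokens) not in (n_tri, n_tri + n):
        raise ValueError(
            f"expected {n_tri} lower-triangular entries (+{n} optional frequencies), "
            f"got {len(tokens)} numbers")
    m = np.zeros((n, n))
    k = 0
    for i in range(1, n):
        for j in range(i):
            m[i, j] = m[j, i] = tokens[k]
            k += 1
    S = ExchangeabilityMatrix(alphabet, m)
    freqs = None
    if len(tokens) == n_tri + n:
        freqs = FrequencyVector(alphabet, np.array(tokens[n_tri:]) / sum(tokens[n_tri:]))
    return S, freqs


def write_paml_matrix(S: ExchangeabilityMatrix, path: str | Path,
                      freqs: FrequencyVector | None = None,
                      header: str | None = None) -> None:
    """Write lower-triangular entries plus a frequency line.

    If no frequencies are supplied, uniform frequencies are written (the
    dialect requires the line; downstream tools typically override it
    with empirical counts anyway).
    """
    n = S.alphabet.size
    lines = []
    if header:
        lines.extend(f"# {text}" for text in header.splitlines())
    for i in range(1, n):
        lines.append(" ".join(_fmt(S.values[i, j]) for j in range(i)))
    lines.append("")
    f = freqs.values if freqs is not None else np.full(n, 1.0 / n)
    lines.append(" ".join(_fmt(x) for x in f))
    Path(path).write_text("\n".join(lines) + "\n")


def write_vector_csv(vector: np.ndarray, alphabet: Alphabet, path: str | Path,
                     column: str = "exchangeability") -> None:
    """Flattened upper-triangle vector as a pair-labelled single-column CSV."""
    pd.DataFrame({column: np.asarray(vector, dtype=float)},
                 index=pd.Index(alphabet.pair_labels(), name="pair")).to_csv(path)


def read_vector_csv(path: str | Path, alphabet: Alphabet | None = None) -> np.ndarray:
    alphabet = alphabet or protein_alphabet()
    df = pd.read_csv(path, index_col=0)
    expected = alphabet.pair_labels()
    if list(df.index) != expected:
        raise ValueError("vector CSV pair labels do not match the canonical order")
    return df.iloc[:, 0].to_numpy(dtype=float)
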