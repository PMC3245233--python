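"""Physicochemical interpretation of basis matrices.

Two display/diagnostic tools: ordering residues by the Stanfel
physicochemical classes so conserved-property blocks are visible in a
rendered matrix, and correlating each basis column's exchangeabilities
with the absolute difference in a residue property across the 190 pairs.
Substitution rates are expected to correlate negatively with property
differences; significance uses a one-tailed test on Pearson's r at a
per-test alpha of 0.01 (0.05 Bonferroni-corrected across the five
properties), which puts the critical value at -0.16867 for 190 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import t as student_t

from .alphabet import Alphabet, protein_alphabet

__all__ = [
    "PropertyTable", "ClassPartition", "CorrelationReport",
    "property_difference_vector", "correlate_basis",
    "negative_correlation_threshold", "stanfel_order",
    "load_property_table", "load_stanfel_partition", "correlation_report",
    "render_matrix_grayscale",
]

PROPERTY_NAMES = ("chemical composition", "polarity", "volume",
                  "isoelectric point", "hydropathy")


@dataclass(frozen=True)
class PropertyTable:
    alphabet: Alphabet
    properties: dict  # name -> length-20 ndarray in alphabet order

    def __post_init__(self):
        for name, values in self.properties.items():
            v = np.asarray(values, dtype=float)
            if v.shape != (self.alphabet.size,):
                raise ValueError(f"property {name!r} must cover all residues")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"property {name!r} has non-finite values")

    def vector(self, name: str) -> np.ndarray:
        if name not in self.properties:
            raise KeyError(f"unknown property {name!r}")
        return np.asarray(self.properties[name], dtype=float)


@dataclass(frozen=True)
class ClassPartition:
    alphabet: Alphabet
    groups: tuple  # ordered tuple of frozensets of residues

    def __post_init__(self):
        seen = set()
        for group in self.groups:
            if seen & set(group):
                raise ValueError("groups must be disjoint")
            seen |= set(group)
        if seen != set(self.alphabet.symbols):
            raise ValueError("groups must cover the whole alphabet")


@dataclass(frozen=True)
class CorrelationReport:
    table: pd.DataFrame  # columns: basis_index, property, r, threshold, significant

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def load_property_table(path: str | Path | None = None,
                        alphabet: Alphabet | None = None) -> PropertyTable:
    """The shipped table (Grantham composition/polarity/volume, standard pI,
    Kyte-Doolittle hydropathy) or any CSV with the same layout."""
    alphabet = alphabet or protein_alphabet()
    if path is None:
        ref = resources.files("ratemix.data") / "properties.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, comment="#", index_col=0)
    else:
        df = pd.read_csv(path, comment="#", index_col=0)
    df = df.reindex(list(alphabet.symbols))
    if df.isna().any().any():
        raise ValueError("property table missing residues")
    return PropertyTable(alphabet, {c: df[c].to_numpy(dtype=float) for c in df.columns})


def load_stanfel_partition(path: str | Path | None = None,
                           alphabet: Alphabet | None = None) -> ClassPartition:
    alphabet = alphabet or protein_alphabet()
    if path is None:
        ref = resources.files("ratemix.data") / "stanfel.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    groups = tuple(frozenset(row) for row in df["residues"])
    return ClassPartition(alphabet, groups)


def property_difference_vector(table: PropertyTable, property_name: str) -> np.ndarray:
    """|value_i - value_j| for every unordered residue pair, canonical order."""
    values = table.vector(property_name)
    i, j = np.triu_indices(table.alphabet.size, k=1)
    return np.abs(values[i] - values[j])


def correlate_basis(basis_column: np.ndarray, diff: np.ndarray) -> float:
    """Pearson correlation between exchangeabilities and property differences."""
    x = np.asarray(basis_column, dtype=float)
    y = np.asarray(diff, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def negative_correlation_threshold(n_pairs: int, alpha_per_test: float = 0.01) -> float:
    """Critical value for a one-tailed negative correlation test.

    -t_crit / sqrt(df + t_crit^2) with df = n_pairs - 2; about -0.16867
    at n_pairs = 190 and alpha 0.01.
    """
    if n_pairs < 3:
        raise ValueError("need at least 3 pairs")
    if not 0 < alpha_per_test < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n_pairs - 2
    t_crit = float(student_t.ppf(1.0 - alpha_per_test, df))
    return -t_crit / np.sqrt(df + t_crit ** 2)


def stanfel_order(partition: ClassPartition) -> list[str]:
    """Residues ordered by class, alphabetical within class (display only)."""
    out = []
    for group in partition.groups:
        out.extend(sorted(group))
    return out


def correlation_report(basis_matrix: np.ndarray, table: PropertyTable,
                       alpha_per_test: float = 0.01) -> CorrelationReport:
    """Pearson r of every (basis column, property) pair with significance."""
    basis_matrix = np.asarray(basis_matrix, dtype=float)
    n_pairs = basis_matrix.shape[0]
    threshold = negative_correlation_threshold(n_pairs, alpha_per_test)
    rows = []
    for b in range(basis_matrix.shape[1]):
        for name in table.properties:
            r = correlate_basis(basis_matrix[:, b],
                                property_difference_vector(table, name))
            rows.append({"basis_index": b + 1, "property": name, "r": r,
                         "threshold": threshold, "significant": r <= threshold})
    return CorrelationReport(pd.DataFrame(rows))


def render_matrix_grayscale(S_values: np.ndarray, alphabet: Alphabet,
                            order: list[str] | None = None, ax=None):
    """Grayscale matrix image: white is rate zero, black the maximum rate.

    Rows/columns follow ``order`` (e.g. from :func:`stanfel_order`) when
    given.  Requires matplotlib; returns the axes.
    """
    import matplotlib.pyplot as plt

    order = order or list(alphabet.symbols)
    idx = [alphabet.index[ch] for ch in order]
    view = np.asarray(S_values)[np.ix_(idx, idx)]
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(view, cmap="gray_r", vmin=0.0, vmax=view.max() or 1.0)
    ax.set_xticks(range(len(order)), order, fontsize=6)
    ax.set_yticks(range(len(order)), order, fontsize=6)
    return ax
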