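"""Protein multiple sequence alignments and empirical residue frequencies.

Readers accept FASTA and PHYLIP (sequential or interleaved, relaxed
names) through Biopython.  Equilibrium frequencies for likelihood work
are the empirical per-residue counts over all sequences and sites, with
gaps and ambiguity codes excluded, floored at a small constant and
renormalised so no state is ever absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import Alphabet, protein_alphabet
from .matrices import FrequencyVector, FREQ_FLOOR

__all__ = ["Alignment", "empirical_frequencies", "read_alignment", "write_alignment"]


@dataclass(frozen=True)
class Alignment:
    """Equal-length residue strings with ordered sequence identifiers."""

    names: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in length")
        if len(self.rows) == 0:
            raise ValueError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows must all have the same length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def encode(self, alphabet: Alphabet) -> np.ndarray:
        """Integer-coded matrix (n_sequences x n_sites); missing data is -1.

        Cached per (alignment, alphabet): likelihood optimisers evaluate
        the same alignment thousands of times.  The returned array is
        read-only.
        """
        return _encode_cached(self, alphabet)

    def subset_sites(self, sites) -> "Alignment":
        sites = list(sites)
        return Alignment(self.names, tuple("".join(r[s] for s in sites) for r in self.rows))


@lru_cache(maxsize=64)
def _encode_cached(alignment: "Alignment", alphabet: Alphabet) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int16)
    for symbol, i in alphabet.index.items():
        lut[ord(symbol)] = i
        lut[ord(symbol.lower())] = i
    raw = np.frombuffer("".join(alignment.rows).encode("latin-1"), dtype=np.uint8)
    out = lut[raw].reshape(alignment.n_sequences, alignment.n_sites)
    out.flags.writeable = False
    return out


def empirical_frequencies(alignment: Alignment, alphabet: Alphabet | None = None,
                          floor: float = FREQ_FLOOR) -> FrequencyVector:
    """Residue frequencies counted across all sites and sequences.

    Gaps and ambiguity codes are ignored; counts are floored at ``floor``
    after normalisation and renormalised, so every state has positive
    frequency even when absent from the alignment.
    """
    alphabet = alphabet or protein_alphabet()
    coded = alignment.encode(alphabet)
    counts = np.bincount(coded[coded >= 0].ravel(), minlength=alphabet.size).astype(float)
    if counts.sum() == 0:
        raise ValueError("alignment contains no countable residues")
    return FrequencyVector.from_counts(alphabet, counts, floor=floor)


def _to_biopython(alignment: Alignment) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(alignment.names, alignment.rows)
    )


def _from_biopython(msa: MultipleSeqAlignment) -> Alignment:
    return Alignment(tuple(rec.id for rec in msa), tuple(str(rec.seq) for rec in msa))


def read_alignment(path: str | Path, fmt: str | None = None) -> Alignment:
    """Read FASTA or PHYLIP (sequential/interleaved, relaxed names).

    With ``fmt=None`` the format is inferred: FASTA if the file starts
    with ``>``, otherwise the PHYLIP variants are tried in turn.
    """
    path = Path(path)
    if fmt is not None:
        return _from_biopython(AlignIO.read(str(path), fmt))
    head = path.read_text().lstrip()[:1]
    candidates = (
        ["fasta"] if head == ">"
        else ["phylip-relaxed", "phylip", "phylip-sequential"]
    )
    errors = []
    for candidate in candidates:
        try:
            return _from_biopython(AlignIO.read(str(path), candidate))
        except Exception as exc:  # malformed for this dialect; try the next
            errors.append(f"{candidate}: {exc}")
    raise ValueError(f"could not parse alignment {path}: " + "; ".join(errors))


def write_alignment(alignment: Alignment, path: str | Path, fmt: str = "fasta") -> None:
    """Write FASTA (default) or a PHYLIP dialect understood by Biopython."""
    AlignIO.write(_to_biopython(alignment), str(Path(path)), fmt)
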