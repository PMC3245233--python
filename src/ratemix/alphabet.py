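"""Residue alphabets.

All matrix and vector types in the package carry an :class:`Alphabet` and
refuse to mix states from different alphabets.  The canonical protein
alphabet uses the fixed residue order ``ARNDCQEGHILKMFPSTWYV`` — the
de-facto ordering of PAML-style empirical rate-matrix files — so that
flattened parameter vectors and on-disk matrices are interoperable with
standard phylogenetics tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

PROTEIN_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Characters treated as fully missing data (gaps and ambiguity codes).
MISSING = set("-.?XBZJ*")


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of residue one-letter codes."""

    symbols: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise ValueError("alphabet needs at least 2 states")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        object.__setattr__(self, "index", {s: i for i, s in enumerate(self.symbols)})

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def is_missing(self, ch: str) -> bool:
        """Gaps, ambiguity codes and anything outside the alphabet count as missing."""
        return ch.upper() not in self.index

    def pair_labels(self) -> list[str]:
        """Labels like ``A-R`` for each unordered pair in canonical order."""
        syms = self.symbols
        return [f"{syms[i]}-{syms[j]}" for i in range(self.size) for j in range(i + 1, self.size)]


def protein_alphabet() -> Alphabet:
    """The canonical 20-state amino-acid alphabet."""
    return Alphabet(tuple(PROTEIN_ORDER))


def toy_alphabet(n: int) -> Alphabet:
    """A small n-state alphabet (first n protein letters) for tests and demos."""
    if not 2 <= n <= 20:
        raise ValueError("toy alphabet size must be in [2, 20]")
    return Alphabet(tuple(PROTEIN_ORDER[:n]))


def check_same_alphabet(*objs) -> Alphabet:
    alphabets = [o.alphabet for o in objs]
    first = alphabets[0]
    for a in alphabets[1:]:
        if a != first:
            raise ValueError("mixed alphabets")
    return first
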