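"""SMILES attribute extraction.

A molecule written as a SMILES line is decomposed into three attribute
families that together feed the optimal descriptor:

* ``Sk`` — single SMILES atoms: the tokens of the line that cannot be
  split further (one character, a two-letter organic-subset halogen
  ``Cl``/``Br``, a complete bracket expression ``[...]``, or a ``%nn``
  ring closure);
* ``SSk`` — pairs of SMILES atoms adjacent in the line, stored under a
  canonical orientation;
* FLS — fragments of local symmetry: palindromic raw-character windows
  of the forms XYX, XYYX and XYZYX, counted per molecule and encoded as
  count codes ``[xyxN]``, ``[xyyxN]``, ``[xyzyxN]``.

No chemistry-aware parsing happens here: the SMILES line is treated as a
string, exactly as the correlation-weight formalism requires.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterator

from .errors import MalformedInputError

__all__ = [
    "TokenSequence",
    "MoleculeAttributes",
    "tokenize",
    "extract_sk",
    "extract_ssk",
    "extract_fls",
    "fls_codes",
    "pair_label",
    "pad_label",
]

#: two-character tokens recognized outside brackets
_TWO_CHAR = ("Cl", "Br")

#: display width of attribute labels in tabular reports
LABEL_WIDTH = 12


@dataclass(frozen=True)
class TokenSequence:
    """An ordered list of SMILES atoms parsed from one SMILES string.

    Invariant: ``"".join(tokens) == raw``.
    """

    raw: str
    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)


@dataclass(frozen=True)
class MoleculeAttributes:
    """The attribute multiset of one molecule.

    ``sk`` and ``ssk`` carry multiplicities; the three FLS count codes
    appear exactly once each (one code per FLS family per molecule).
    """

    sk: Counter
    ssk: Counter
    fls: tuple[str, str, str]

    @classmethod
    def from_smiles(cls, smiles: str) -> "MoleculeAttributes":
        ts = tokenize(smiles)
        return cls(
            sk=extract_sk(ts),
            ssk=extract_ssk(ts),
            fls=fls_codes(*extract_fls(smiles)),
        )

    def iter_attributes(self, use_fls: bool = True) -> Iterator[tuple[str, int]]:
        """Yield ``(label, multiplicity)`` over all attributes of the molecule."""
        yield from self.sk.items()
        yield from self.ssk.items()
        if use_fls:
            for code in self.fls:
                yield code, 1


def tokenize(smiles: str) -> TokenSequence:
    """Split a SMILES string into SMILES atoms.

    Tokens are: complete bracket expressions ``[...]``, the two-letter
    elements ``Cl`` and ``Br``, ``%nn`` two-digit ring closures, and
    otherwise single characters (including digits, bonds, parentheses and
    any unknown character).  Chemical validity is not checked.

    Raises
    ------
    MalformedInputError
        If a ``[`` has no matching ``]``; the message names the position.
    """
    tokens: list[str] = []
    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i + 1)
            if j < 0:
                raise MalformedInputError(
                    f"unbalanced '[' at position {i} in {smiles!r}"
                )
            tokens.append(smiles[i : j + 1])
            i = j + 1
        elif smiles[i : i + 2] in _TWO_CHAR:
            tokens.append(smiles[i : i + 2])
            i += 2
        elif ch == "%" and smiles[i + 1 : i + 3].isdigit() and i + 3 <= n:
            tokens.append(smiles[i : i + 3])
            i += 3
        else:
            tokens.append(ch)
            i += 1
    return TokenSequence(raw=smiles, tokens=tuple(tokens))


def extract_sk(ts: TokenSequence) -> Counter:
    """One entry per token occurrence, multiplicity preserved."""
    return Counter(ts.tokens)


def pair_label(a: str, b: str) -> str:
    """Canonical label of an adjacent token pair.

    The lexicographically greater token (byte order) comes first, padded
    to a 4-character field with dots, so (``=``, ``O``) and (``O``, ``=``)
    both map to ``"O...="``.
    """
    hi, lo = (a, b) if a >= b else (b, a)
    return hi.ljust(4, ".") + lo


def pad_label(label: str) -> str:
    """Pad an attribute label with dots to the fixed display width."""
    return label.ljust(LABEL_WIDTH, ".")


def extract_ssk(ts: TokenSequence) -> Counter:
    """Canonical labels of all adjacent token pairs, with multiplicity.

    For a sequence of n tokens there are exactly n - 1 pairs.
    """
    toks = ts.tokens
    return Counter(pair_label(a, b) for a, b in zip(toks, toks[1:]))


def extract_fls(smiles: str) -> tuple[int, int, int]:
    """Count fragments of local symmetry in the raw character string.

    Windows slide over single characters (FLS uses one-character SMILES
    atoms only, so multi-character tokens are scanned as their raw
    characters, brackets and digits included):

    * XYX   — positions i with ``s[i] == s[i+2]``;
    * XYYX  — positions i with ``s[i] == s[i+3]`` and ``s[i+1] == s[i+2]``;
    * XYZYX — positions i with ``s[i] == s[i+4]`` and ``s[i+1] == s[i+3]``
      (Z unconstrained; Z may equal X).

    Overlapping windows all count.
    """
    s = smiles
    n = len(s)
    xyx = sum(1 for i in range(n - 2) if s[i] == s[i + 2])
    xyyx = sum(
        1 for i in range(n - 3) if s[i] == s[i + 3] and s[i + 1] == s[i + 2]
    )
    xyzyx = sum(
        1 for i in range(n - 4) if s[i] == s[i + 4] and s[i + 1] == s[i + 3]
    )
    return xyx, xyyx, xyzyx


def fls_codes(xyx: int, xyyx: int, xyzyx: int) -> tuple[str, str, str]:
    """Map the three FLS counts to their per-molecule attribute codes."""
    return (f"[xyx{xyx}]", f"[xyyx{xyyx}]", f"[xyzyx{xyzyx}]")
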