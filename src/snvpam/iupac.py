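"""IUPAC degenerate nucleotide alphabet: expansions, complements, matching.

PAM motifs are written in the 15-letter IUPAC nucleotide code (N = any base,
R = purine, Y = pyrimidine, ...). Matching a motif against genomic sequence
reduces to per-symbol set membership; reverse-strand matching reduces to
forward matching of the symbol-wise complemented, reversed motif.
"""

from __future__ import annotations

__all__ = [
    "IUPAC_CODES",
    "COMPLEMENT",
    "BASES",
    "expand",
    "iupac_match",
    "complement",
    "reverse_complement",
]

#: Expansion of each IUPAC symbol into the set of unambiguous bases it denotes.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "M": frozenset("AC"),
    "R": frozenset("AG"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "V": frozenset("ACG"),
    "H": frozenset("ACT"),
    "D": frozenset("AGT"),
    "B": frozenset("CGT"),
    "N": frozenset("ACGT"),
}

#: Watson-Crick complement extended to ambiguity codes (W, S, N are self-complementary).
COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "M": "K", "K": "M", "R": "Y", "Y": "R",
    "W": "W", "S": "S",
    "V": "B", "B": "V", "H": "D", "D": "H",
    "N": "N",
}

#: The four unambiguous bases.
BASES: tuple[str, ...] = ("A", "C", "G", "T")


class InvalidSymbolError(ValueError):
    """A character is not a valid IUPAC nucleotide code."""


def validate_pattern(pattern: str) -> str:
    """Return ``pattern`` uppercased, or raise listing the first bad character."""
    if not pattern:
        raise InvalidSymbolError("empty pattern")
    up = pattern.upper()
    for i, sym in enumerate(up):
        if sym not in IUPAC_CODES:
            raise InvalidSymbolError(
                f"invalid IUPAC symbol {sym!r} at position {i + 1} in pattern {pattern!r}"
            )
    return up


def expand(symbol: str) -> frozenset[str]:
    """The set of unambiguous bases an IUPAC symbol stands for."""
    try:
        return IUPAC_CODES[symbol.upper()]
    except KeyError:
        raise InvalidSymbolError(f"invalid IUPAC symbol {symbol!r}") from None


def iupac_match(symbol: str, base: str) -> bool:
    """True iff ``base`` (A/C/G/T) belongs to the expansion of ``symbol``."""
    b = base.upper()
    if b not in IUPAC_CODES or len(IUPAC_CODES[b]) != 1:
        raise InvalidSymbolError(f"not an unambiguous base: {base!r}")
    return b in expand(symbol)


def complement(symbol: str) -> str:
    """Symbol-wise IUPAC complement (an involution)."""
    try:
        return COMPLEMENT[symbol.upper()]
    except KeyError:
        raise InvalidSymbolError(f"invalid IUPAC symbol {symbol!r}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement of a plain or degenerate nucleotide string."""
    return "".join(complement(s) for s in reversed(seq))
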