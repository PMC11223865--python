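"""SNV-derived PAM search: the allele-discrimination protocol.

A single-nucleotide variant can *create* a PAM that is present on the mutant
allele but absent from the wild type, letting a Cas nuclease cut the
disease-causing allele while sparing the healthy one. For each candidate PAM
motif of length L the search window spans L bases on each side of the variant
(2L+1 in total, clipped at contig ends): the flanking context matters because
a motif placement that also fits the wild-type sequence anywhere nearby — in
either orientation — defeats allele selectivity. Canonical counter-example:
for the single-mismatch motif NG and an N→G variant, a downstream G lets the
motif sit with its N on the variant and match both alleles, so no hit is
reported.

A motif *qualifies* for a variant iff it matches the mutant window in at least
one placement (forward or reverse strand) and matches the wild-type window in
no placement on either strand. Every qualifying mutant placement is emitted as
a :class:`PamHit`. A hit is additionally flagged *discriminating-specific*
("*") when the motif symbol aligned with the variant is a fully specific base
equal to the mutant nucleotide — e.g. a C→G variant is better served by a
motif demanding G at that position than by one accepting R.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .iupac import BASES, expand, reverse_complement, validate_pattern
from .registry import PamPattern, Registry, selectivity_score

__all__ = [
    "Variant",
    "Window",
    "PamHit",
    "ReferenceMismatchError",
    "build_window",
    "pattern_matches_at",
    "find_pattern_placements",
    "pattern_qualifies",
    "find_snv_derived_pams",
    "classify_discrimination",
    "rank_hits",
]

logger = logging.getLogger(__name__)


class ReferenceMismatchError(ValueError):
    """The variant's stated reference base disagrees with the FASTA."""


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide substitution on a named reference sequence.

    ``position`` is 1-based, as in VCF and HGVS; internal window arithmetic is
    0-based half-open.
    """

    sequence_id: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        ref, alt = self.ref.upper(), self.alt.upper()
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)
        if ref not in BASES or alt not in BASES:
            raise ValueError(
                f"only single-base substitutions over A/C/G/T are supported, "
                f"got {self.ref!r}>{self.alt!r}"
            )
        if ref == alt:
            raise ValueError(f"ref and alt are identical ({ref}) at {self.sequence_id}:{self.position}")
        if self.position < 1:
            raise ValueError(f"position must be 1-based positive, got {self.position}")

    def __str__(self) -> str:
        return f"{self.sequence_id}:g.{self.position}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class Window:
    """Mutation-centred search window: wild-type and mutant sequence."""

    wt_seq: str
    mut_seq: str
    centre_index: int

    def __post_init__(self) -> None:
        diffs = [i for i, (a, b) in enumerate(zip(self.wt_seq, self.mut_seq)) if a != b]
        if len(self.wt_seq) != len(self.mut_seq) or diffs != [self.centre_index]:
            raise ValueError("wt and mut window must differ exactly at the centre index")

    def __len__(self) -> int:
        return len(self.wt_seq)


def build_window(reference: str, variant: Variant, L: int) -> Window:
    """Window of up to L bases either side of the variant (length ≤ 2L+1).

    Clipped without error at sequence boundaries. Raises
    :class:`ReferenceMismatchError` if the reference base at the variant
    position is not ``variant.ref``.
    """
    if L < 1:
        raise ValueError("window half-width L must be >= 1")
    seq = reference.upper()
    pos0 = variant.position - 1
    if not 0 <= pos0 < len(seq):
        raise ValueError(
            f"variant position {variant.position} outside reference of length {len(seq)}"
        )
    if seq[pos0] != variant.ref:
        raise ReferenceMismatchError(
            f"reference has {seq[pos0]!r} at position {variant.position}, "
            f"variant states ref {variant.ref!r}"
        )
    start = max(0, pos0 - L)
    end = min(len(seq), pos0 + L + 1)
    wt = seq[start:end]
    centre = pos0 - start
    mut = wt[:centre] + variant.alt + wt[centre + 1:]
    return Window(wt_seq=wt, mut_seq=mut, centre_index=centre)


def pattern_matches_at(symbols: str, seq: str, start: int) -> bool:
    """True iff the motif fits ``seq`` at offset ``start`` entirely.

    Any window character outside A/C/G/T disqualifies placements covering it
    (ambiguity in the reference cannot guarantee allele exclusivity).
    """
    if start < 0 or start + len(symbols) > len(seq):
        return False
    for sym, base in zip(symbols, seq[start:start + len(symbols)]):
        if base not in "ACGT" or base not in expand(sym):
            return False
    return True


def find_pattern_placements(symbols: str, seq: str) -> list[int]:
    """All start offsets at which the motif matches ``seq``."""
    return [s for s in range(len(seq) - len(symbols) + 1) if pattern_matches_at(symbols, seq, s)]


def _warn_ambiguous(window: Window) -> None:
    bad = sorted({c for c in window.wt_seq if c not in "ACGT"})
    if bad:
        warnings.warn(
            f"window contains non-ACGT character(s) {bad}; placements covering "
            "them are disqualified",
            stacklevel=3,
        )


def pattern_qualifies(pattern: PamPattern | str, window: Window) -> list[tuple[str, int]]:
    """Placements making a motif allele-selective within a window.

    Returns the list of qualifying mutant placements as ``(orientation,
    start)`` pairs — empty when the motif matches the wild-type window in any
    placement on either strand, or matches the mutant nowhere.
    """
    symbols = pattern.symbols if isinstance(pattern, PamPattern) else validate_pattern(pattern)
    rc = reverse_complement(symbols)
    _warn_ambiguous(window)
    if find_pattern_placements(symbols, window.wt_seq) or find_pattern_placements(rc, window.wt_seq):
        return []
    hits = [("forward", s) for s in find_pattern_placements(symbols, window.mut_seq)]
    hits += [("reverse", s) for s in find_pattern_placements(rc, window.mut_seq)]
    return hits


@dataclass(frozen=True)
class PamHit:
    """One qualifying mutant-exclusive PAM placement."""

    enzyme_name: str
    pattern: PamPattern
    less_preferred: bool
    orientation: str  # "forward" | "reverse"
    offset: int  # placement start relative to the variant position
    matched_sequence: str
    discriminating_specific: bool
    score: float
    variant: Variant | None = field(default=None, compare=False)

    @property
    def applied_symbols(self) -> str:
        """Motif as matched against the forward-strand window."""
        return (
            self.pattern.symbols
            if self.orientation == "forward"
            else reverse_complement(self.pattern.symbols)
        )


def classify_discrimination(orientation: str, pattern: PamPattern, offset: int, alt: str) -> bool:
    """"*" flag: is the motif symbol over the variant a fully specific base
    equal to the mutant nucleotide on the matched strand?

    ``offset`` is the placement start relative to the variant; the variant
    falls at motif index ``-offset``. Raises if the placement does not cover
    the variant.
    """
    symbols = pattern.symbols if orientation == "forward" else reverse_complement(pattern.symbols)
    idx = -offset
    if not 0 <= idx < len(symbols):
        raise ValueError("placement does not overlap the variant position")
    sym = symbols[idx]
    return sym in "ACGT" and sym == alt.upper()


def _evaluate_pattern(
    reference: str,
    variant: Variant,
    enzyme_name: str,
    pattern: PamPattern,
    less_preferred: bool,
    weight_table,
) -> list[PamHit]:
    window = build_window(reference, variant, len(pattern))
    hits = []
    for orientation, start in pattern_qualifies(pattern, window):
        offset = start - window.centre_index
        matched = window.mut_seq[start:start + len(pattern)]
        flag = classify_discrimination(orientation, pattern, offset, variant.alt)
        hits.append(
            PamHit(
                enzyme_name=enzyme_name,
                pattern=pattern,
                less_preferred=less_preferred,
                orientation=orientation,
                offset=offset,
                matched_sequence=matched,
                discriminating_specific=flag,
                score=selectivity_score(pattern, weight_table),
                variant=variant,
            )
        )
    return hits


def find_snv_derived_pams(
    reference: str,
    variant: Variant,
    registry: Registry,
    include_less_preferred: bool = False,
    strict_promiscuity: bool = False,
) -> list[PamHit]:
    """All qualifying SNV-derived PAM placements across a registry, ranked.

    Each pattern (primary, plus less-preferred when enabled) is evaluated
    independently in its own 2L+1 window. With ``strict_promiscuity`` an
    enzyme's hits are dropped when any of its *other* annotated motifs matches
    the wild type in that motif's own window — a guard against enzymes whose
    alternate PAM preferences would still cut the healthy allele.
    """
    all_hits: list[PamHit] = []
    for enzyme in registry:
        enzyme_hits: list[PamHit] = []
        for pattern, lp in enzyme.patterns(include_less_preferred=True):
            if lp and not include_less_preferred:
                continue
            enzyme_hits.extend(
                _evaluate_pattern(reference, variant, enzyme.name, pattern, lp, registry.weight_table)
            )
        if enzyme_hits and strict_promiscuity:
            wt_promiscuous = False
            for pattern, _ in enzyme.patterns(include_less_preferred=True):
                window = build_window(reference, variant, len(pattern))
                rc = reverse_complement(pattern.symbols)
                if find_pattern_placements(pattern.symbols, window.wt_seq) or find_pattern_placements(
                    rc, window.wt_seq
                ):
                    wt_promiscuous = True
                    break
            if wt_promiscuous:
                logger.info(
                    "strict mode: dropping %d hit(s) for %s (alternate motif matches wild type)",
                    len(enzyme_hits),
                    enzyme.name,
                )
                continue
        all_hits.extend(enzyme_hits)
    return rank_hits(all_hits)


def rank_hits(hits: list[PamHit]) -> list[PamHit]:
    """Order hits by descending selectivity score; ties broken by the
    discrimination flag (flagged first), then enzyme name, then placement."""
    return sorted(
        hits,
        key=lambda h: (
            -h.score,
            not h.discriminating_specific,
            h.enzyme_name,
            h.orientation,
            h.offset,
        ),
    )
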