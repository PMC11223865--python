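"""Cas enzyme / PAM pattern registry and the selectivity scoring scheme.

The packaged registry covers 39 class-2 Cas nucleases (types II and V) with
experimentally annotated PAM preferences: 22 natural orthologs and 17
engineered PAM-relaxed or PAM-shifted variants. Several enzymes additionally
recognize "less-preferred" alternative motifs with reduced efficiency; these
are stored as separate flagged patterns, never merged into the primary one.

Each PAM pattern carries a *selectivity score*: the sum over its IUPAC symbols
of a specificity weight (N = 0.25; V/H/D/B = 0.33; M/R/W/S/Y/K = 0.50;
A/C/G/T = 1.00). Longer, more specific motifs score higher; the score orders
candidate enzymes when several can target the same SNV-derived PAM.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .iupac import IUPAC_CODES, validate_pattern

__all__ = [
    "DEFAULT_WEIGHTS",
    "PamPattern",
    "CasEnzyme",
    "Registry",
    "RegistryError",
    "load_registry",
    "add_custom_cas",
    "selectivity_score",
]

#: Per-symbol specificity weights: fully specific bases count 1.00, two-fold
#: degenerate symbols 0.50, three-fold 0.33, N 0.25.
DEFAULT_WEIGHTS: dict[str, float] = {
    **{s: 1.00 for s in "ACGT"},
    **{s: 0.50 for s in "MRWSYK"},
    **{s: 0.33 for s in "VHDB"},
    "N": 0.25,
}


class RegistryError(ValueError):
    """Malformed registry data or an operation violating registry invariants."""


def selectivity_score(pattern: "PamPattern | str", weight_table: Mapping[str, float] | None = None) -> float:
    """Sum of per-symbol specificity weights of a PAM pattern.

    Rewards both motif length and base specificity, e.g. NNGRRT (3.50)
    outranks NG (1.25).
    """
    weights = DEFAULT_WEIGHTS if weight_table is None else weight_table
    symbols = pattern.symbols if isinstance(pattern, PamPattern) else validate_pattern(pattern)
    missing = [s for s in symbols if s not in weights]
    if missing:
        raise RegistryError(f"no weight for symbol(s) {sorted(set(missing))}")
    return sum(weights[s] for s in symbols)


@dataclass(frozen=True)
class PamPattern:
    """An ordered IUPAC motif, e.g. ``NGG`` or ``TTTV``."""

    symbols: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", validate_pattern(self.symbols))

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols

    @property
    def score(self) -> float:
        return selectivity_score(self)


@dataclass(frozen=True)
class CasEnzyme:
    """One registry entry: a Cas nuclease and its annotated PAM preferences."""

    name: str
    organism: str
    source: str  # "natural" | "engineered"
    subtype: str
    primary_pattern: PamPattern
    uniprot_id: str | None = None
    variant: str | None = None
    less_preferred_patterns: tuple[PamPattern, ...] = ()
    structure_ids: tuple[str, ...] = ()
    user_supplied: bool = False

    def __post_init__(self) -> None:
        if self.source not in ("natural", "engineered"):
            raise RegistryError(
                f"{self.name}: source must be 'natural' or 'engineered', got {self.source!r}"
            )
        if self.source == "engineered" and not (self.variant or "Cas" in self.name):
            raise RegistryError(f"{self.name}: engineered entry lacks a variant tag")
        if self.source == "natural" and not self.organism:
            raise RegistryError(f"{self.name}: natural entry lacks an organism")

    def patterns(self, include_less_preferred: bool = False) -> Iterator[tuple[PamPattern, bool]]:
        """Yield (pattern, is_less_preferred) pairs for this enzyme."""
        yield self.primary_pattern, False
        if include_less_preferred:
            for p in self.less_preferred_patterns:
                yield p, True


_COLUMNS = [
    "name", "organism", "uniprot_id", "variant", "source",
    "subtype", "pam", "less_preferred", "structures",
]


@dataclass(frozen=True)
class Registry:
    """An immutable, queryable collection of Cas enzymes."""

    enzymes: tuple[CasEnzyme, ...]
    weight_table: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        names = [e.name for e in self.enzymes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RegistryError(f"duplicate enzyme name(s): {sorted(dupes)}")
        uncovered = set(IUPAC_CODES) - set(self.weight_table)
        if uncovered:
            raise RegistryError(f"weight table misses IUPAC code(s): {sorted(uncovered)}")

    def __len__(self) -> int:
        return len(self.enzymes)

    def __iter__(self) -> Iterator[CasEnzyme]:
        return iter(self.enzymes)

    def get(self, name: str) -> CasEnzyme:
        for e in self.enzymes:
            if e.name == name:
                return e
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.enzymes)

    @property
    def structure_ids(self) -> tuple[str, ...]:
        """All structure accessions across entries, in registry order."""
        return tuple(sid for e in self.enzymes for sid in e.structure_ids)

    def to_tsv(self, path: str | Path) -> None:
        """Serialize in the same tabular dialect ``load_registry`` reads."""
        lines = ["\t".join(_COLUMNS)]
        for e in self.enzymes:
            lines.append("\t".join([
                e.name,
                e.organism or "-",
                e.uniprot_id or "-",
                e.variant or "-",
                e.source,
                e.subtype or "-",
                e.primary_pattern.symbols,
                ";".join(p.symbols for p in e.less_preferred_patterns) or "-",
                ";".join(e.structure_ids) or "-",
            ]))
        Path(path).write_text("\n".join(lines) + "\n")


def _parse_row(line_no: int, fields: list[str]) -> CasEnzyme:
    if len(fields) != len(_COLUMNS):
        raise RegistryError(
            f"line {line_no}: expected {len(_COLUMNS)} tab-separated fields, got {len(fields)}"
        )
    row = dict(zip(_COLUMNS, (f.strip() for f in fields)))

    def opt(key: str) -> str | None:
        return None if row[key] in ("-", "") else row[key]

    def split(key: str) -> tuple[str, ...]:
        val = opt(key)
        return tuple(v.strip() for v in val.split(";")) if val else ()

    try:
        return CasEnzyme(
            name=row["name"],
            organism=row["organism"] if row["organism"] != "-" else "",
            uniprot_id=opt("uniprot_id"),
            variant=opt("variant"),
            source=row["source"],
            subtype=row["subtype"],
            primary_pattern=PamPattern(row["pam"]),
            less_preferred_patterns=tuple(PamPattern(p) for p in split("less_preferred")),
            structure_ids=split("structures"),
        )
    except ValueError as exc:
        raise RegistryError(f"line {line_no} (field data): {exc}") from exc


def load_registry(source: str | Path | None = None) -> Registry:
    """Load the packaged default registry, or a user registry in the same
    tab-separated dialect (one enzyme per row; ``;``-joined multi-valued
    columns; ``-`` for empty; ``#`` comment lines ignored)."""
    if source is None:
        text = (importlib.resources.files("snvpam") / "data" / "cas_registry.tsv").read_text()
    else:
        text = Path(source).read_text()
    enzymes: list[CasEnzyme] = []
    header_seen = False
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if not header_seen:
            if [f.strip() for f in fields] != _COLUMNS:
                raise RegistryError(
                    f"line {line_no}: bad header, expected columns {_COLUMNS}"
                )
            header_seen = True
            continue
        enzymes.append(_parse_row(line_no, fields))
    if not header_seen:
        raise RegistryError("registry file has no header row")
    return Registry(enzymes=tuple(enzymes))


def add_custom_cas(
    registry: Registry,
    name: str,
    pattern_string: str,
    structure_id: str | None = None,
    *,
    organism: str = "user-supplied",
    less_preferred: Iterable[str] = (),
    subtype: str = "custom",
) -> Registry:
    """Return a new registry extended with a user-supplied enzyme.

    The packaged entries are unchanged; the new entry is flagged
    ``user_supplied`` and classified as engineered.
    """
    if name in registry:
        raise RegistryError(f"duplicate enzyme name: {name!r}")
    enzyme = CasEnzyme(
        name=name,
        organism=organism,
        source="engineered",
        variant="custom",
        subtype=subtype,
        primary_pattern=PamPattern(pattern_string),
        less_preferred_patterns=tuple(PamPattern(p) for p in less_preferred),
        structure_ids=(structure_id,) if structure_id else (),
        user_supplied=True,
    )
    return replace(registry, enzymes=registry.enzymes + (enzyme,))
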