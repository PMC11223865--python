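"""Batch targetability screening and synthetic variant-set generation.

Screening a variant cohort answers two questions the single-variant finder
cannot: what fraction of variants of each substitution class (ref base ->
alt base) gains at least one allele-discriminating PAM, and how the
qualification events distribute over the Cas repertoire. The counting unit
for coverage is one (variant, enzyme, pattern) qualification event —
multiple placements of the same motif at one variant collapse to a single
event, so trivially overlapping windows are not double-counted.

The synthetic generator builds seeded random references with planted SNVs,
optionally constrained by a context rule (e.g. plant wild-type ``TA`` and
mutate the A to G, guaranteeing a ``TG``-creating variant) so tests know the
ground truth by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .finder import Variant, build_window, find_snv_derived_pams, pattern_qualifies
from .registry import Registry

__all__ = [
    "TargetabilityMatrix",
    "CasCoverage",
    "ScreenResult",
    "screen",
    "PlantRule",
    "generate_fixture_variants",
]

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class TargetabilityMatrix:
    """4x4 substitution-class grid: counts screened/targetable and percentages."""

    targetable: pd.DataFrame  # ref base (rows) x alt base (cols), counts
    screened: pd.DataFrame  # same shape, counts

    @property
    def percentages(self) -> pd.DataFrame:
        """Percent of screened variants of each class with >= 1 SNV-derived PAM
        (NaN where the class was never observed; diagonal undefined)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.targetable / self.screened
        return pct

    @property
    def overall_percentage(self) -> float:
        total = self.screened.to_numpy().sum()
        return float(100.0 * self.targetable.to_numpy().sum() / total) if total else float("nan")


@dataclass(frozen=True)
class CasCoverage:
    """Per-enzyme share of all qualification events, with breakdown columns."""

    table: pd.DataFrame  # index enzyme; columns events, share_pct, pam, pam_length, source

    @property
    def total_events(self) -> int:
        return int(self.table["events"].sum())


@dataclass(frozen=True)
class ScreenResult:
    targetability: TargetabilityMatrix
    coverage: CasCoverage
    n_screened: int
    n_targetable: int
    n_skipped: int
    natural_share_pct: float = field(default=float("nan"))
    engineered_share_pct: float = field(default=float("nan"))


def _empty_grid() -> pd.DataFrame:
    return pd.DataFrame(0, index=list(_BASES), columns=list(_BASES), dtype=int)


def screen(
    variants: list[Variant],
    reference: dict[str, str] | str,
    registry: Registry,
    include_less_preferred: bool = False,
) -> ScreenResult:
    """Aggregate finder output over a cohort.

    ``reference`` is a dict of sequences keyed by id (or a single sequence
    used for every variant). A variant is *targetable* iff at least one
    enzyme/pattern qualifies. Variants whose reference is missing or whose
    stated ref base mismatches are skipped and counted, never fatal.
    """
    refs = reference if isinstance(reference, dict) else None
    targetable, screened = _empty_grid(), _empty_grid()
    events: dict[str, int] = {}
    n_targetable = n_skipped = 0
    for variant in variants:
        seq = refs.get(variant.sequence_id) if refs is not None else reference
        if seq is None:
            n_skipped += 1
            logger.warning("no reference sequence %r; variant skipped", variant.sequence_id)
            continue
        try:
            hits = find_snv_derived_pams(
                seq, variant, registry, include_less_preferred=include_less_preferred
            )
        except ValueError as exc:
            n_skipped += 1
            logger.warning("variant %s skipped: %s", variant, exc)
            continue
        screened.loc[variant.ref, variant.alt] += 1
        if hits:
            n_targetable += 1
            targetable.loc[variant.ref, variant.alt] += 1
        for key in {(h.enzyme_name, h.pattern.symbols) for h in hits}:
            events[key[0]] = events.get(key[0], 0) + 1

    rows = []
    total_events = sum(events.values())
    for enzyme in registry:
        n = events.get(enzyme.name, 0)
        rows.append(
            {
                "enzyme": enzyme.name,
                "events": n,
                "share_pct": 100.0 * n / total_events if total_events else 0.0,
                "pam": enzyme.primary_pattern.symbols,
                "pam_length": len(enzyme.primary_pattern),
                "source": enzyme.source,
            }
        )
    cov = pd.DataFrame(rows).set_index("enzyme")
    by_source = cov.groupby("source")["share_pct"].sum()
    return ScreenResult(
        targetability=TargetabilityMatrix(targetable=targetable, screened=screened),
        coverage=CasCoverage(table=cov),
        n_screened=int(screened.to_numpy().sum()),
        n_targetable=n_targetable,
        n_skipped=n_skipped,
        natural_share_pct=float(by_source.get("natural", float("nan"))),
        engineered_share_pct=float(by_source.get("engineered", float("nan"))),
    )


@dataclass(frozen=True)
class PlantRule:
    """Context rule for the generator: plant ``wt_motif`` around the variant.

    The variant sits at ``variant_index`` within the motif and mutates to
    ``alt``. When ``target_pattern`` is set, flanks are resampled until that
    motif qualifies as an SNV-derived PAM for the planted variant, making the
    ground truth certain by construction.
    """

    wt_motif: str
    variant_index: int
    alt: str
    target_pattern: str | None = None
    max_resamples: int = 500

    def __post_init__(self) -> None:
        wt = self.wt_motif[self.variant_index]
        if wt == self.alt:
            raise ValueError("planted variant must change the base")


def generate_fixture_variants(
    n: int,
    seed: int,
    context_rules: PlantRule | None = None,
    contig_length: int = 41,
) -> tuple[dict[str, str], list[Variant]]:
    """Seeded synthetic cohort: one contig per variant, SNV at the centre.

    Without rules: uniform-random A/C/G/T contigs and a random substitution.
    With a :class:`PlantRule`: the motif is planted across the centre and
    (when ``target_pattern`` is set) flanks are rejection-sampled until the
    target motif qualifies. Identical ``(n, seed)`` reproduce identical
    output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    refs: dict[str, str] = {}
    variants: list[Variant] = []
    centre = contig_length // 2
    for i in range(n):
        name = f"synth_{i}"
        if context_rules is None:
            seq = "".join(rng.choice(_BASES, size=contig_length))
            ref_base = seq[centre]
            alt = str(rng.choice([b for b in _BASES if b != ref_base]))
            variant = Variant(name, centre + 1, ref_base, alt)
        else:
            rule = context_rules
            start = centre - rule.variant_index
            if start < 0 or start + len(rule.wt_motif) > contig_length:
                raise ValueError("motif does not fit the contig at the centre")
            for attempt in range(rule.max_resamples):
                flanks = rng.choice(_BASES, size=contig_length)
                seq_list = list(flanks)
                seq_list[start:start + len(rule.wt_motif)] = list(rule.wt_motif)
                seq = "".join(seq_list)
                variant = Variant(name, centre + 1, rule.wt_motif[rule.variant_index], rule.alt)
                if rule.target_pattern is None:
                    break
                window = build_window(seq, variant, len(rule.target_pattern))
                if pattern_qualifies(rule.target_pattern, window):
                    break
            else:
                raise RuntimeError(
                    f"could not satisfy target pattern {rule.target_pattern!r} "
                    f"in {rule.max_resamples} resamples"
                )
        refs[name] = seq
        variants.append(variant)
    return refs, variants
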