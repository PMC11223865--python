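"""Readers and writers: FASTA references, minimal VCF, HGVS-g strings, reports.

Coordinates are 1-based in all user-facing I/O (VCF POS, HGVS ``g.`` numbers);
conversion to the 0-based internal convention happens in the finder, never
here.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import IO, Iterable

from Bio import SeqIO

from .finder import PamHit, Variant

__all__ = [
    "parse_hgvs_g",
    "format_hgvs_g",
    "read_fasta",
    "read_vcf_snvs",
    "write_report",
    "fetch_clinvar_snv",
    "UnsupportedVariantError",
]

logger = logging.getLogger(__name__)


class UnsupportedVariantError(ValueError):
    """A variant description that is not a single-nucleotide substitution."""


# [accession:]g.<pos><ref>><alt>, whitespace-tolerant around ':' and '>'
_HGVS_SUB = re.compile(
    r"""^\s*
        (?:(?P<acc>[A-Za-z0-9_.\-]+)\s*:)?\s*
        g\.\s*(?P<pos>\d+)\s*
        (?P<ref>[ACGTacgt])\s*>\s*(?P<alt>[ACGTacgt])
        \s*$""",
    re.VERBOSE,
)
_HGVS_OTHER = re.compile(r"g\.\s*\d+.*(del|ins|dup|inv|=|\[)", re.IGNORECASE)


def parse_hgvs_g(text: str, default_sequence_id: str = "sequence") -> Variant:
    """Parse a genomic-coordinate substitution like ``NG_008624.1:g.8631A>G``.

    The accession is recorded as the variant's sequence id when present;
    non-substitution descriptions (del/ins/dup/...) are rejected.
    """
    m = _HGVS_SUB.match(text)
    if not m:
        if _HGVS_OTHER.search(text):
            raise UnsupportedVariantError(
                f"only single-nucleotide substitutions are supported: {text!r}"
            )
        raise ValueError(f"malformed HGVS-g substitution: {text!r}")
    return Variant(
        sequence_id=m.group("acc") or default_sequence_id,
        position=int(m.group("pos")),
        ref=m.group("ref"),
        alt=m.group("alt"),
    )


def format_hgvs_g(variant: Variant) -> str:
    """Canonical HGVS-g string; round-trips through :func:`parse_hgvs_g`."""
    return f"{variant.sequence_id}:g.{variant.position}{variant.ref}>{variant.alt}"


def read_fasta(path: str | Path) -> dict[str, str]:
    """Reference sequences keyed by record id, uppercased."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_vcf_snvs(path: str | Path) -> list[Variant]:
    """Biallelic SNV rows of a (possibly header-less) VCF-like text file.

    Accepts the minimal dialect CHROM POS ID REF ALT [...]; ``#`` lines are
    headers. Non-SNV rows (indels, MNVs, multi-allelic ALTs, symbolic
    alleles) are skipped; the skip count is logged.
    """
    variants: list[Variant] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 5:
                skipped += 1
                continue
            chrom, pos, _id, ref, alt = fields[:5]
            if (
                not pos.isdigit()
                or len(ref) != 1
                or len(alt) != 1
                or ref.upper() not in "ACGT"
                or alt.upper() not in "ACGT"
                or ref.upper() == alt.upper()
            ):
                skipped += 1
                continue
            variants.append(Variant(sequence_id=chrom, position=int(pos), ref=ref, alt=alt))
    logger.info("read %d SNV(s) from %s, skipped %d non-SNV row(s)", len(variants), path, skipped)
    return variants


_REPORT_COLUMNS = [
    "enzyme", "pattern", "less_preferred", "strand", "offset",
    "matched_sequence", "star", "score",
]


def _hit_row(hit: PamHit) -> dict:
    return {
        "enzyme": hit.enzyme_name,
        "pattern": hit.pattern.symbols,
        "less_preferred": hit.less_preferred,
        "strand": hit.orientation,
        "offset": hit.offset,
        "matched_sequence": hit.matched_sequence,
        "star": hit.discriminating_specific,
        "score": round(hit.score, 2),
    }


def write_report(hits: Iterable[PamHit], format: str, destination: str | Path | IO[str]) -> None:
    """Serialize ranked hits as TSV or JSON with a stable schema.

    Output is deterministic for fixed input: fixed column order, scores to two
    decimals, booleans as ``true``/``false`` in both formats.
    """
    rows = [_hit_row(h) for h in hits]
    if format == "tsv":
        lines = ["\t".join(_REPORT_COLUMNS)]
        for r in rows:
            lines.append(
                "\t".join(
                    str(r[c]).lower() if isinstance(r[c], bool) else f"{r[c]:.2f}" if c == "score" else str(r[c])
                    for c in _REPORT_COLUMNS
                )
            )
        text = "\n".join(lines) + "\n"
    elif format == "json":
        text = json.dumps(rows, indent=2, sort_keys=False) + "\n"
    else:
        raise ValueError(f"unknown report format {format!r} (expected 'tsv' or 'json')")
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


_EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"


def fetch_clinvar_snv(
    clinvar_id: int | str,
    flank: int = 25,
    timeout: float = 15.0,
) -> tuple[Variant, dict[str, str]]:
    """Resolve a ClinVar variation id to a variant plus local genomic context.

    Explicit opt-in online helper (NCBI eutils); the core pipeline is fully
    offline. Uses the record's canonical SPDI to place the substitution, then
    fetches ``2*flank + 1`` bases of the genomic assembly around it. Returns
    the variant re-anchored on the fetched window (position ``flank + 1``)
    and a one-entry reference dict ready for the finder.
    """
    import urllib.parse
    import urllib.request

    def _get(url: str) -> bytes:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            return resp.read()

    summary_url = (
        f"{_EUTILS}/esummary.fcgi?"
        + urllib.parse.urlencode({"db": "clinvar", "id": str(clinvar_id), "retmode": "json"})
    )
    payload = json.loads(_get(summary_url))
    record = payload["result"][str(clinvar_id)]
    spdi = next(
        vs["canonical_spdi"] for vs in record["variation_set"] if vs.get("canonical_spdi")
    )
    accession, pos0_text, deleted, inserted = spdi.split(":")
    if len(deleted) != 1 or len(inserted) != 1:
        raise UnsupportedVariantError(f"ClinVar {clinvar_id}: not an SNV ({spdi})")
    pos1 = int(pos0_text) + 1  # SPDI is 0-based
    start, stop = max(1, pos1 - flank), pos1 + flank
    fasta_url = (
        f"{_EUTILS}/efetch.fcgi?"
        + urllib.parse.urlencode(
            {"db": "nuccore", "id": accession, "rettype": "fasta", "retmode": "text",
             "seq_start": start, "seq_stop": stop}
        )
    )
    lines = _get(fasta_url).decode().splitlines()
    seq = "".join(l.strip() for l in lines if not l.startswith(">")).upper()
    window_id = f"{accession}_{start}_{stop}"
    variant = Variant(window_id, pos1 - start + 1, deleted, inserted)
    return variant, {window_id: seq}


def read_report_tsv(path: str | Path) -> list[dict]:
    """Read back a TSV hit report (inverse of :func:`write_report`)."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    out = []
    for line in lines[1:]:
        vals = line.split("\t")
        row = dict(zip(header, vals))
        row["less_preferred"] = row["less_preferred"] == "true"
        row["star"] = row["star"] == "true"
        row["offset"] = int(row["offset"])
        row["score"] = float(row["score"])
        out.append(row)
    return out
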