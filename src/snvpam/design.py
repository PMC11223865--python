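"""Cas-engineering companion: conservation scoring, substitution candidates,
and iterative ΔΔG ranking over a pluggable scorer.

Workflow: PAM-contact residues (see :mod:`snvpam.structure`) are candidate
sites for engineering PAM specificity. For each site, substitutions scoring
at least a BLOSUM62 threshold (default 0, i.e. conservative replacements) are
proposed. Evolutionary conservation of each site, computed from a
user-supplied multiple sequence alignment of homologs, is annotated as advice
— a highly conserved position is more likely functionally constrained — but
never filters the candidate list. Finally a ΔΔG scorer ranks candidates; the
scorer is an injected callable (an external protein-design engine, or a mock
in tests) with the convention that *negative* ΔΔG means a more favourable
Cas-PAM interaction. Because some engines report only their top-scoring
mutant per run, ranking is iterative: score the pool, extract the best
(most negative), remove it, re-score the remainder, repeat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Protocol, runtime_checkable

import gemmi
import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment, substitution_matrices

from .structure import ContactResidue

__all__ = [
    "AMINO_ACIDS",
    "ONE_TO_THREE",
    "THREE_TO_ONE",
    "blosum62",
    "candidate_mutations",
    "propose_mutations",
    "MutationCandidate",
    "ConservationProfile",
    "conservation_index",
    "DdgScorer",
    "MockScorer",
    "SubprocessScorer",
    "score_candidates",
    "iterative_rank",
    "write_candidates_tsv",
    "export_mutant_pdb",
]

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

_BLOSUM62 = None


def blosum62():
    """The packaged BLOSUM62 substitution matrix (Biopython's copy)."""
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def _score(matrix, a: str, b: str) -> int:
    return int(matrix[a, b])


def candidate_mutations(wt_aa: str, matrix=None, threshold: int = 0) -> set[str]:
    """Amino acids ``a != wt`` with substitution score ``matrix[wt, a] >= threshold``.

    With BLOSUM62 and the default threshold this is the set of conservative
    replacements, e.g. Thr -> {Ala, Asn, Ser, Val}.
    """
    wt = wt_aa.upper()
    if wt not in AMINO_ACIDS:
        raise ValueError(f"unknown amino acid {wt_aa!r}")
    m = blosum62() if matrix is None else matrix
    return {a for a in AMINO_ACIDS if a != wt and _score(m, wt, a) >= threshold}


@dataclass(frozen=True)
class MutationCandidate:
    """A proposed point substitution at a PAM-contact residue."""

    residue_number: int
    wt_aa: str
    proposed_aa: str
    blosum_score: int
    chain: str = "A"
    conservation: float | None = None
    ddg: float | None = None

    def __post_init__(self) -> None:
        if self.proposed_aa == self.wt_aa:
            raise ValueError("proposed amino acid equals wild type")

    @property
    def spec(self) -> str:
        """Canonical mutation string, e.g. ``T291N``."""
        return f"{self.wt_aa}{self.residue_number}{self.proposed_aa}"


def propose_mutations(
    contacts: Iterable[ContactResidue],
    matrix=None,
    threshold: int = 0,
    conservation: "ConservationProfile | None" = None,
) -> list[MutationCandidate]:
    """BLOSUM-curated substitution candidates for each contact residue.

    Residues with non-standard names are skipped with a log message.
    Conservation, when supplied, is annotated; it never filters.
    """
    out: list[MutationCandidate] = []
    for contact in contacts:
        wt = THREE_TO_ONE.get(contact.residue_name)
        if wt is None:
            logger.warning("skipping non-standard residue %s %s",
                           contact.residue_name, contact.residue_number)
            continue
        cons = conservation.scores.get(contact.residue_number) if conservation else None
        m = blosum62() if matrix is None else matrix
        for aa in sorted(candidate_mutations(wt, m, threshold)):
            out.append(
                MutationCandidate(
                    residue_number=contact.residue_number,
                    wt_aa=wt,
                    proposed_aa=aa,
                    blosum_score=_score(m, wt, aa),
                    chain=contact.chain,
                    conservation=cons,
                )
            )
    return out


@dataclass(frozen=True)
class ConservationProfile:
    """Per-residue conservation index in [0, 1], keyed by the query's
    ungapped residue numbering; 0 = unconstrained, 1 = invariant."""

    scores: Mapping[int, float]
    msa_depth: int


def conservation_index(
    msa: MultipleSeqAlignment | str | Path,
    query_id: str,
    matrix=None,
    first_residue_number: int = 1,
) -> ConservationProfile:
    """Column conservation of a supplied alignment, mapped to query numbering.

    For every pair of sequences in a column the BLOSUM62 similarity of their
    residues is normalized to [0, 1] as ``(s(a,b) - s_min) / (max(s(a,a),
    s(b,b)) - s_min)`` where ``s_min`` is the matrix minimum; a pair involving
    a gap (or any non-standard symbol) contributes the minimum, 0. The column
    index is the mean over all pairs, so a column identical across sequences
    scores exactly 1. Columns where the query is gapped carry no entry.
    """
    if isinstance(msa, (str, Path)):
        msa = AlignIO.read(str(msa), "fasta")
    if len(msa) < 2:
        raise ValueError(f"alignment depth {len(msa)} < 2")
    lengths = {len(rec.seq) for rec in msa}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    query = next((rec for rec in msa if rec.id == query_id), None)
    if query is None:
        raise KeyError(f"query id {query_id!r} not in alignment")
    m = blosum62() if matrix is None else matrix
    s_min = min(_score(m, a, b) for a in AMINO_ACIDS for b in AMINO_ACIDS)

    def pair_similarity(a: str, b: str) -> float:
        if a not in AMINO_ACIDS or b not in AMINO_ACIDS:
            return 0.0
        denom = max(_score(m, a, a), _score(m, b, b)) - s_min
        return (_score(m, a, b) - s_min) / denom

    scores: dict[int, float] = {}
    resnum = first_residue_number
    n = len(msa)
    for col in range(msa.get_alignment_length()):
        q = str(query.seq[col]).upper()
        if q in ("-", "."):
            continue
        column = [str(rec.seq[col]).upper() for rec in msa]
        vals = [
            pair_similarity(column[i], column[j])
            for i in range(n) for j in range(i + 1, n)
        ]
        scores[resnum] = float(np.clip(np.mean(vals), 0.0, 1.0))
        resnum += 1
    return ConservationProfile(scores=scores, msa_depth=n)


@runtime_checkable
class DdgScorer(Protocol):
    """Contract for ΔΔG engines: deterministic callable mapping a structure
    (path or object, engine's choice) and one mutation to a real ΔΔG;
    negative = more favourable PAM interaction."""

    def __call__(self, structure, mutation: MutationCandidate) -> float: ...


class MockScorer:
    """Deterministic table-driven scorer for tests and dry runs.

    ``table`` maps mutation strings like ``"T291N"`` to ΔΔG; unlisted
    mutations get ``default``.
    """

    def __init__(self, table: Mapping[str, float] | None = None, default: float = 0.0):
        self.table = dict(table or {})
        self.default = default

    def __call__(self, structure, mutation: MutationCandidate) -> float:
        return self.table.get(mutation.spec, self.default)


class SubprocessScorer:
    """Adapter template for an external protein-design executable.

    Runs ``argv_template`` with ``{structure}``, ``{chain}`` and ``{mutation}``
    placeholders substituted, and parses the last whitespace-separated token
    of stdout as the ΔΔG. Adjust ``parse`` for engines with other output
    conventions.
    """

    def __init__(self, argv_template: list[str], parse: Callable[[str], float] | None = None):
        self.argv_template = list(argv_template)
        self.parse = parse or (lambda out: float(out.split()[-1]))

    def __call__(self, structure, mutation: MutationCandidate) -> float:
        import subprocess

        argv = [
            arg.format(structure=structure, chain=mutation.chain, mutation=mutation.spec)
            for arg in self.argv_template
        ]
        result = subprocess.run(argv, capture_output=True, text=True, check=True)
        return self.parse(result.stdout)


def score_candidates(
    structure,
    contacts: Iterable[ContactResidue],
    candidates: Iterable[MutationCandidate],
    scorer: DdgScorer,
) -> list[MutationCandidate]:
    """Annotate each candidate with the scorer's ΔΔG, preserving input order.

    A scorer failure leaves that candidate unscored (``ddg=None``) and the run
    continues; failures are logged.
    """
    out: list[MutationCandidate] = []
    for cand in candidates:
        try:
            ddg = float(scorer(structure, cand))
            out.append(replace(cand, ddg=ddg))
        except Exception as exc:  # noqa: BLE001 - contract: isolate scorer faults
            logger.warning("scorer failed on %s: %s", cand.spec, exc)
            out.append(replace(cand, ddg=None))
    return out


def iterative_rank(
    candidates: Iterable[MutationCandidate],
    scorer: DdgScorer,
    structure=None,
) -> list[MutationCandidate]:
    """Rank candidates by repeated best-extraction.

    Each round the scorer is invoked on every remaining candidate; the most
    negative ΔΔG is extracted (ties broken by residue number, then proposed
    amino acid) and the pool re-scored. For a round-independent scorer this
    equals a single sort; for engines whose landscape shifts after removing
    the top mutant it follows the per-round minima. Returns candidates in
    extraction order with ``ddg`` set to the score of the round in which each
    was extracted. Unscorable candidates rank last within their round.
    """
    pool = list(candidates)
    ranked: list[MutationCandidate] = []
    while pool:
        round_scores: list[tuple[float, int, str, int]] = []
        for i, cand in enumerate(pool):
            try:
                ddg = float(scorer(structure, cand))
            except Exception as exc:  # noqa: BLE001
                logger.warning("scorer failed on %s: %s", cand.spec, exc)
                ddg = float("inf")
            round_scores.append((ddg, cand.residue_number, cand.proposed_aa, i))
        ddg, _, _, i = min(round_scores)
        ranked.append(replace(pool.pop(i), ddg=None if ddg == float("inf") else ddg))
    return ranked


def write_candidates_tsv(candidates: Iterable[MutationCandidate], destination) -> None:
    """TSV mirror of the interactive candidate table (rank = row order)."""
    lines = ["rank\tresidue\twt\tproposed\tblosum\tconservation\tddg"]
    for rank, c in enumerate(candidates, start=1):
        cons = f"{c.conservation:.3f}" if c.conservation is not None else "-"
        ddg = f"{c.ddg:.3f}" if c.ddg is not None else "-"
        lines.append(
            f"{rank}\t{c.residue_number}\t{c.wt_aa}\t{c.proposed_aa}"
            f"\t{c.blosum_score}\t{cons}\t{ddg}"
        )
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


def export_mutant_pdb(
    structure_path: str | Path,
    mutation: MutationCandidate,
    destination: str | Path,
) -> Path:
    """Write one PDB with the mutated residue renamed (side-chain atoms beyond
    Cβ removed; rebuilding the side chain is the scorer's concern)."""
    st = gemmi.read_structure(str(structure_path))
    st.setup_entities()
    new_name = ONE_TO_THREE[mutation.proposed_aa]
    found = False
    for model in st:
        for chain in model:
            if chain.name != mutation.chain:
                continue
            for residue in chain:
                if residue.seqid.num == mutation.residue_number:
                    if THREE_TO_ONE.get(residue.name) != mutation.wt_aa:
                        raise ValueError(
                            f"residue {mutation.chain}/{mutation.residue_number} is "
                            f"{residue.name}, expected {ONE_TO_THREE[mutation.wt_aa]}"
                        )
                    residue.name = new_name
                    backbone = {"N", "CA", "C", "O", "CB", "OXT"}
                    for i in range(len(residue) - 1, -1, -1):
                        if residue[i].name not in backbone:
                            del residue[i]
                    found = True
    if not found:
        raise ValueError(
            f"residue {mutation.chain}/{mutation.residue_number} not found in {structure_path}"
        )
    dest = Path(destination)
    st.write_pdb(str(dest))
    return dest
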