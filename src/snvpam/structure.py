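"""PAM-contact detection in Cas-DNA complex structures.

Given a deposited Cas nuclease / DNA complex and a user designation of which
nucleotides form the PAM, report every protein residue with at least one heavy
atom within a distance threshold (default 4.0 Å) of any heavy atom of those
nucleotides. These PAM-interacting residues are the starting point for
engineering PAM specificity. The PAM nucleotides must be designated
explicitly (chain + residue numbers): deposited numbering of PAM positions is
author-assigned and cannot be inferred from the coordinate file alone.

Distances are minimum Euclidean atom-atom distances over heavy atoms;
hydrogens are retained in the model but excluded from contact math, because
deposited structures vary in hydrogen content. Waters and non-designated
hetero groups never count as PAM atoms.
"""

from __future__ import annotations

import math
import urllib.request
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Structure",
    "PamSelection",
    "ContactResidue",
    "load_structure",
    "find_pam_contacts",
    "fetch_structure",
    "StructureFormatError",
    "SelectionError",
]


class StructureFormatError(ValueError):
    """Unparsable or empty coordinate file."""


class SelectionError(ValueError):
    """A PAM selection referencing residues absent from the structure."""


@dataclass(frozen=True)
class Atom:
    chain: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float
    altloc: str

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def pos(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class Structure:
    """Flat atom list with per-chain polymer classification."""

    atoms: tuple[Atom, ...]
    chain_kinds: dict  # chain id -> "protein" | "nucleic" | "other"
    name: str = ""

    def protein_atoms(self) -> list[Atom]:
        return [
            a for a in self.atoms
            if self.chain_kinds.get(a.chain) == "protein" and not a.is_hydrogen
        ]

    def residue_atoms(self, chain: str, residue_number: int) -> list[Atom]:
        return [a for a in self.atoms if a.chain == chain and a.residue_number == residue_number]


def _residue_kind(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None:
        if info.is_amino_acid():
            return "protein"
        if info.is_nucleic_acid():
            return "nucleic"
    return "other"


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per atom name: highest occupancy, ties to altloc 'A'/''."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        key = (atom.occ, atom.altloc in ("", "A"))
        prev_key = (prev.occ, prev.altloc in ("", "A"))
        if key > prev_key:
            by_name[atom.name] = atom
    return list(by_name.values())


def load_structure(path: str | Path) -> Structure:
    """Read a PDB or mmCIF file into a flat, altloc-resolved atom list.

    Chains are classified protein/nucleic by majority vote over their residue
    names. Hydrogens are retained (contact math skips them later).
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"no models in {path}")
    model = st[0]
    atoms: list[Atom] = []
    kind_votes: dict[str, dict[str, int]] = {}
    for chain in model:
        votes = kind_votes.setdefault(chain.name, {})
        for residue in chain:
            kind = _residue_kind(residue.name)
            if kind != "other" or residue.name not in ("HOH", "WAT"):
                votes[kind] = votes.get(kind, 0) + 1
            for atom in _resolve_altlocs(residue):
                pos = atom.pos
                if not all(math.isfinite(v) for v in (pos.x, pos.y, pos.z)):
                    raise StructureFormatError(
                        f"non-finite coordinates for {chain.name}/{residue.seqid.num}/{atom.name}"
                    )
                atoms.append(
                    Atom(
                        chain=chain.name,
                        residue_number=residue.seqid.num,
                        insertion_code=residue.seqid.icode.strip(),
                        residue_name=residue.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        x=pos.x,
                        y=pos.y,
                        z=pos.z,
                        occupancy=atom.occ,
                        altloc=atom.altloc,
                    )
                )
    if not atoms:
        raise StructureFormatError(f"empty coordinate list in {path}")
    chain_kinds = {
        cid: max(votes, key=votes.get) if votes else "other"
        for cid, votes in kind_votes.items()
    }
    return Structure(atoms=tuple(atoms), chain_kinds=chain_kinds, name=st.name or Path(path).stem)


@dataclass(frozen=True)
class PamSelection:
    """Designation of the PAM nucleotides: one chain, explicit residue numbers."""

    chain: str
    residue_numbers: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.residue_numbers:
            raise SelectionError("PAM selection lists no residues")
        object.__setattr__(self, "residue_numbers", tuple(self.residue_numbers))

    def atoms(self, structure: Structure) -> list[Atom]:
        """Heavy atoms of the designated nucleotides; validates existence."""
        out: list[Atom] = []
        for num in self.residue_numbers:
            res_atoms = structure.residue_atoms(self.chain, num)
            if not res_atoms:
                raise SelectionError(
                    f"PAM selection references missing residue {self.chain}/{num}"
                )
            kinds = {_residue_kind(a.residue_name) for a in res_atoms}
            if "nucleic" not in kinds:
                raise SelectionError(
                    f"PAM selection residue {self.chain}/{num} is not a nucleotide "
                    f"({res_atoms[0].residue_name})"
                )
            out.extend(a for a in res_atoms if not a.is_hydrogen)
        return out


@dataclass(frozen=True)
class ContactResidue:
    """A protein residue within the contact threshold of the PAM."""

    chain: str
    residue_number: int
    residue_name: str
    min_distance: float
    protein_atom: str
    nucleic_atom: str

    @property
    def label(self) -> str:
        """Compact one-letter label like ``T291`` when the residue is standard."""
        one = _THREE_TO_ONE.get(self.residue_name, "X")
        return f"{one}{self.residue_number}"


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def find_pam_contacts(
    structure: Structure,
    pam_selection: PamSelection,
    threshold: float = 4.0,
) -> list[ContactResidue]:
    """Protein residues with a heavy atom within ``threshold`` Å of any heavy
    PAM-nucleotide atom, sorted by (chain, residue number), each annotated
    with the minimum distance and the closest atom pair."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    pam_atoms = pam_selection.atoms(structure)
    prot_atoms = structure.protein_atoms()
    if not prot_atoms:
        return []
    tree = cKDTree(np.array([a.pos for a in prot_atoms]))
    pam_xyz = np.array([a.pos for a in pam_atoms])
    best: dict[tuple[str, int], tuple[float, Atom, Atom]] = {}
    for pam_atom, neighbours in zip(pam_atoms, tree.query_ball_point(pam_xyz, r=threshold)):
        for j in neighbours:
            pa = prot_atoms[j]
            d = math.dist(pa.pos, pam_atom.pos)
            key = (pa.chain, pa.residue_number)
            if key not in best or d < best[key][0]:
                best[key] = (d, pa, pam_atom)
    contacts = [
        ContactResidue(
            chain=chain,
            residue_number=num,
            residue_name=pa.residue_name,
            min_distance=d,
            protein_atom=pa.atom_name,
            nucleic_atom=na.atom_name,
        )
        for (chain, num), (d, pa, na) in best.items()
    ]
    contacts.sort(key=lambda c: (c.chain, c.residue_number))
    return contacts


def write_contacts_tsv(contacts: list[ContactResidue], destination: str | Path) -> None:
    """TSV report: chain, number, name, min distance (2 decimals), atom pair."""
    lines = ["chain\tresidue_number\tresidue_name\tmin_distance\tprotein_atom\tnucleic_atom"]
    for c in contacts:
        lines.append(
            f"{c.chain}\t{c.residue_number}\t{c.residue_name}\t{c.min_distance:.2f}"
            f"\t{c.protein_atom}\t{c.nucleic_atom}"
        )
    Path(destination).write_text("\n".join(lines) + "\n")


def fetch_structure(pdb_id: str, destination: str | Path, timeout: float = 30.0) -> Path:
    """Download a deposited mmCIF by accession (explicit opt-in; the core
    pipeline never fetches on its own)."""
    pdb_id = pdb_id.lower()
    url = f"https://files.rcsb.org/download/{pdb_id}.cif"
    dest = Path(destination)
    dest.parent.mkdir(parents=True, exist_ok=True)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        dest.write_bytes(resp.read())
    return dest
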