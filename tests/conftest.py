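"""Shared fixtures: independent brute-force oracles and toy-structure builders.

The oracles here deliberately re-derive IUPAC semantics and distance math
from first principles (their own expansion and complement tables, all-pairs
scans) so they stay independent of the package code paths they check.
"""

from __future__ import annotations

import math
import random

import pytest

from snvpam import load_registry

# --- independent IUPAC machinery (do not import from snvpam.iupac) ----------

ORACLE_EXPANSION = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "M": "AC", "R": "AG", "W": "AT", "S": "CG", "Y": "CT", "K": "GT",
    "V": "ACG", "H": "ACT", "D": "AGT", "B": "CGT", "N": "ACGT",
}
_BASE_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def oracle_pattern_sets(pattern: str) -> list[set[str]]:
    return [set(ORACLE_EXPANSION[s]) for s in pattern]


def oracle_rc_sets(pattern: str) -> list[set[str]]:
    """Reverse-complement as base-set algebra: complement every base in each
    expansion set, then reverse the list."""
    return [{_BASE_COMP[b] for b in s} for s in reversed(oracle_pattern_sets(pattern))]


def oracle_placements(sets: list[set[str]], seq: str) -> list[int]:
    L = len(sets)
    out = []
    for start in range(len(seq) - L + 1):
        if all(seq[start + i] in sets[i] for i in range(L)):
            out.append(start)
    return out


def oracle_qualifying_placements(pattern: str, wt: str, mut: str) -> list[tuple[str, int]]:
    """Mutant-exclusive placements per the discrimination rule, brute force."""
    fwd, rev = oracle_pattern_sets(pattern), oracle_rc_sets(pattern)
    if oracle_placements(fwd, wt) or oracle_placements(rev, wt):
        return []
    return [("forward", s) for s in oracle_placements(fwd, mut)] + [
        ("reverse", s) for s in oracle_placements(rev, mut)
    ]


def random_window_and_pattern(rng: random.Random) -> tuple[str, str, int, str]:
    """A random (wt_window, mut_window via centre substitution, centre, pattern)."""
    pattern = "".join(rng.choices(list(ORACLE_EXPANSION), k=rng.randint(1, 8)))
    L = len(pattern)
    width = rng.randint(1, 2 * L + 1)
    wt = "".join(rng.choices("ACGT", k=width))
    centre = rng.randrange(width)
    alt = rng.choice([b for b in "ACGT" if b != wt[centre]])
    mut = wt[:centre] + alt + wt[centre + 1:]
    return wt, mut, centre, pattern


# --- toy structures ----------------------------------------------------------

_PDB_ATOM = (
    "ATOM  {serial:5d} {name:<4s}{altloc:1s}{resname:>3s} {chain:1s}{resnum:4d}"
    "    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bfac:6.2f}          {element:>2s}\n"
)


def format_pdb(atoms) -> str:
    """Render atom tuples (chain, resnum, resname, atom_name, element, x, y, z,
    occ, altloc) as PDB text."""
    text = ""
    for serial, (chain, resnum, resname, name, element, x, y, z, occ, altloc) in enumerate(
        atoms, start=1
    ):
        padded = name if len(name) >= 4 else f" {name:<3s}"
        text += _PDB_ATOM.format(
            serial=serial, name=padded, altloc=altloc or " ", resname=resname,
            chain=chain, resnum=resnum, x=x, y=y, z=z, occ=occ, bfac=0.0,
            element=element,
        )
    return text + "END\n"


def toy_complex_atoms(contact_distances: dict[int, float]):
    """A DNA nucleotide (chain B, residue 1) at the origin plus one-atom ALA
    residues on chain A, residue number -> distance from the PAM atom."""
    atoms = [("B", 1, "DG", "N9", "N", 0.0, 0.0, 0.0, 1.0, "")]
    for resnum, dist in sorted(contact_distances.items()):
        atoms.append(("A", resnum, "ALA", "CA", "C", dist, 0.0, 0.0, 1.0, ""))
    return atoms


def oracle_contacts(structure, pam_atoms, threshold: float) -> dict[tuple[str, int], float]:
    """Naive all-pairs min-distance scan over heavy atoms (independent of the
    spatially indexed implementation)."""
    out: dict[tuple[str, int], float] = {}
    for pa in structure.atoms:
        if structure.chain_kinds.get(pa.chain) != "protein" or pa.element in ("H", "D"):
            continue
        for na in pam_atoms:
            d = math.dist((pa.x, pa.y, pa.z), (na.x, na.y, na.z))
            key = (pa.chain, pa.residue_number)
            if d <= threshold and (key not in out or d < out[key]):
                out[key] = d
    return out


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture
def write_pdb(tmp_path):
    def _write(atoms, name="toy.pdb"):
        path = tmp_path / name
        path.write_text(format_pdb(atoms))
        return path

    return _write
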