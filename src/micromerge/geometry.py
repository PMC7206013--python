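"""Coordinate-model checks: chains per asymmetric unit, catalytic-site
distances, and disordered-region gaps.

A metacaspase zymogen keeps its catalytic dyad (His/Cys) poised around the
carbonyl carbon of the self-cleavage lysine; the deposited models place both
dyad atoms ~3.2 Å from that carbonyl.  This module reads PDB coordinate
files (via gemmi) into a light chain/residue/atom model and answers the
geometric questions the models are cited for: how many protein chains are in
the asymmetric unit, how far two selected atoms are, and which residue
ranges are missing (disordered) in a chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "AtomSelector",
    "read_pdb",
    "count_polymer_chains",
    "atom_distance",
    "chain_gaps",
    "dyad_distances",
]

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    alt_loc: str = ""

    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Residue:
    number: int
    name: str
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def is_amino_acid(self) -> bool:
        return self.name.upper() in _AA3


@dataclass
class Chain:
    chain_id: str
    residues: dict[int, Residue] = field(default_factory=dict)

    def amino_acid_count(self) -> int:
        return sum(1 for r in self.residues.values() if r.is_amino_acid)

    def residue_numbers(self) -> list[int]:
        return sorted(n for n, r in self.residues.items() if r.is_amino_acid)


@dataclass
class StructureModel:
    name: str
    chains: dict[str, Chain] = field(default_factory=dict)

    def chain(self, chain_id: str) -> Chain:
        if chain_id not in self.chains:
            raise KeyError(f"no chain {chain_id!r} in model {self.name!r}")
        return self.chains[chain_id]


@dataclass(frozen=True)
class AtomSelector:
    """(chain, residue number, atom name) selection."""

    chain: str
    residue: int
    atom: str

    def __str__(self) -> str:
        return f"{self.chain}/{self.residue}/{self.atom}"


def read_pdb(path, name: str | None = None) -> tuple[StructureModel, list[str]]:
    """Read a PDB coordinate file into a StructureModel.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties go to alt-loc 'A'); waters and ligands are retained in their
    chains but flagged non-polymer by residue name.  Returns the model plus
    per-line diagnostics for records whose coordinate fields do not parse.
    Raises on an empty model.
    """
    diagnostics = _scan_records(path)
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    model_name = name or str(getattr(st, "name", "") or path)
    out = StructureModel(name=model_name)
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    first = st[0]
    for ch in first:
        chain = out.chains.setdefault(ch.name, Chain(chain_id=ch.name))
        for res in ch:
            number = res.seqid.num
            residue = chain.residues.setdefault(number, Residue(number=number, name=res.name))
            # group atom sites by name, keep the best alt-loc
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                cur = best.get(atom.name)
                if cur is None:
                    best[atom.name] = atom
                    continue
                if atom.occ > cur.occ or (
                    atom.occ == cur.occ and (atom.altloc or "B") < (cur.altloc or "B")
                ):
                    best[atom.name] = atom
            for aname, atom in best.items():
                residue.atoms[aname] = Atom(
                    name=aname,
                    element=atom.element.name,
                    x=atom.pos.x,
                    y=atom.pos.y,
                    z=atom.pos.z,
                    occupancy=atom.occ,
                    alt_loc=atom.altloc or "",
                )
    if not any(ch.residues for ch in out.chains.values()):
        raise ValueError(f"{path}: model contains no residues")
    return out, diagnostics


def _scan_records(path) -> list[str]:
    diagnostics = []
    with open(path, "r", encoding="ascii", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                diagnostics.append(f"line {lineno}: truncated coordinate record")
                continue
            try:
                [float(line[i:j]) for i, j in ((30, 38), (38, 46), (46, 54))]
            except ValueError:
                diagnostics.append(f"line {lineno}: non-numeric coordinate field")
    return diagnostics


def count_polymer_chains(model: StructureModel, min_residues: int = 20) -> int:
    """Chains with at least ``min_residues`` amino-acid residues."""
    return sum(1 for ch in model.chains.values() if ch.amino_acid_count() >= min_residues)


def _resolve(model: StructureModel, sel: AtomSelector) -> Atom:
    try:
        chain = model.chain(sel.chain)
        residue = chain.residues[sel.residue]
        return residue.atoms[sel.atom]
    except KeyError as exc:
        raise KeyError(f"selection {sel} does not resolve in model {model.name!r}") from exc


def atom_distance(model: StructureModel, sel1: AtomSelector, sel2: AtomSelector) -> float:
    """Euclidean distance (Å) between two uniquely selected atoms."""
    a1, a2 = _resolve(model, sel1), _resolve(model, sel2)
    return float(np.linalg.norm(a1.position() - a2.position()))


def chain_gaps(model: StructureModel, chain_id: str) -> list[tuple[int, int]]:
    """Maximal runs of missing residue numbers inside a chain's observed span."""
    numbers = model.chain(chain_id).residue_numbers()
    if len(numbers) < 2:
        return []
    present = set(numbers)
    gaps: list[tuple[int, int]] = []
    start = None
    for n in range(numbers[0], numbers[-1] + 1):
        if n not in present:
            if start is None:
                start = n
        elif start is not None:
            gaps.append((start, n - 1))
            start = None
    return gaps


def dyad_distances(
    model: StructureModel,
    chain_id: str,
    his_residue: int = 86,
    nucleophile_residue: int = 139,
    carbonyl_residue: int = 225,
) -> dict[str, float]:
    """Candidate dyad-to-scissile-carbonyl distances.

    Which exact atoms carry the quoted dyad geometry is ambiguous, so the
    checker reports every sensible candidate: the His side-chain nitrogens
    (NE2, ND1) and the nucleophile's side-chain terminus (SG when the
    catalytic cysteine is present, CB for a Cys→Ala mutant), each measured
    to the carbonyl carbon (C) of the cleavage-site residue.
    """
    chain = model.chain(chain_id)
    try:
        target = AtomSelector(chain_id, carbonyl_residue, "C")
        _resolve(model, target)
    except KeyError:
        raise KeyError(
            f"carbonyl carbon of residue {carbonyl_residue} not present in chain {chain_id}"
        )
    out: dict[str, float] = {}
    for atom in ("NE2", "ND1"):
        sel = AtomSelector(chain_id, his_residue, atom)
        try:
            out[f"His{his_residue}.{atom}"] = atom_distance(model, sel, target)
        except KeyError:
            continue
    nuc = chain.residues.get(nucleophile_residue)
    if nuc is not None:
        terminal = "SG" if "SG" in nuc.atoms else "CB"
        sel = AtomSelector(chain_id, nucleophile_residue, terminal)
        try:
            out[f"{nuc.name.title()}{nucleophile_residue}.{terminal}"] = atom_distance(
                model, sel, target
            )
        except KeyError:
            pass
    return out
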