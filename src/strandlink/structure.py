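"""Hierarchical coordinate model and PDB I/O.

The data model is deliberately light: chains of residues of atoms, with
optional per-residue secondary-structure labels ('H' helix, 'E' strand,
'L' loop).  Only the ATOM/TER/END subset of the PDB format is handled;
HETATM records and waters are skipped on reading.  File parsing and
writing are delegated to gemmi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1TO3 = {v: k for k, v in _AA3TO1.items()}


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float).reshape(3)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    """One residue; `index` is the 1-based position within its chain."""

    index: int
    aa: str
    atoms: dict[str, Atom] = field(default_factory=dict)
    incomplete: bool = False

    def __getitem__(self, atom_name: str) -> np.ndarray:
        return self.atoms[atom_name].coord

    def __contains__(self, atom_name: str) -> bool:
        return atom_name in self.atoms

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms.values() if a.element != "H"])

    def copy(self) -> "Residue":
        return Residue(
            self.index,
            self.aa,
            {n: Atom(a.name, a.element, a.coord.copy()) for n, a in self.atoms.items()},
            self.incomplete,
        )


class Structure:
    """Ordered chains of residues with optional secondary-structure labels."""

    def __init__(self, name: str = "structure"):
        self.name = name
        self.chains: dict[str, list[Residue]] = {}
        # per-chain label strings over {'H','E','L'}, parallel to residue lists
        self.ss: dict[str, list[str]] = {}

    # -- construction ------------------------------------------------------

    def add_chain(self, chain_id: str, residues: list[Residue]) -> None:
        if len(chain_id) != 1:
            raise ValueError("chain ids are single characters")
        if chain_id in self.chains:
            raise ValueError(f"duplicate chain id {chain_id!r}")
        indices = [r.index for r in residues]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("residue indices must be strictly increasing")
        self.chains[chain_id] = residues

    # -- access ------------------------------------------------------------

    def __getitem__(self, chain_id: str) -> list[Residue]:
        return self.chains[chain_id]

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def residues(self):
        """Iterate (chain_id, residue) over all chains in order."""
        for cid, residues in self.chains.items():
            for res in residues:
                yield cid, res

    def heavy_coords(self) -> np.ndarray:
        coords = [
            a.coord
            for _, res in self.residues()
            for a in res.atoms.values()
            if a.element != "H"
        ]
        return np.array(coords) if coords else np.empty((0, 3))

    def backbone_coords(self, chain_id: str, atom: str = "CA") -> np.ndarray:
        return np.array([r[atom] for r in self.chains[chain_id]])

    # -- manipulation ------------------------------------------------------

    def copy(self) -> "Structure":
        out = Structure(self.name)
        for cid, residues in self.chains.items():
            out.add_chain(cid, [r.copy() for r in residues])
        out.ss = {cid: list(lab) for cid, lab in self.ss.items()}
        return out

    def transformed(self, transform) -> "Structure":
        """Return a copy moved by a RigidTransform (labels preserved)."""
        out = self.copy()
        for _, res in out.residues():
            for atom in res.atoms.values():
                atom.coord = transform.apply(atom.coord)
        return out


@dataclass
class StrandSegment:
    """A run of strand ('E') residues within one chain; ends inclusive."""

    chain_id: str
    start: int
    end: int
    ca_coords: np.ndarray

    def __post_init__(self) -> None:
        if self.length < 3:
            raise ValueError("strand segments must span at least 3 residues")
        self.ca_coords = np.asarray(self.ca_coords, dtype=float).reshape(-1, 3)
        if len(self.ca_coords) != self.length:
            raise ValueError("CA coordinate count does not match residue span")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def residues(self, structure: Structure) -> list[Residue]:
        chain = structure[self.chain_id]
        by_index = {r.index: r for r in chain}
        return [by_index[i] for i in range(self.start, self.end + 1)]


# -- PDB I/O ---------------------------------------------------------------


def read_pdb(path) -> Structure:
    """Read ATOM records from a PDB file.

    HETATM records and waters are skipped; of alternate locations only
    blank or 'A' is kept.  Residues missing any backbone atom are flagged
    incomplete with a warning rather than rejected.
    """
    try:
        doc = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    doc.setup_entities()
    if len(doc) == 0:
        raise ValueError(f"no ATOM records in {path}")
    model = doc[0]
    out = Structure(name=str(path))
    for chain in model:
        residues = []
        for i, res in enumerate(chain, start=1):
            if res.het_flag != "A" or res.name in ("HOH", "WAT"):
                continue
            atoms: dict[str, Atom] = {}
            for atom in res:
                if atom.altloc not in ("", "\x00", "A"):
                    continue
                atoms[atom.name] = Atom(
                    atom.name,
                    atom.element.name if atom.element else atom.name[0],
                    np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                )
            r = Residue(len(residues) + 1, _AA3TO1.get(res.name, "X"), atoms)
            if not r.has_backbone():
                r.incomplete = True
                logger.warning(
                    "residue %s %s%d missing backbone atoms; flagged incomplete",
                    res.name, chain.name, res.seqid.num,
                )
            residues.append(r)
        if residues:
            out.add_chain(chain.name[:1], residues)
    if not out.chains:
        raise ValueError(f"no ATOM records in {path}")
    return out


def write_pdb(structure: Structure, path) -> None:
    """Write standard ATOM records with TER between chains and END."""
    for _, res in structure.residues():
        for atom in res.atoms.values():
            if np.any(np.abs(atom.coord) >= 10000.0):
                raise ValueError(
                    f"coordinate {atom.coord} exceeds the PDB 8.3 field width"
                )
    doc = gemmi.Structure()
    doc.name = structure.name
    model = gemmi.Model("1")
    for cid, residues in structure.chains.items():
        chain = gemmi.Chain(cid)
        for res in residues:
            g_res = gemmi.Residue()
            g_res.name = _AA1TO3.get(res.aa, "UNK")
            g_res.seqid = gemmi.SeqId(res.index, " ")
            for atom in res.atoms.values():
                g_atom = gemmi.Atom()
                g_atom.name = atom.name
                g_atom.element = gemmi.Element(atom.element)
                g_atom.pos = gemmi.Position(*atom.coord)
                g_res.add_atom(g_atom)
            chain.add_residue(g_res)
        model.add_chain(chain)
    doc.add_model(model)
    doc.setup_entities()
    doc.write_pdb(str(path))
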