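"""Internal-coordinate backbone building (NeRF chain extension).

Residues are built from ideal peptide bond lengths and angles plus a
per-residue (phi, psi, omega) triple.  Poly-alanine is produced: CB is
placed tetrahedrally off CA so that sidechain stripping (polyglycine
conversion) is a real operation downstream.
"""

from __future__ import annotations

import numpy as np

from .structure import Atom, Residue, Structure

# ideal peptide geometry (lengths in A, angles in degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O, A_C_CA_CB = 111.2, 116.2, 121.7, 120.8, 110.1
# improper torsion N-C-CA-CB placing CB with L-amino-acid chirality
T_N_C_CA_CB = 120.0


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d given chain a-b-c, |cd|, angle(b,c,d) and torsion(a,b,c,d)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def build_backbone(dihedrals: list[tuple[float, float, float]], aa: str = "A"):
    """Build a chain of residues from (phi, psi, omega) triples.

    phi of the first residue is unused (no preceding C); omega of residue i
    is the CA(i)-C(i)-N(i+1)-CA(i+1) torsion.  Returns a list of Residues
    indexed from 1.
    """
    n_res = len(dihedrals)
    if n_res < 1:
        raise ValueError("need at least one residue")
    coords: list[dict[str, np.ndarray]] = []
    ang = np.radians(A_N_CA_C)
    first = {
        "N": np.zeros(3),
        "CA": np.array([B_N_CA, 0.0, 0.0]),
    }
    first["C"] = first["CA"] + B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append(first)
    for i in range(1, n_res):
        phi_i = dihedrals[i][0]
        psi_prev, omega_prev = dihedrals[i - 1][1], dihedrals[i - 1][2]
        prev = coords[-1]
        cur: dict[str, np.ndarray] = {}
        cur["N"] = place_atom(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, psi_prev)
        cur["CA"] = place_atom(prev["CA"], prev["C"], cur["N"], B_N_CA, A_C_N_CA, omega_prev)
        cur["C"] = place_atom(prev["C"], cur["N"], cur["CA"], B_CA_C, A_N_CA_C, phi_i)
        coords.append(cur)
    # carbonyl O: trans to the next N (psi + 180)
    for i, cur in enumerate(coords):
        psi_i = dihedrals[i][1]
        cur["O"] = place_atom(cur["N"], cur["CA"], cur["C"], B_C_O, A_CA_C_O, psi_i + 180.0)
        if aa != "G":
            cur["CB"] = place_atom(
                cur["N"], cur["C"], cur["CA"], B_CA_CB, A_C_CA_CB, T_N_C_CA_CB
            )
    residues = []
    for i, cur in enumerate(coords, start=1):
        atoms = {name: Atom(name, name[0], xyz) for name, xyz in cur.items()}
        residues.append(Residue(i, aa, atoms))
    return residues


def residues_to_structure(residues, chain_id: str = "A", name: str = "built") -> Structure:
    s = Structure(name)
    s.add_chain(chain_id, residues)
    return s
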